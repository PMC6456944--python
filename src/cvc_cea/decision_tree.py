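"""Three-attempt catheterization decision tree.

Each patient undergoes up to three cannulation attempts. Every attempt
carries a per-attempt complication risk (``c1``, ``c2``, ``c3``); the first
two attempts additionally split into success/failure (``f1``, ``f2``) with
failures moving on to the next attempt. The third attempt is terminal
whether or not it succeeds. A patient's event indicator is 1 when a
complication occurred on any attempt reached; effectiveness is the
probability of remaining complication-free.

Costs accrue once per attempt-with-complication, at the expected cost of a
single complication episode (see :func:`attribute_cost`): the split between
arterial puncture and the nine pooled "other" complications is a weight
vector, not a sub-tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Union

from .parameters import StrategyParams

__all__ = [
    "ChanceNode",
    "Terminal",
    "StrategyResult",
    "build_tree",
    "evaluate",
    "evaluate_strategy",
    "attribute_cost",
    "arterial_share",
    "p_any_complication_closed_form",
    "expected_complications_closed_form",
    "tree_to_json",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class Terminal:
    """Leaf of the tree: accumulated cost and complication indicator."""

    cost: float
    event: int

    def __post_init__(self) -> None:
        if self.cost < 0.0:
            raise ValueError(f"terminal cost must be nonnegative, got {self.cost}")
        if self.event not in (0, 1):
            raise ValueError(f"event indicator must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class ChanceNode:
    """A chance node with probability-weighted branches summing to one."""

    label: str
    branches: tuple[tuple[float, Union["ChanceNode", Terminal]], ...]

    def __post_init__(self) -> None:
        total = 0.0
        for p, _child in self.branches:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.label}: branch probability {p} outside [0, 1]")
            total += p
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(
                f"{self.label}: branch probabilities sum to {total}, expected 1"
            )


@dataclass(frozen=True)
class StrategyResult:
    """Per-person expected cost and complication risk for one strategy."""

    strategy: str
    expected_cost: float
    p_any_complication: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_any_complication <= 1.0 + _PROB_TOL:
            raise ValueError(
                f"p_any_complication {self.p_any_complication} outside [0, 1]"
            )
        if self.expected_cost < 0.0:
            raise ValueError("expected_cost must be nonnegative")

    @property
    def effectiveness(self) -> float:
        """Probability of a complication-free catheterization."""
        return 1.0 - self.p_any_complication


def arterial_share(params: StrategyParams) -> float:
    """Fraction of complications that are arterial punctures.

    Estimated as the ratio of the per-attempt arterial puncture probability
    to the first-attempt total complication probability, clamped to [0, 1].
    """
    c_bar = params.c1.mean
    if c_bar <= 0.0:
        return 0.0
    return min(max(params.arterial.mean / c_bar, 0.0), 1.0)


def attribute_cost(params: StrategyParams, w_arterial: float | None = None) -> float:
    """Expected € cost of one complication episode.

    A complication is an arterial puncture with probability ``w_arterial``
    (default: :func:`arterial_share`) and otherwise one of the nine pooled
    complications mixed by ``other_complication_weights``.
    """
    if w_arterial is None:
        w_arterial = arterial_share(params)
    if not 0.0 <= w_arterial <= 1.0:
        raise ValueError(f"w_arterial {w_arterial} outside [0, 1]")
    other = sum(
        w * params.cost_map[name].mean_cost
        for name, w in params.other_complication_weights.items()
    )
    return (
        w_arterial * params.cost_map["arterial puncture"].mean_cost
        + (1.0 - w_arterial) * other
    )


def build_tree(params: StrategyParams, cost_scale: float = 1.0) -> ChanceNode:
    """Build the three-attempt tree for one strategy.

    ``cost_scale`` multiplies every accrued complication cost; it exists as a
    calibration hook for the cost side and never affects the effect side.
    """
    if cost_scale < 0.0:
        raise ValueError("cost_scale must be nonnegative")
    unit_cost = attribute_cost(params) * cost_scale
    c = [params.c1.mean, params.c2.mean, params.c3.mean]
    f = [params.f1.mean, params.f2.mean]

    def leaf(n_compl: int) -> Terminal:
        return Terminal(cost=n_compl * unit_cost, event=int(n_compl > 0))

    def attempt(k: int, n_compl: int) -> ChanceNode:
        # Complication split, then (attempts 1-2) failure split.
        ck = c[k - 1]

        def after_complication(n: int) -> Union[ChanceNode, Terminal]:
            if k == 3:
                return leaf(n)
            fk = f[k - 1]
            return ChanceNode(
                label=f"attempt {k} outcome",
                branches=(
                    (fk, attempt(k + 1, n)),
                    (1.0 - fk, leaf(n)),
                ),
            )

        return ChanceNode(
            label=f"attempt {k} complication",
            branches=(
                (ck, after_complication(n_compl + 1)),
                (1.0 - ck, after_complication(n_compl)),
            ),
        )

    return attempt(1, 0)


def evaluate(tree: ChanceNode, strategy: str = "") -> StrategyResult:
    """Expected-value rollback over all terminal paths."""
    expected_cost = 0.0
    p_any = 0.0
    stack: list[tuple[float, Union[ChanceNode, Terminal]]] = [(1.0, tree)]
    while stack:
        prob, node = stack.pop()
        if isinstance(node, Terminal):
            expected_cost += prob * node.cost
            p_any += prob * node.event
        else:
            for p, child in node.branches:
                if p > 0.0:
                    stack.append((prob * p, child))
    return StrategyResult(
        strategy=strategy,
        expected_cost=expected_cost,
        p_any_complication=min(p_any, 1.0),
    )


def evaluate_strategy(params: StrategyParams, cost_scale: float = 1.0) -> StrategyResult:
    """Build and evaluate the tree for one parameter set."""
    result = evaluate(build_tree(params, cost_scale=cost_scale), strategy=params.strategy)
    return result


def p_any_complication_closed_form(params: StrategyParams) -> float:
    """Closed-form per-person probability of at least one complication.

    The complement multiplies the no-complication probabilities along the
    attempt sequence, weighting by the failure probabilities that determine
    how far a patient progresses::

        p_no = (1-c1) * [(1-f1) + f1*(1-c2)*((1-f2) + f2*(1-c3))]
    """
    c1, c2, c3 = params.c1.mean, params.c2.mean, params.c3.mean
    f1, f2 = params.f1.mean, params.f2.mean
    p_no = (1.0 - c1) * ((1.0 - f1) + f1 * (1.0 - c2) * ((1.0 - f2) + f2 * (1.0 - c3)))
    return 1.0 - p_no


def expected_complications_closed_form(params: StrategyParams) -> float:
    """Expected number of complication episodes per patient.

    ``c1 + f1*c2 + f1*f2*c3`` — each attempt contributes its complication
    probability weighted by the probability of reaching it.
    """
    return (
        params.c1.mean
        + params.f1.mean * params.c2.mean
        + params.f1.mean * params.f2.mean * params.c3.mean
    )


def tree_to_json(tree: Union[ChanceNode, Terminal], indent: int | None = 2) -> str:
    """Serialize a tree to JSON for inspection or cross-tool comparison."""

    def encode(node: Union[ChanceNode, Terminal]) -> dict:
        if isinstance(node, Terminal):
            return {"type": "terminal", "cost": node.cost, "event": node.event}
        return {
            "type": "chance",
            "label": node.label,
            "branches": [
                {"probability": p, "child": encode(child)} for p, child in node.branches
            ],
        }

    return json.dumps(encode(tree), indent=indent)
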