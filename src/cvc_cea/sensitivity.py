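"""Deterministic and probabilistic sensitivity analysis.

One-way (deterministic) analysis re-evaluates the model with each input at
its lower and upper bound — confidence limits for probabilities, ±50% for
costs — and ranks parameters tornado-style by the span of their influence.
The probabilistic analysis samples every probability from its moment-matched
beta distribution and every cost from its gamma distribution, re-evaluating
both strategies per Monte Carlo iteration. A threshold analysis reports the
per-procedure intervention cost at which the cost saving is exhausted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cea import compare
from .decision_tree import evaluate_strategy
from .parameters import CostParam, ProbabilityParam, StrategyParams

__all__ = [
    "DSAEntry",
    "PSAResult",
    "one_way_dsa",
    "run_psa",
    "threshold_intervention_cost",
]


@dataclass(frozen=True)
class DSAEntry:
    """One-way sensitivity result for a single parameter.

    ``span`` is the absolute change in the ranking metric between the two
    bounds; ``pct_of_base`` expresses it relative to the base-case value of
    that metric (tornado annotation).
    """

    parameter: str
    low: float
    high: float
    delta_cost_at_low: float
    delta_cost_at_high: float
    delta_effect_at_low: float
    delta_effect_at_high: float
    span_cost: float
    span_effect: float
    span: float
    pct_of_base: float


def _point(name: str, value: float) -> ProbabilityParam:
    """Degenerate probability parameter fixed at one value (DSA bound)."""
    if not 0.0 <= value <= 1.0:
        warnings.warn(
            f"{name}: bound {value} outside [0, 1], clamped", stacklevel=3
        )
        value = min(max(value, 0.0), 1.0)
    return ProbabilityParam(name, value, value, value)


def _deltas(ug: StrategyParams, lm: StrategyParams, cost_scale: float) -> tuple[float, float]:
    res = compare(
        evaluate_strategy(ug, cost_scale=cost_scale),
        evaluate_strategy(lm, cost_scale=cost_scale),
    )
    return res.delta_cost, res.delta_effect


def one_way_dsa(
    ug: StrategyParams,
    lm: StrategyParams,
    metric: str = "delta_cost",
    cost_scale: float = 1.0,
) -> list[DSAEntry]:
    """Univariate deterministic sensitivity analysis over all inputs.

    Probability parameters (six per strategy) are varied over their 95%
    confidence limits; each complication cost is varied over its ``low``/
    ``high`` range (±50% of the mean by default) simultaneously in both
    strategies, since unit costs are shared. All other inputs stay at base.

    Because the base-case verdict is dominance — an ICER ratio has no
    stable sign — entries are ranked by the span of the incremental cost
    (``metric="delta_cost"``) or incremental effect (``"delta_effect"``),
    ties broken alphabetically.
    """
    if metric not in ("delta_cost", "delta_effect"):
        raise ValueError(f"unknown metric {metric!r}")
    base_cost, base_effect = _deltas(ug, lm, cost_scale)
    base_value = base_cost if metric == "delta_cost" else base_effect

    entries: list[DSAEntry] = []

    def record(name: str, low: float, high: float, at_low, at_high) -> None:
        span_cost = abs(at_high[0] - at_low[0])
        span_effect = abs(at_high[1] - at_low[1])
        span = span_cost if metric == "delta_cost" else span_effect
        pct = abs(span / base_value) * 100.0 if base_value != 0.0 else np.inf
        entries.append(
            DSAEntry(
                parameter=name,
                low=low,
                high=high,
                delta_cost_at_low=at_low[0],
                delta_cost_at_high=at_high[0],
                delta_effect_at_low=at_low[1],
                delta_effect_at_high=at_high[1],
                span_cost=span_cost,
                span_effect=span_effect,
                span=span,
                pct_of_base=pct,
            )
        )

    # Clinical probabilities, per strategy, varied over their 95% CIs.
    for arm, other in ((ug, lm), (lm, ug)):
        for key, p in arm.probabilities.items():
            name = f"{arm.strategy}.{key}"
            varied_low = arm.with_probability(key, _point(name, p.ci_low))
            varied_high = arm.with_probability(key, _point(name, p.ci_high))
            if arm is ug:
                at_low = _deltas(varied_low, lm, cost_scale)
                at_high = _deltas(varied_high, lm, cost_scale)
            else:
                at_low = _deltas(ug, varied_low, cost_scale)
                at_high = _deltas(ug, varied_high, cost_scale)
            record(name, p.ci_low, p.ci_high, at_low, at_high)

    # Unit costs, shared by both strategies, varied over low/high (±50%).
    for cname, cp in ug.cost_map.items():
        name = f"cost.{cname}"

        def with_cost(value: float) -> tuple[StrategyParams, StrategyParams]:
            new = CostParam(cname, value, low=value, high=value, se_frac=cp.se_frac)
            return ug.with_cost(cname, new), lm.with_cost(cname, new)

        at_low = _deltas(*with_cost(cp.low), cost_scale)
        at_high = _deltas(*with_cost(cp.high), cost_scale)
        record(name, cp.low, cp.high, at_low, at_high)

    entries.sort(key=lambda e: (-e.span, e.parameter))
    return entries


def dsa_table(entries: list[DSAEntry]) -> pd.DataFrame:
    """Tornado-ordered table of one-way sensitivity results."""
    return pd.DataFrame([e.__dict__ for e in entries])


@dataclass
class PSAResult:
    """Probabilistic sensitivity analysis output.

    ``draws`` holds one row per Monte Carlo iteration with per-strategy
    costs and effectiveness plus the incremental quantities;
    ``dominance_fraction`` is the proportion of iterations in which the
    intervention is both cheaper and more effective. Percentiles use the
    inclusive linear-interpolation definition (recorded in ``metadata``).
    """

    iterations: int
    seed: int
    draws: pd.DataFrame
    dominance_fraction: float
    metadata: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        q = self.draws.quantile([0.025, 0.975], interpolation="linear")
        out = pd.DataFrame(
            {
                "mean": self.draws.mean(),
                "p2.5": q.loc[0.025],
                "p97.5": q.loc[0.975],
            }
        )
        return out

    def percentile(self, column: str, q: float) -> float:
        return float(self.draws[column].quantile(q / 100.0, interpolation="linear"))

    def write_scatter_csv(self, path: str | Path) -> None:
        """Per-iteration (delta_cost, delta_effect) for CE-plane plotting."""
        self.draws[["delta_cost", "delta_effect"]].to_csv(path, index=False)


def _draw_probability(
    rng: np.random.Generator, p: ProbabilityParam, n: int, se_scale: float
) -> np.ndarray:
    """Beta draws moment-matched to a probability parameter.

    A degenerate parameter (zero CI width) or a zero ``se_scale`` collapses
    to the point estimate, which makes the PSA reproduce the base case.
    """
    se = p.se * se_scale
    if se <= 0.0 or not 0.0 < p.mean < 1.0:
        return np.full(n, p.mean)
    var = se * se
    bound = p.mean * (1.0 - p.mean)
    if var >= bound:
        raise ValueError(
            f"{p.name}: se {se} too large for a beta distribution "
            f"(variance bound {bound})"
        )
    nu = bound / var - 1.0
    return rng.beta(p.mean * nu, (1.0 - p.mean) * nu, size=n)


def _draw_cost(
    rng: np.random.Generator, cp: CostParam, n: int, se_scale: float
) -> np.ndarray:
    se = cp.se_frac * cp.mean_cost * se_scale
    if se <= 0.0 or cp.mean_cost <= 0.0:
        return np.full(n, cp.mean_cost)
    shape = (cp.mean_cost / se) ** 2
    scale = se * se / cp.mean_cost
    return rng.gamma(shape, scale, size=n)


def _evaluate_draws(
    params: StrategyParams,
    probs: dict[str, np.ndarray],
    costs: dict[str, np.ndarray],
    cost_scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tree evaluation for sampled parameter vectors.

    Uses the closed-form identities that the test suite verifies against
    the explicit tree rollback: the complication-free probability factors
    over attempts, and expected cost is the expected number of complication
    episodes times the expected cost per episode.
    """
    c1, c2, c3 = probs["c1"], probs["c2"], probs["c3"]
    f1, f2 = probs["f1"], probs["f2"]
    arterial = probs["arterial"]

    p_no = (1.0 - c1) * ((1.0 - f1) + f1 * (1.0 - c2) * ((1.0 - f2) + f2 * (1.0 - c3)))
    p_any = 1.0 - p_no

    expected_episodes = c1 + f1 * c2 + f1 * f2 * c3
    with np.errstate(divide="ignore", invalid="ignore"):
        w_a = np.where(c1 > 0.0, np.clip(arterial / c1, 0.0, 1.0), 0.0)
    other = sum(
        w * costs[name] for name, w in params.other_complication_weights.items()
    )
    unit = w_a * costs["arterial puncture"] + (1.0 - w_a) * other
    return expected_episodes * unit * cost_scale, p_any


def run_psa(
    ug: StrategyParams,
    lm: StrategyParams,
    iterations: int = 10_000,
    seed: int = 0,
    se_scale: float = 1.0,
    cost_scale: float = 1.0,
) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Every clinical probability of both strategies is drawn independently
    from its beta distribution and every unit cost (shared across
    strategies) from its gamma distribution; both trees are re-evaluated
    per iteration. ``se_scale`` multiplies all standard errors (useful for
    convergence checks); draws are deterministic given ``seed``.
    """
    if iterations < 1:
        raise ValueError("iterations must be at least 1")
    rng = np.random.Generator(np.random.Philox(seed))

    draws = {}
    for arm in (ug, lm):
        probs = {
            key: _draw_probability(rng, p, iterations, se_scale)
            for key, p in arm.probabilities.items()
        }
        draws[arm.strategy] = probs
    costs = {
        name: _draw_cost(rng, cp, iterations, se_scale)
        for name, cp in ug.cost_map.items()
    }

    cost_ug, p_any_ug = _evaluate_draws(ug, draws[ug.strategy], costs, cost_scale)
    cost_lm, p_any_lm = _evaluate_draws(lm, draws[lm.strategy], costs, cost_scale)

    frame = pd.DataFrame(
        {
            "cost_ug": cost_ug,
            "cost_lm": cost_lm,
            "effect_ug": 1.0 - p_any_ug,
            "effect_lm": 1.0 - p_any_lm,
            "delta_cost": cost_ug - cost_lm,
            "delta_effect": p_any_lm - p_any_ug,
        }
    )
    dominance = float(((frame.delta_cost < 0.0) & (frame.delta_effect > 0.0)).mean())
    return PSAResult(
        iterations=iterations,
        seed=seed,
        draws=frame,
        dominance_fraction=dominance,
        metadata={
            "percentile_method": "linear interpolation (inclusive)",
            "se_scale": se_scale,
            "cost_se_fraction": ug.cost_map["arterial puncture"].se_frac,
        },
    )


def threshold_intervention_cost(delta_cost_base: float) -> float:
    """Break-even per-procedure intervention cost.

    When the intervention currently saves ``-delta_cost_base`` euros per
    procedure, an intervention cost of exactly that amount added to the
    intervention arm brings the incremental cost to zero. Expected cost is
    linear in an additive per-procedure cost, so the threshold is simply
    the negated base-case incremental cost.
    """
    if delta_cost_base >= 0.0:
        if delta_cost_base > 0.0:
            warnings.warn(
                "intervention is not cost saving at base case; threshold is 0",
                stacklevel=2,
            )
        return 0.0
    return -delta_cost_base
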