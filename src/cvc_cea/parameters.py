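"""Model inputs and parameter transformations.

Holds the clinical branch probabilities (with 95% CIs) and per-complication
costs of the three-attempt central venous catheterization model, together
with the transformations used to derive standard errors and the moment-matched
beta/gamma distributions sampled in probabilistic sensitivity analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

__all__ = [
    "ProbabilityParam",
    "CostParam",
    "StrategyParams",
    "BudgetContext",
    "OTHER_COMPLICATIONS",
    "ci_to_se",
    "beta_from_moments",
    "gamma_from_moments",
    "rate_to_probability",
    "apply_odds_ratio",
    "default_parameters",
    "load_parameters",
]

#: Names of the nine complications pooled into the composite
#: "other complications" endpoint (everything except arterial puncture).
OTHER_COMPLICATIONS: tuple[str, ...] = (
    "thrombosis",
    "embolism",
    "hydromediastinum",
    "hematomediastinum",
    "hematothorax",
    "hydrothorax",
    "pneumothorax",
    "nerve injury",
    "subcutaneous emphysema",
)


def ci_to_se(ci_low: float, ci_high: float) -> float:
    """Standard error implied by a 95% confidence interval.

    Uses the normal approximation: a symmetric 95% CI spans
    ``2 * 1.96 = 3.92`` standard errors.

    Parameters
    ----------
    ci_low, ci_high : float
        Lower and upper confidence limits.

    Returns
    -------
    float
        ``(ci_high - ci_low) / 3.92``. Zero for a degenerate interval.
    """
    if ci_high < ci_low:
        raise ValueError(f"CI upper limit {ci_high} below lower limit {ci_low}")
    return (ci_high - ci_low) / 3.92


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta distribution parameters.

    Solves for ``(alpha, beta)`` such that ``Beta(alpha, beta)`` has the
    given mean and standard deviation.

    Raises
    ------
    ValueError
        If the mean is not strictly inside (0, 1) or the variance is not
        strictly between 0 and ``mean * (1 - mean)`` (outside that range no
        beta distribution exists).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must be in (0, 1), got {mean}")
    var = se * se
    if var <= 0.0:
        raise ValueError(f"se must be positive, got {se}")
    bound = mean * (1.0 - mean)
    if var >= bound:
        raise ValueError(
            f"variance {var} exceeds beta bound mean*(1-mean) = {bound}"
        )
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma ``(shape, scale)`` for a cost parameter.

    ``shape = (mean/se)**2`` and ``scale = se**2 / mean``, so the gamma
    distribution reproduces the requested mean and variance exactly.
    """
    if mean <= 0.0:
        raise ValueError(f"mean must be positive, got {mean}")
    if se <= 0.0:
        raise ValueError(f"se must be positive, got {se}")
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


def rate_to_probability(rate: float, horizon: float = 1.0) -> float:
    """Convert a constant event rate to a probability over a time horizon.

    Assumes exponentially distributed waiting times:
    ``p = 1 - exp(-rate * horizon)``.
    """
    if rate < 0.0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    if horizon <= 0.0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    return 1.0 - math.exp(-rate * horizon)


def apply_odds_ratio(p_base: float, odds_ratio: float) -> float:
    """Apply an odds ratio to a baseline probability.

    The reported escalation of complication risk with repeated puncture
    attempts is expressed as odds ratios (8.4 for the second attempt, 35.6
    for the third, relative to the first). This converts the baseline
    probability to odds, multiplies, and converts back:
    ``p' = OR*odds / (1 + OR*odds)`` with ``odds = p/(1-p)``.

    Note that the published per-attempt complication probabilities are used
    verbatim as model defaults; this transformation is provided for
    user-defined scenarios where only a first-attempt probability is known.
    """
    if not 0.0 <= p_base < 1.0:
        raise ValueError(f"p_base must be in [0, 1), got {p_base}")
    if odds_ratio <= 0.0:
        raise ValueError(f"odds_ratio must be positive, got {odds_ratio}")
    odds = p_base / (1.0 - p_base)
    scaled = odds_ratio * odds
    return scaled / (1.0 + scaled)


@dataclass(frozen=True)
class ProbabilityParam:
    """A branch probability with its 95% CI and derived uncertainty.

    ``se`` defaults to the normal-approximation value from the CI width, and
    ``alpha``/``beta`` to the moment-matched beta shape parameters (``nan``
    when the interval is degenerate and no spread information exists).
    """

    name: str
    mean: float
    ci_low: float
    ci_high: float
    se: float = field(default=None)  # type: ignore[assignment]
    alpha: float = field(default=None)  # type: ignore[assignment]
    beta: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.mean <= self.ci_high <= 1.0:
            raise ValueError(
                f"{self.name}: require 0 <= ci_low <= mean <= ci_high <= 1, "
                f"got ({self.ci_low}, {self.mean}, {self.ci_high})"
            )
        if self.se is None:
            object.__setattr__(self, "se", ci_to_se(self.ci_low, self.ci_high))
        if self.alpha is None:
            if self.se > 0.0 and 0.0 < self.mean < 1.0:
                a, b = beta_from_moments(self.mean, self.se)
            else:
                a, b = math.nan, math.nan
            object.__setattr__(self, "alpha", a)
            object.__setattr__(self, "beta", b)

    def scaled(self, multiplier: float, clamp: float = 0.999) -> "ProbabilityParam":
        """Return a copy with mean and CI scaled by ``multiplier`` (clamped)."""
        if multiplier <= 0.0:
            raise ValueError(f"multiplier must be positive, got {multiplier}")
        m = min(self.mean * multiplier, clamp)
        lo = min(self.ci_low * multiplier, m)
        hi = min(self.ci_high * multiplier, clamp)
        return ProbabilityParam(self.name, m, lo, max(hi, m))


@dataclass(frozen=True)
class CostParam:
    """A per-complication cost in € with its sensitivity-analysis range.

    ``low``/``high`` default to ±50% of the mean (the deterministic
    sensitivity range used when no sampling uncertainty is available) and
    the gamma ``shape``/``scale`` are moment-matched with
    ``se = se_frac * mean``.
    """

    name: str
    mean_cost: float
    low: float = field(default=None)  # type: ignore[assignment]
    high: float = field(default=None)  # type: ignore[assignment]
    se_frac: float = 0.25
    shape: float = field(default=None)  # type: ignore[assignment]
    scale: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mean_cost < 0.0:
            raise ValueError(f"{self.name}: cost must be nonnegative")
        if self.low is None:
            object.__setattr__(self, "low", 0.5 * self.mean_cost)
        if self.high is None:
            object.__setattr__(self, "high", 1.5 * self.mean_cost)
        if not self.low <= self.mean_cost <= self.high:
            raise ValueError(
                f"{self.name}: require low <= mean <= high, got "
                f"({self.low}, {self.mean_cost}, {self.high})"
            )
        if self.shape is None:
            if self.mean_cost > 0.0 and self.se_frac > 0.0:
                sh, sc = gamma_from_moments(self.mean_cost, self.se_frac * self.mean_cost)
            else:
                sh, sc = math.nan, math.nan
            object.__setattr__(self, "shape", sh)
            object.__setattr__(self, "scale", sc)


@dataclass(frozen=True)
class StrategyParams:
    """Full parameter set for one catheterization strategy (UG or LM).

    Attributes
    ----------
    strategy : str
        ``"UG"`` (ultrasound guidance) or ``"LM"`` (landmark method).
    f1, f2 : ProbabilityParam
        Probability of a failed cannulation on the first / second attempt.
    c1, c2, c3 : ProbabilityParam
        Probability of any catheter-related complication on attempt 1/2/3.
    arterial : ProbabilityParam
        Per-attempt probability of an arterial puncture.
    cost_map : dict[str, CostParam]
        € cost per complication episode, keyed by complication name.
    other_complication_weights : dict[str, float]
        Mix of the nine non-arterial complications within the composite
        endpoint; must sum to 1.
    """

    strategy: str
    f1: ProbabilityParam
    f2: ProbabilityParam
    c1: ProbabilityParam
    c2: ProbabilityParam
    c3: ProbabilityParam
    arterial: ProbabilityParam
    cost_map: dict[str, CostParam]
    other_complication_weights: dict[str, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.other_complication_weights is None:
            w = 1.0 / len(OTHER_COMPLICATIONS)
            object.__setattr__(
                self,
                "other_complication_weights",
                {name: w for name in OTHER_COMPLICATIONS},
            )
        weights = self.other_complication_weights
        if any(v < 0.0 for v in weights.values()):
            raise ValueError("other_complication_weights must be nonnegative")
        total = sum(weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"other_complication_weights sum to {total}, expected 1")
        missing = set(weights) - set(self.cost_map)
        if missing:
            raise ValueError(f"weights refer to unknown complications: {missing}")

    @property
    def probabilities(self) -> dict[str, ProbabilityParam]:
        """The six clinical probabilities keyed by short name."""
        return {
            "f1": self.f1,
            "f2": self.f2,
            "c1": self.c1,
            "c2": self.c2,
            "c3": self.c3,
            "arterial": self.arterial,
        }

    def with_probability(self, key: str, value: ProbabilityParam) -> "StrategyParams":
        """Return a copy with one clinical probability replaced."""
        if key not in self.probabilities:
            raise KeyError(key)
        return replace(self, **{key: value})

    def with_cost(self, name: str, value: CostParam) -> "StrategyParams":
        """Return a copy with one complication cost replaced."""
        if name not in self.cost_map:
            raise KeyError(name)
        new_map = dict(self.cost_map)
        new_map[name] = value
        return replace(self, cost_map=new_map)


@dataclass(frozen=True)
class BudgetContext:
    """Inputs of the annual payer-level budget impact projection."""

    annual_catheters: int
    adoption_low: float
    adoption_high: float
    incremental_cost: float
    incremental_effect: float

    def __post_init__(self) -> None:
        if self.annual_catheters <= 0:
            raise ValueError("annual_catheters must be positive")
        if not 0.0 <= self.adoption_low <= self.adoption_high <= 1.0:
            raise ValueError("require 0 <= adoption_low <= adoption_high <= 1")


# Published clinical inputs: mean [95% CI] per strategy.
_UG_PROBS = {
    "f1": (0.164, 0.143, 0.183),
    "f2": (0.049, 0.031, 0.067),
    "c1": (0.029, 0.019, 0.040),
    "c2": (0.041, 0.029, 0.053),
    "c3": (0.047, 0.034, 0.059),
    "arterial": (0.015, 0.010, 0.021),
}
_LM_PROBS = {
    "f1": (0.376, 0.356, 0.395),
    "f2": (0.166, 0.138, 0.193),
    "c1": (0.114, 0.096, 0.132),
    "c2": (0.156, 0.136, 0.176),
    "c3": (0.177, 0.156, 0.197),
    "arterial": (0.081, 0.069, 0.093),
}

# € per complication episode (statutory health insurance perspective,
# DRG-difference estimates, €2016).
_COSTS = {
    "arterial puncture": 94.0,
    "thrombosis": 131.0,
    "embolism": 131.0,
    "hydromediastinum": 133.0,
    "hematomediastinum": 94.0,
    "hematothorax": 177.0,
    "hydrothorax": 217.0,
    "pneumothorax": 178.0,
    "nerve injury": 347.0,
    "subcutaneous emphysema": 16.0,
}

# Base-case incremental cost of ultrasound guidance vs landmark (€/person,
# published figure; negative = cost saving) used in the budget projection.
DEFAULT_INCREMENTAL_COST = -179.0

_ANNUAL_CATHETERS = 568_000
_ADOPTION = (0.10, 0.20)


def _strategy(name: str, probs: dict, cost_se_frac: float = 0.25) -> StrategyParams:
    pp = {
        key: ProbabilityParam(f"{name}_{key}", mean, lo, hi)
        for key, (mean, lo, hi) in probs.items()
    }
    cost_map = {
        cname: CostParam(cname, c, se_frac=cost_se_frac) for cname, c in _COSTS.items()
    }
    return StrategyParams(strategy=name, cost_map=cost_map, **pp)


def default_parameters(
    incremental_effect: float | None = None,
) -> tuple[StrategyParams, StrategyParams, BudgetContext]:
    """Return the embedded base-case inputs.

    Returns the ultrasound-guidance and landmark parameter sets with the
    published probabilities, CIs and complication costs, plus the budget
    impact context (568,000 catheterizations/year, 10–20% adoption, €−179
    incremental cost per procedure).

    Parameters
    ----------
    incremental_effect : float, optional
        Averted complications per person for the budget context. When omitted
        it is computed from the base-case decision tree.
    """
    ug = _strategy("UG", _UG_PROBS)
    lm = _strategy("LM", _LM_PROBS)
    if incremental_effect is None:
        from .decision_tree import p_any_complication_closed_form

        incremental_effect = p_any_complication_closed_form(
            lm
        ) - p_any_complication_closed_form(ug)
    ctx = BudgetContext(
        annual_catheters=_ANNUAL_CATHETERS,
        adoption_low=_ADOPTION[0],
        adoption_high=_ADOPTION[1],
        incremental_cost=DEFAULT_INCREMENTAL_COST,
        incremental_effect=incremental_effect,
    )
    return ug, lm, ctx


def load_parameters(
    path: str | Path,
) -> tuple[StrategyParams, StrategyParams, BudgetContext]:
    """Load a full parameter set from a YAML or JSON file.

    Expected layout::

        strategies:
          ug:
            f1: {mean: 0.164, ci_low: 0.143, ci_high: 0.183}
            ...
          lm:
            ...
        costs:
          arterial puncture: {mean: 94}          # low/high optional
          ...
        budget:
          annual_catheters: 568000
          adoption_low: 0.10
          adoption_high: 0.20
          incremental_cost: -179                 # optional
        weights:                                  # optional
          pneumothorax: 0.2
          ...

    Any omitted section falls back to the embedded defaults.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    data = data or {}

    ug_def, lm_def, ctx_def = default_parameters()

    costs_cfg = data.get("costs", {})
    cost_map = dict(ug_def.cost_map)
    for cname, spec in costs_cfg.items():
        cost_map[cname] = CostParam(
            cname,
            float(spec["mean"]),
            low=float(spec["low"]) if "low" in spec else None,
            high=float(spec["high"]) if "high" in spec else None,
        )

    weights = data.get("weights")
    if weights is not None:
        weights = {k: float(v) for k, v in weights.items()}

    def build(label: str, base: StrategyParams) -> StrategyParams:
        cfg = data.get("strategies", {}).get(label.lower(), {})
        probs = {}
        for key, default in base.probabilities.items():
            spec = cfg.get(key)
            if spec is None:
                probs[key] = default
            else:
                probs[key] = ProbabilityParam(
                    f"{label}_{key}",
                    float(spec["mean"]),
                    float(spec.get("ci_low", spec["mean"])),
                    float(spec.get("ci_high", spec["mean"])),
                )
        return StrategyParams(
            strategy=label,
            cost_map=cost_map,
            other_complication_weights=weights,
            **probs,
        )

    budget_cfg = data.get("budget", {})
    ctx = BudgetContext(
        annual_catheters=int(budget_cfg.get("annual_catheters", ctx_def.annual_catheters)),
        adoption_low=float(budget_cfg.get("adoption_low", ctx_def.adoption_low)),
        adoption_high=float(budget_cfg.get("adoption_high", ctx_def.adoption_high)),
        incremental_cost=float(budget_cfg.get("incremental_cost", ctx_def.incremental_cost)),
        incremental_effect=float(
            budget_cfg.get("incremental_effect", ctx_def.incremental_effect)
        ),
    )
    return build("UG", ug_def), build("LM", lm_def), ctx
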