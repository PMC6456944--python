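"""Patient-level microsimulation and synthetic trial generation.

This module serves two purposes. First, it is an independent oracle for the
analytic decision tree: cohorts of simulated patients are pushed through the
same three-attempt pathway with Bernoulli draws, so empirical complication
probabilities and costs must converge to the tree's closed-form values.
Second, it regenerates trial-like event tables from which the clinical input
probabilities and their 95% CIs can be re-estimated, closing the loop from
raw events to model inputs without any external data.

Randomness uses a counter-based Philox stream keyed on the root seed; every
patient owns a fixed-width row of uniforms, so cohorts are reproducible and
each patient's outcome is independent of cohort ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .decision_tree import arterial_share
from .parameters import OTHER_COMPLICATIONS, CostParam, ProbabilityParam, StrategyParams

__all__ = [
    "PatientRecord",
    "Cohort",
    "SyntheticTrial",
    "simulate_cohort",
    "simulate_trial",
    "trial_from_cohort",
    "estimate_params",
]

# Fixed uniform layout per patient: complication/failure draws for each
# attempt plus a complication-type draw per attempt.
_N_DRAWS = 8
_COL_C1, _COL_F1, _COL_C2, _COL_F2, _COL_C3, _COL_T1, _COL_T2, _COL_T3 = range(_N_DRAWS)


@dataclass(frozen=True)
class PatientRecord:
    """One simulated catheterization episode.

    ``complications`` lists ``(attempt_index, type_name)`` pairs for every
    attempt on which a complication occurred. The third attempt is
    absorbing: its success is not modelled separately, so ``success`` is 1
    for every pathway that terminates.
    """

    patient_id: int
    attempts_used: int
    success: int
    complications: tuple[tuple[int, str], ...]
    total_cost: float

    def __post_init__(self) -> None:
        if not 1 <= self.attempts_used <= 3:
            raise ValueError("attempts_used must be 1, 2 or 3")
        for attempt, _name in self.complications:
            if attempt > self.attempts_used:
                raise ValueError("complication on an attempt never reached")


class Cohort:
    """A simulated patient cohort stored as column arrays.

    Scalar summaries (:meth:`p_any_complication`, :meth:`mean_cost`) are the
    quantities compared against the analytic tree; :meth:`to_dataframe` and
    :meth:`write_csv` expose the patient-level data.
    """

    def __init__(
        self,
        params: StrategyParams,
        reached: np.ndarray,
        complication: np.ndarray,
        type_index: np.ndarray,
        type_names: list[str],
        cost_per_type: np.ndarray,
    ) -> None:
        self.params = params
        self._reached = reached  # (n, 3) bool
        self._complication = complication  # (n, 3) bool, only where reached
        self._type_index = type_index  # (n, 3) int, -1 where no complication
        self._type_names = type_names
        self._cost_per_type = cost_per_type

    def __len__(self) -> int:
        return self._reached.shape[0]

    @property
    def attempts_used(self) -> np.ndarray:
        return self._reached.sum(axis=1)

    @property
    def n_complications(self) -> np.ndarray:
        return self._complication.sum(axis=1)

    @property
    def any_complication(self) -> np.ndarray:
        return self._complication.any(axis=1)

    @property
    def total_cost(self) -> np.ndarray:
        costs = np.where(
            self._complication, self._cost_per_type[self._type_index], 0.0
        )
        return costs.sum(axis=1)

    def p_any_complication(self) -> float:
        return float(self.any_complication.mean())

    def mean_cost(self) -> float:
        return float(self.total_cost.mean())

    def records(self) -> Iterator[PatientRecord]:
        total_cost = self.total_cost
        attempts = self.attempts_used
        for i in range(len(self)):
            compl = tuple(
                (k + 1, self._type_names[self._type_index[i, k]])
                for k in range(3)
                if self._complication[i, k]
            )
            yield PatientRecord(
                patient_id=i,
                attempts_used=int(attempts[i]),
                success=1,
                complications=compl,
                total_cost=float(total_cost[i]),
            )

    def to_dataframe(self) -> pd.DataFrame:
        type_of = np.array(self._type_names + [""], dtype=object)
        frame = {"patient_id": np.arange(len(self)), "attempts_used": self.attempts_used}
        for k in range(3):
            idx = np.where(self._complication[:, k], self._type_index[:, k], -1)
            frame[f"complication_attempt{k + 1}"] = type_of[idx]
        frame["n_complications"] = self.n_complications
        frame["total_cost"] = self.total_cost
        return pd.DataFrame(frame)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _type_distribution(params: StrategyParams) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Complication-type categories, probabilities and unit costs.

    Category 0 is arterial puncture with probability ``arterial_share``;
    the rest follow ``other_complication_weights``, keeping the sampled
    expected cost per episode identical to :func:`attribute_cost`.
    """
    w_a = arterial_share(params)
    names = ["arterial puncture"] + list(OTHER_COMPLICATIONS)
    probs = np.array(
        [w_a]
        + [(1.0 - w_a) * params.other_complication_weights[n] for n in OTHER_COMPLICATIONS]
    )
    costs = np.array([params.cost_map[n].mean_cost for n in names])
    return names, probs, costs


def simulate_cohort(
    params: StrategyParams, n: int, seed: int, cost_scale: float = 1.0
) -> Cohort:
    """Simulate ``n`` independent patients through the three-attempt pathway.

    Per attempt reached, a complication is drawn as Bernoulli(``c_k``) and —
    on attempts 1 and 2 — failure as Bernoulli(``f_k``); failures proceed to
    the next attempt. Complication types are drawn from the arterial/other
    mix so that expected cost per episode matches the analytic tree.
    """
    if n < 1:
        raise ValueError(f"cohort size must be at least 1, got {n}")
    if seed < 0:
        raise ValueError("seed must be nonnegative")
    rng = np.random.Generator(np.random.Philox(seed))
    u = rng.random((n, _N_DRAWS))

    fail1 = u[:, _COL_F1] < params.f1.mean
    fail2 = fail1 & (u[:, _COL_F2] < params.f2.mean)
    reached = np.column_stack([np.ones(n, dtype=bool), fail1, fail2])

    comp = np.column_stack(
        [
            u[:, _COL_C1] < params.c1.mean,
            fail1 & (u[:, _COL_C2] < params.c2.mean),
            fail2 & (u[:, _COL_C3] < params.c3.mean),
        ]
    )

    names, type_probs, type_costs = _type_distribution(params)
    edges = np.cumsum(type_probs)
    edges[-1] = 1.0  # guard against round-off at the top edge
    type_index = np.empty((n, 3), dtype=np.int64)
    for k, col in enumerate((_COL_T1, _COL_T2, _COL_T3)):
        type_index[:, k] = np.searchsorted(edges, u[:, col], side="right")
    type_index = np.minimum(type_index, len(names) - 1)
    type_index[~comp] = -1

    return Cohort(params, reached, comp, type_index, names, type_costs * cost_scale)


@dataclass(frozen=True)
class SyntheticTrial:
    """Aggregated event counts for one strategy arm.

    Denominators follow the pathway: first-attempt outcomes are out of
    ``n``; second-attempt outcomes out of ``n_reach2`` (first-attempt
    failures); third-attempt complications out of ``n_reach3``. Arterial
    punctures are counted on first attempts (out of ``n``), matching the
    per-attempt definition of the arterial probability.
    """

    arm: str
    n: int
    n_reach2: int
    n_reach3: int
    fail1: int
    fail2: int
    comp1: int
    comp2: int
    comp3: int
    arterial1: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("trial arm must contain patients")
        if not (self.n >= self.n_reach2 >= self.n_reach3 >= 0):
            raise ValueError("attempt denominators must be nested")
        checks = [
            (self.fail1, self.n),
            (self.comp1, self.n),
            (self.arterial1, self.n),
            (self.fail2, self.n_reach2),
            (self.comp2, self.n_reach2),
            (self.comp3, self.n_reach3),
        ]
        for count, denom in checks:
            if not 0 <= count <= denom:
                raise ValueError("event count exceeds its denominator")


def simulate_trial(params: StrategyParams, n: int, seed: int) -> SyntheticTrial:
    """Draw trial-arm event counts directly from nested binomials.

    Distributionally identical to aggregating :func:`simulate_cohort`
    (failures and complications are independent per attempt) but O(1) in
    ``n``, which makes repeated-replicate coverage studies cheap.
    """
    if n < 1:
        raise ValueError(f"trial size must be at least 1, got {n}")
    rng = np.random.Generator(np.random.Philox(seed))
    fail1 = int(rng.binomial(n, params.f1.mean))
    fail2 = int(rng.binomial(fail1, params.f2.mean)) if fail1 else 0
    comp1 = int(rng.binomial(n, params.c1.mean))
    comp2 = int(rng.binomial(fail1, params.c2.mean)) if fail1 else 0
    comp3 = int(rng.binomial(fail2, params.c3.mean)) if fail2 else 0
    arterial1 = int(rng.binomial(n, params.arterial.mean))
    return SyntheticTrial(
        arm=params.strategy,
        n=n,
        n_reach2=fail1,
        n_reach3=fail2,
        fail1=fail1,
        fail2=fail2,
        comp1=comp1,
        comp2=comp2,
        comp3=comp3,
        arterial1=arterial1,
    )


def trial_from_cohort(cohort: Cohort) -> SyntheticTrial:
    """Aggregate a simulated cohort into trial-arm event counts."""
    reached = cohort._reached
    comp = cohort._complication
    arterial_first = comp[:, 0] & (
        cohort._type_index[:, 0] == 0
    )  # type 0 is arterial puncture
    return SyntheticTrial(
        arm=cohort.params.strategy,
        n=len(cohort),
        n_reach2=int(reached[:, 1].sum()),
        n_reach3=int(reached[:, 2].sum()),
        fail1=int(reached[:, 1].sum()),
        fail2=int(reached[:, 2].sum()),
        comp1=int(comp[:, 0].sum()),
        comp2=int(comp[:, 1].sum()),
        comp3=int(comp[:, 2].sum()),
        arterial1=int(arterial_first.sum()),
    )


def _wilson_ci(count: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Wilson score 95% interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    phat = count / n
    z2 = z * z
    denom = 1.0 + z2 / n
    center = (phat + z2 / (2.0 * n)) / denom
    half = z * np.sqrt(phat * (1.0 - phat) / n + z2 / (4.0 * n * n)) / denom
    return max(center - half, 0.0), min(center + half, 1.0)


def _normal_ci(count: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    phat = count / n
    half = z * np.sqrt(phat * (1.0 - phat) / n)
    return max(phat - half, 0.0), min(phat + half, 1.0)


def estimate_params(
    trial: SyntheticTrial,
    cost_map: dict[str, CostParam] | None = None,
    ci_method: str = "wilson",
) -> StrategyParams:
    """Re-estimate the strategy's clinical probabilities from trial counts.

    Each probability is ``events / denominator`` with a 95% interval by the
    Wilson score method (default) or the normal approximation. Because the
    Wilson interval is asymmetric about the point estimate, the estimate is
    stored as the interval-consistent mean (clipped into the CI); the raw
    proportion is always within the interval.

    The interval method used is recorded in each parameter's name suffix.
    """
    if ci_method == "wilson":
        ci = _wilson_ci
    elif ci_method == "normal":
        ci = _normal_ci
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    if cost_map is None:
        from .parameters import default_parameters

        cost_map = default_parameters()[0].cost_map

    specs = {
        "f1": (trial.fail1, trial.n),
        "f2": (trial.fail2, trial.n_reach2),
        "c1": (trial.comp1, trial.n),
        "c2": (trial.comp2, trial.n_reach2),
        "c3": (trial.comp3, trial.n_reach3),
        "arterial": (trial.arterial1, trial.n),
    }
    probs = {}
    for key, (count, denom) in specs.items():
        if denom <= 0:
            raise ValueError(f"{key}: zero denominator, cannot estimate")
        lo, hi = ci(count, denom)
        mean = min(max(count / denom, lo), hi)
        probs[key] = ProbabilityParam(
            f"{trial.arm}_{key}_{ci_method}", mean, lo, hi
        )
    return StrategyParams(strategy=trial.arm, cost_map=cost_map, **probs)
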