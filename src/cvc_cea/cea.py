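"""Incremental cost-effectiveness comparison and dominance verdicts."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .decision_tree import StrategyResult

__all__ = ["CEAResult", "compare", "results_table", "write_results_table"]


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of an intervention against a comparator.

    ``delta_cost`` is intervention minus comparator cost; ``delta_effect``
    is comparator minus intervention complication probability, i.e. averted
    complications per person. The verdict is ``"dominates"`` when the
    intervention is cheaper and more effective, ``"dominated"`` when it is
    costlier and less effective, ``"equal-effect"`` when the effect
    difference is zero (ICER undefined), and ``"icer"`` otherwise. Dominance
    is never reported as a negative cost-effectiveness ratio.
    """

    delta_cost: float
    delta_effect: float
    verdict: str
    icer: float | None = None


def compare(intervention: StrategyResult, comparator: StrategyResult) -> CEAResult:
    """Compute incremental cost, incremental effect, and the verdict."""
    delta_cost = intervention.expected_cost - comparator.expected_cost
    delta_effect = comparator.p_any_complication - intervention.p_any_complication
    if delta_cost < 0.0 and delta_effect > 0.0:
        return CEAResult(delta_cost, delta_effect, "dominates")
    if delta_cost > 0.0 and delta_effect < 0.0:
        return CEAResult(delta_cost, delta_effect, "dominated")
    if delta_effect == 0.0:
        return CEAResult(delta_cost, delta_effect, "equal-effect")
    return CEAResult(delta_cost, delta_effect, "icer", icer=delta_cost / delta_effect)


def results_table(
    intervention: StrategyResult, comparator: StrategyResult
) -> pd.DataFrame:
    """Two-row incremental cost-effectiveness table.

    Columns mirror the conventional CEA layout: per-strategy cost,
    incremental cost, complications per person, incremental effect, and the
    ICER or dominance verdict (reported on the intervention row).
    """
    res = compare(intervention, comparator)
    icer_label = res.verdict.capitalize() if res.icer is None else f"{res.icer:.0f}"
    return pd.DataFrame(
        {
            "strategy": [intervention.strategy, comparator.strategy],
            "cost": [intervention.expected_cost, comparator.expected_cost],
            "incremental_cost": [res.delta_cost, None],
            "complications_per_person": [
                intervention.p_any_complication,
                comparator.p_any_complication,
            ],
            "incremental_effect": [res.delta_effect, None],
            "icer_or_verdict": [icer_label, None],
        }
    )


def write_results_table(
    intervention: StrategyResult, comparator: StrategyResult, path: str | Path
) -> pd.DataFrame:
    """Write the incremental comparison table to CSV and return it."""
    table = results_table(intervention, comparator)
    table.to_csv(path, index=False)
    return table
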