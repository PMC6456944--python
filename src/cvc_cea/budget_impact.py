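"""Annual payer-level budget impact of adopting ultrasound guidance.

Multiplies the per-procedure incremental cost and incremental effect by the
number of catheterizations performed under ultrasound guidance in a year
(annual volume times adoption share). The projection is single-year and
undiscounted, and linear in both adoption and volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .parameters import BudgetContext

__all__ = ["BudgetResult", "project", "project_range", "budget_table"]


@dataclass(frozen=True)
class BudgetResult:
    """Annual projection at one adoption share."""

    adoption: float
    n_ug: float
    annual_cost_delta: float
    annual_complications_averted: float

    @property
    def annual_savings(self) -> float:
        """Positive € savings when the incremental cost is negative."""
        return -self.annual_cost_delta

    @property
    def savings_millions_rounded(self) -> float:
        """Savings rounded to the nearest €0.1 million."""
        return round(self.annual_savings / 1e6, 1)

    @property
    def complications_averted_rounded(self) -> int:
        """Averted complications rounded to the nearest thousand."""
        return int(round(self.annual_complications_averted / 1000.0)) * 1000


def project(ctx: BudgetContext, adoption: float) -> BudgetResult:
    """Project annual cost change and averted complications at one share."""
    if not 0.0 <= adoption <= 1.0:
        raise ValueError(f"adoption must be in [0, 1], got {adoption}")
    n_ug = adoption * ctx.annual_catheters
    return BudgetResult(
        adoption=adoption,
        n_ug=n_ug,
        annual_cost_delta=n_ug * ctx.incremental_cost,
        annual_complications_averted=n_ug * ctx.incremental_effect,
    )


def project_range(ctx: BudgetContext, adoptions: list[float] | None = None) -> list[BudgetResult]:
    """Project across adoption shares (default: the context's low and high)."""
    if adoptions is None:
        adoptions = [ctx.adoption_low, ctx.adoption_high]
    return [project(ctx, a) for a in adoptions]


def budget_table(results: list[BudgetResult], path: str | Path | None = None) -> pd.DataFrame:
    """Tabulate raw and rounded budget figures; optionally write CSV."""
    table = pd.DataFrame(
        {
            "adoption": [r.adoption for r in results],
            "n_ug_catheterizations": [r.n_ug for r in results],
            "annual_cost_delta_eur": [r.annual_cost_delta for r in results],
            "annual_savings_eur_millions_rounded": [
                r.savings_millions_rounded for r in results
            ],
            "annual_complications_averted": [
                r.annual_complications_averted for r in results
            ],
            "annual_complications_averted_rounded": [
                r.complications_averted_rounded for r in results
            ],
        }
    )
    if path is not None:
        table.to_csv(path, index=False)
    return table
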