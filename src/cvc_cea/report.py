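"""End-to-end pipeline run and report generation.

Executes the base case, one-way sensitivity analysis, probabilistic
sensitivity analysis, structural scenarios and the budget impact projection
in one pass, writing CSV tables, a machine-readable JSON of headline
numbers, and a short human-readable report. Headline figures are emitted
both unrounded and at reporting precision (costs to €1, probabilities to
three decimals).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .budget_impact import budget_table, project_range
from .cea import compare, write_results_table
from .decision_tree import evaluate_strategy
from .parameters import default_parameters, load_parameters
from .scenarios import Scenario, run_scenarios, scenarios_from_config
from .sensitivity import dsa_table, one_way_dsa, run_psa, threshold_intervention_cost

__all__ = ["RunConfig", "run_all"]

DEFAULT_SCENARIOS = [
    Scenario(name="doubled complication rates", multiplier=2.0),
    Scenario(name="tripled complication rates", multiplier=3.0),
]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    parameter_file: str | None = None
    seed: int = 0
    psa_iterations: int = 10_000
    scenario_file: str | None = None
    outdir: str = "results"
    cost_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.psa_iterations < 1:
            raise ValueError("psa_iterations must be at least 1")

    def config_hash(self) -> str:
        # hash only settings that influence the numbers, not where they land
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _round_cost(x: float) -> float:
    return round(x)


def _round_prob(x: float) -> float:
    return round(x, 3)


def run_all(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``.

    Returns the headline-number dictionary that is also written to
    ``report.json``. Outputs are deterministic given the seed.
    """
    outdir = Path(config.outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise RuntimeError(f"cannot create output directory {outdir}: {exc}") from exc

    if config.parameter_file:
        ug, lm, ctx = load_parameters(config.parameter_file)
    else:
        ug, lm, ctx = default_parameters()

    # Base case
    r_ug = evaluate_strategy(ug, cost_scale=config.cost_scale)
    r_lm = evaluate_strategy(lm, cost_scale=config.cost_scale)
    base = compare(r_ug, r_lm)
    write_results_table(r_ug, r_lm, outdir / "base_case.csv")

    # One-way DSA / tornado
    entries = one_way_dsa(ug, lm, cost_scale=config.cost_scale)
    dsa_table(entries).to_csv(outdir / "tornado.csv", index=False)

    # PSA
    psa = run_psa(
        ug,
        lm,
        iterations=config.psa_iterations,
        seed=config.seed,
        cost_scale=config.cost_scale,
    )
    psa.summary().to_csv(outdir / "psa_summary.csv")
    psa.write_scatter_csv(outdir / "psa_scatter.csv")

    # Structural scenarios
    if config.scenario_file:
        scenario_list = scenarios_from_config(config.scenario_file)
    else:
        scenario_list = DEFAULT_SCENARIOS
    scen = run_scenarios(
        ug, lm, scenario_list, include_base=True, cost_scale=config.cost_scale
    )
    scen.to_csv(outdir / "scenarios.csv", index=False)

    # Budget impact (incremental effect from this run's base case)
    ctx = dataclasses.replace(ctx, incremental_effect=base.delta_effect)
    budget = project_range(ctx)
    budget_table(budget, outdir / "budget.csv")

    threshold = threshold_intervention_cost(ctx.incremental_cost)

    headline = {
        "base_case": {
            "cost_ug": r_ug.expected_cost,
            "cost_lm": r_lm.expected_cost,
            "cost_ug_rounded": _round_cost(r_ug.expected_cost),
            "cost_lm_rounded": _round_cost(r_lm.expected_cost),
            "p_any_ug": r_ug.p_any_complication,
            "p_any_lm": r_lm.p_any_complication,
            "p_any_ug_rounded": _round_prob(r_ug.p_any_complication),
            "p_any_lm_rounded": _round_prob(r_lm.p_any_complication),
            "delta_cost": base.delta_cost,
            "delta_effect": base.delta_effect,
            "delta_effect_rounded": _round_prob(base.delta_effect),
            "verdict": base.verdict,
        },
        "psa": {
            "iterations": psa.iterations,
            "precision": "full" if psa.iterations >= 10_000 else "reduced",
            "dominance_fraction": psa.dominance_fraction,
            "effect_ug_p2.5": psa.percentile("effect_ug", 2.5),
            "effect_ug_p2.5_rounded": round(psa.percentile("effect_ug", 2.5), 2),
            "effect_lm_p97.5": psa.percentile("effect_lm", 97.5),
        },
        "threshold_intervention_cost_eur": threshold,
        "budget_impact": [
            {
                "adoption": r.adoption,
                "annual_savings_eur": r.annual_savings,
                "annual_savings_eur_millions_rounded": r.savings_millions_rounded,
                "annual_complications_averted": r.annual_complications_averted,
                "annual_complications_averted_rounded": r.complications_averted_rounded,
            }
            for r in budget
        ],
        "scenarios": scen.to_dict(orient="records"),
        "metadata": {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "python_version": platform.python_version(),
            "seed": config.seed,
            "config_hash": config.config_hash(),
        },
    }

    (outdir / "report.json").write_text(json.dumps(headline, indent=2, sort_keys=True))
    (outdir / "report.txt").write_text(_text_report(headline))
    return headline


def _text_report(h: dict) -> str:
    b = h["base_case"]
    lines = [
        "Cost-effectiveness of ultrasound-guided vs landmark central venous catheterization",
        "=" * 80,
        "",
        "Base case (per person):",
        f"  UG: cost EUR {b['cost_ug']:.2f}, complications {b['p_any_ug']:.4f}",
        f"  LM: cost EUR {b['cost_lm']:.2f}, complications {b['p_any_lm']:.4f}",
        f"  Incremental effect (averted complications/person): {b['delta_effect']:.3f}",
        f"  Verdict: {b['verdict']}",
        "",
        f"PSA ({h['psa']['iterations']} iterations, {h['psa']['precision']} precision):",
        f"  UG dominates in {h['psa']['dominance_fraction'] * 100:.1f}% of iterations",
        f"  2.5th percentile of UG effectiveness: {h['psa']['effect_ug_p2.5']:.3f}",
        "",
        f"Break-even intervention cost: EUR {h['threshold_intervention_cost_eur']:.0f}",
        "",
        "Budget impact:",
    ]
    for r in h["budget_impact"]:
        lines.append(
            f"  adoption {r['adoption']:.0%}: savings EUR "
            f"{r['annual_savings_eur_millions_rounded']:.1f}M, "
            f"~{r['annual_complications_averted_rounded']} complications averted/yr"
        )
    lines += [
        "",
        f"Seed: {h['metadata']['seed']}  config hash: {h['metadata']['config_hash']}",
        "",
    ]
    return "\n".join(lines)
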