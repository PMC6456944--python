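"""Structural sensitivity analyses.

Two kinds of scenario are supported: risk multipliers, which scale all
complication probabilities (per-attempt totals and arterial puncture) by a
common factor in both strategies to represent higher-risk populations, and
replacement scenarios, which substitute complete alternative parameter sets
(e.g. populations that include pediatric patients or indirect cannulation,
supplied via configuration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .cea import compare
from .decision_tree import evaluate_strategy
from .parameters import StrategyParams, load_parameters
from .sensitivity import run_psa

__all__ = ["Scenario", "apply_scenario", "run_scenarios", "scenarios_from_config"]

_CLAMP = 0.999
_COMPLICATION_KEYS = ("c1", "c2", "c3", "arterial")


@dataclass(frozen=True)
class Scenario:
    """A named transformation of the base-case parameter sets."""

    name: str
    multiplier: float | None = None
    replacement: tuple[StrategyParams, StrategyParams] | None = None

    def __post_init__(self) -> None:
        if (self.multiplier is None) == (self.replacement is None):
            raise ValueError("scenario needs exactly one of multiplier or replacement")
        if self.multiplier is not None and self.multiplier <= 0.0:
            raise ValueError(f"multiplier must be positive, got {self.multiplier}")


def apply_scenario(
    ug: StrategyParams, lm: StrategyParams, scenario: Scenario
) -> tuple[StrategyParams, StrategyParams]:
    """Transform the base parameter sets according to a scenario.

    Multiplier scenarios scale the complication probabilities (``c1``,
    ``c2``, ``c3`` and arterial puncture) directly, leaving failure
    probabilities unchanged; results are clamped to 0.999 with a warning.
    Replacement scenarios return the substituted parameter sets as-is.
    """
    if scenario.replacement is not None:
        return scenario.replacement
    m = scenario.multiplier
    out = []
    for arm in (ug, lm):
        new = arm
        for key in _COMPLICATION_KEYS:
            p = arm.probabilities[key]
            if p.mean * m > _CLAMP:
                warnings.warn(
                    f"{scenario.name}: {arm.strategy}.{key} clamped to {_CLAMP}",
                    stacklevel=2,
                )
            new = new.with_probability(key, p.scaled(m, clamp=_CLAMP))
        out.append(new)
    return out[0], out[1]


def run_scenarios(
    ug: StrategyParams,
    lm: StrategyParams,
    scenarios: list[Scenario],
    include_base: bool = True,
    cost_scale: float = 1.0,
    psa_iterations: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate a list of scenarios into a comparison table.

    Each row carries per-strategy costs and complication probabilities, the
    incremental quantities and the dominance verdict; with
    ``psa_iterations`` set, a per-scenario probabilistic analysis adds the
    fraction of iterations in which the intervention dominates.
    """
    todo: list[tuple[str, StrategyParams, StrategyParams]] = []
    if include_base:
        todo.append(("base case", ug, lm))
    for sc in scenarios:
        s_ug, s_lm = apply_scenario(ug, lm, sc)
        todo.append((sc.name, s_ug, s_lm))

    rows = []
    for name, s_ug, s_lm in todo:
        r_ug = evaluate_strategy(s_ug, cost_scale=cost_scale)
        r_lm = evaluate_strategy(s_lm, cost_scale=cost_scale)
        res = compare(r_ug, r_lm)
        row = {
            "scenario": name,
            "cost_ug": r_ug.expected_cost,
            "cost_lm": r_lm.expected_cost,
            "p_any_ug": r_ug.p_any_complication,
            "p_any_lm": r_lm.p_any_complication,
            "delta_cost": res.delta_cost,
            "delta_effect": res.delta_effect,
            "verdict": res.verdict if res.icer is None else f"{res.icer:.0f}",
        }
        if psa_iterations is not None:
            psa = run_psa(
                s_ug, s_lm, iterations=psa_iterations, seed=seed, cost_scale=cost_scale
            )
            row["psa_dominance_fraction"] = psa.dominance_fraction
        rows.append(row)
    return pd.DataFrame(rows)


def scenarios_from_config(source: str | Path | list[dict]) -> list[Scenario]:
    """Build scenarios from a YAML file or a list of mappings.

    Each entry is ``{name, type: multiplier|replacement, value}``; for a
    multiplier, ``value`` is the factor, for a replacement it is the path
    of a parameter file providing the substituted strategies.
    """
    if isinstance(source, (str, Path)):
        entries = yaml.safe_load(Path(source).read_text()) or []
    else:
        entries = source
    out = []
    for entry in entries:
        kind = entry.get("type", "multiplier")
        if kind == "multiplier":
            out.append(Scenario(name=entry["name"], multiplier=float(entry["value"])))
        elif kind == "replacement":
            s_ug, s_lm, _ = load_parameters(entry["value"])
            out.append(Scenario(name=entry["name"], replacement=(s_ug, s_lm)))
        else:
            raise ValueError(f"unknown scenario type {kind!r}")
    return out
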