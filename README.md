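# cvc-cea

Decision-analytic cost-effectiveness model of **ultrasound-guided (UG)**
versus **landmark (LM)** central venous catheterization of the internal
jugular vein, from the perspective of the German Statutory Health Insurance
(SHI).

Central venous catheters are placed either by surface anatomical landmarks
or under real-time two-dimensional ultrasound. Failed attempts and
catheter-related complications — arterial puncture most frequently, plus a
composite of thrombosis, embolism, hydro-/hematomediastinum,
hemato-/hydrothorax, pneumothorax, nerve injury and subcutaneous emphysema —
are more common with the landmark technique. This package implements the
full health-economic pipeline that quantifies that trade-off for health
economists and intensive-care/anesthesia decision makers: a three-attempt
decision tree, incremental cost-effectiveness with dominance verdicts,
deterministic (tornado) and probabilistic (Monte Carlo) sensitivity
analysis, structural scenarios for higher-risk populations, a break-even
threshold for the intervention cost, an annual budget impact projection,
and a patient-level microsimulation that serves as an independent oracle
for every analytic result.

## Model

Each patient undergoes up to three cannulation attempts. Attempt
*k* ∈ {1, 2, 3} carries a complication probability *c<sub>k</sub>*; attempts
1 and 2 additionally fail with probabilities *f₁*, *f₂* (failures move on to
the next attempt; the third attempt is absorbing). The per-person
probability of at least one complication is

```
p_any = 1 − (1 − c₁) · [ (1 − f₁) + f₁ (1 − c₂) ( (1 − f₂) + f₂ (1 − c₃) ) ]
```

and effectiveness is `1 − p_any` (probability of a complication-free
catheterization). Each attempt-with-complication accrues the expected cost
of one complication episode,
`w_a · cost(arterial) + (1 − w_a) · Σ_j w_j cost_j`, where `w_a` is the
arterial share of total complications. Strategies are compared by
incremental cost `ΔC` and incremental effect `ΔE` (averted complications
per person); when `ΔC < 0` and `ΔE > 0` the intervention *dominates* and no
ICER ratio is reported.

For probabilistic sensitivity analysis, every probability is drawn from a
beta distribution moment-matched to its mean and standard error
(SE = 95% CI width / 3.92) and every unit cost from a gamma distribution;
10,000 iterations re-evaluate both strategies per draw.

## Worked example

```bash
cvc-cea --outdir results --seed 1 all
```

prints (abridged):

```
Base case (per person):
  UG: cost EUR 4.51, complications 0.0359
  LM: cost EUR 20.68, complications 0.1742
  Incremental effect (averted complications/person): 0.138
  Verdict: dominates

PSA (10000 iterations, full precision):
  UG dominates in 100.0% of iterations
  2.5th percentile of UG effectiveness: 0.953

Break-even intervention cost: EUR 179

Budget impact:
  adoption 10%: savings EUR 10.2M, ~8000 complications averted/yr
  adoption 20%: savings EUR 20.3M, ~16000 complications averted/yr
```

Reading: with the published clinical inputs, ultrasound guidance leaves
3.6% of patients with at least one complication versus 17.4% under the
landmark method — 0.138 complications averted per person — and is also
cheaper, i.e. it *dominates*. The probability that this conclusion flips
under joint parameter uncertainty is negligible (dominance in all 10,000
Monte Carlo iterations; the lower 95% limit of UG effectiveness is 0.95).
At the published saving of €179 per procedure, shifting 10–20% of the
568,000 annual German catheterizations to ultrasound saves €10.2–20.3
million and averts roughly 8,000–16,000 complications per year. Note the
per-person complication-treatment costs shown here (€4.51/€20.68) cover
only the ten tabulated complication costs; see `docs/methods.md` for why
total procedure costs are out of the model's reach and how the `cost_scale`
hook relates to them.

The same analyses are available as library calls:

```python
from cvc_cea import default_parameters, evaluate_strategy, compare, run_psa

ug, lm, ctx = default_parameters()
res = compare(evaluate_strategy(ug), evaluate_strategy(lm))
print(res.delta_effect, res.verdict)   # 0.138... dominates
```

Subcommands `base`, `dsa`, `psa`, `scenarios`, `budget` run the stages
individually; `--config` loads a YAML/JSON parameter file overriding any
subset of the embedded defaults.

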