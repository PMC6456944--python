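# Methods

## Model structure

The model is a decision tree over a hypothetical cohort undergoing central
venous catheterization of the internal jugular vein (Seldinger technique),
comparing real-time two-dimensional ultrasound guidance (UG) against the
anatomical landmark method (LM) over a one-year horizon with no
discounting. A maximum of three cannulation attempts is allowed. Attempt
*k* applies a per-attempt total-complication probability *c_k* to every
patient who reaches it; attempts 1 and 2 then split into success/failure
with probabilities *f1*, *f2*, and failures proceed to the next attempt.
The third attempt is absorbing: it has no failure branch, and a
complication occurring on it is counted whether or not the cannulation
ultimately succeeds. Complication draws are independent across attempts —
no within-patient correlation structure is available to justify anything
richer.

The per-patient outcome is binary: effectiveness is the probability of
experiencing **no** complication on any attempt reached. This person-level
"any complication" coding (rather than expected complication counts) is
what reproduces the published per-person complication probabilities
(0.036 UG / 0.175 LM); the two coincide only to first order when the
probabilities are small. Rollback over the 14 terminal paths agrees with
the closed form

    p_any = 1 − (1−c1)·[(1−f1) + f1·(1−c2)·((1−f2) + f2·(1−c3))]

to 1e−12, a property the test suite checks over 1,000 random parameter
sets.

## Parameters

Clinical probabilities (per strategy: f1, f2, c1, c2, c3, and the
per-attempt arterial puncture probability) are embedded with their
published means and 95% CIs and can be overridden from a YAML/JSON file.
The escalation of complication risk over repeated attempts is also
published as odds ratios (8.4 for the second attempt, 35.6 for the third);
`apply_odds_ratio` implements that transformation, but applying it to the
first-attempt probabilities does **not** reproduce the published
second/third-attempt values (e.g. UG 0.029 → 0.2006 vs the printed 0.041 —
the pooling the original analysts used is not stated), so the printed
per-attempt values are used verbatim as defaults and the odds-ratio
transform is reserved for user-defined scenarios.

Standard errors for probabilities come from the normal approximation
SE = (CI width)/3.92 — the CIs are the only spread information available.
Beta distributions are moment-matched (`alpha = mean·(mean(1−mean)/SE² − 1)`
etc.); gamma distributions for costs use `shape = (mean/SE)²`,
`scale = SE²/mean`. Cost SEs default to 0.25·mean so that the ±50%
deterministic range corresponds to roughly ±2 SE; this fraction is
configurable per cost (`se_frac`).

Unit costs per complication episode (€2016, SHI perspective, derived from
DRG reimbursement differences at a maximum-care hospital) are embedded for
the ten complication types. The composite "other complications" endpoint
has no published within-composite incidence split, so the mix defaults to
equal weights (1/9 each) and is exposed in configuration for calibration.
The arterial share of complications, `w_a`, defaults to the ratio of the
arterial puncture probability to the first-attempt total complication
probability (UG 0.015/0.029, LM 0.081/0.114), clamped to [0, 1].

## Cost side and its limits

With these inputs the model's expected per-person costs are roughly an
order of magnitude below the published totals (€51 UG / €230 LM): those
totals rest on supplementary cost inputs that were never printed and
cannot be reconstructed from the tabulated per-complication costs alone.
The package therefore treats the cost side structurally: expected cost is
linear in every unit cost, zero when no complications are possible, and
verified against microsimulation; a per-strategy `cost_scale` hook lets a
user calibrate the cost level without ever touching the effect side. The
published €−179 incremental cost is carried as an explicit input where a
cost level is required (budget impact, break-even threshold), not derived.

## Sensitivity analyses

**One-way (tornado).** Each probability is varied over its 95% CI and each
unit cost over ±50% (both strategies simultaneously, since unit costs are
shared), all else held at base. Because the base-case verdict is dominance,
an ICER ratio has no stable sign to rank by; entries are ranked by the span
of the incremental cost (or, optionally, the incremental effect), with
percent-of-base annotations, ties broken alphabetically.

**Probabilistic.** 10,000 Monte Carlo iterations draw all twelve
probabilities (beta) and ten costs (gamma) independently — no correlation
across attempts or arms is imposed, as none is reported — and re-evaluate
both strategies per draw. Evaluation uses the closed-form identities
(complication-free product over attempts; expected episodes × expected
episode cost), which the tests pin to the explicit tree rollback at 1e−12,
so the vectorized path is the tree, not an approximation of it. Beta draws
cannot exceed 1 and gamma draws cannot go negative, so no clamping is
applied. Percentiles use linear interpolation (recorded in result
metadata). With the default SEs the 2.5th percentile of UG effectiveness
lands at ≈0.95 (a delta-method calculation predicts ≈0.954) and UG
dominates LM in effectively every iteration. The published PSA cost
intervals depend on the unavailable cost SEs and are reproduced only
qualitatively (UG and LM cost distributions do not overlap under the
configured SEs).

**Structural scenarios.** Higher-risk populations are modelled by scaling
the complication probabilities (c1, c2, c3, arterial) directly by a common
multiplier — probabilities, not odds, matching the "doubled/tripled rates"
framing — leaving failure probabilities unchanged and clamping at 0.999
with a warning. Neither probability- nor odds-scaling exactly reproduces
the published doubled-rate per-person outcomes (we compute ≈0.071/0.330
versus the printed 0.076/0.343; the exact doubling semantics were not
stated), so scenario conclusions are assessed on the verdict (UG remains
dominant) and the monotone growth of the effect gap in the multiplier,
both of which hold. Alternative populations (pediatric, indirect
cannulation) require meta-analytic inputs not printed with the model and
are supported as replacement parameter sets supplied via configuration.

**Threshold.** Expected cost is linear in any additive per-procedure
intervention cost, so the break-even intervention cost equals the negated
base-case incremental cost: €179 when the saving is €179.

## Budget impact

Single-year, undiscounted, linear projection: annual savings =
adoption × 568,000 catheterizations × €179 saving per procedure; averted
complications analogously with the model's base-case incremental effect
(0.138). Savings are reported to the nearest €0.1 million and averted
complications to the nearest 1,000 (10.2/20.3 million € and 8,000/16,000
at 10%/20% adoption).

## Microsimulation oracle and synthetic trials

`simulate_cohort` pushes patients through the identical pathway with
Bernoulli draws per attempt; complication types are sampled from
(w_a, (1−w_a)·weights), so the sampled episode cost is unbiased for the
analytic attribution. Randomness is a counter-based Philox stream keyed on
the root seed, with each patient owning a fixed-width row of uniforms:
cohorts are reproducible and a patient's outcome does not depend on cohort
size or ordering. At n = 10⁶ the empirical complication risk and mean cost
match the analytic tree within 3 Monte Carlo SEs.

`simulate_trial` generates trial-like event tables from nested binomials —
distributionally identical to aggregating a cohort (everything is
independent per attempt) but O(1) in n, which makes 1,000-replicate
coverage studies cheap. `estimate_params` recovers the probabilities as
event proportions with Wilson score 95% CIs (normal approximation
available; the method is recorded in the parameter names). Denominators
follow the pathway: first-attempt outcomes out of n, second-attempt out of
first-attempt failures, third-attempt out of second-attempt failures;
arterial punctures are counted on first attempts, matching the per-attempt
definition. Wilson coverage over 1,000 replicates at n = 10⁵ per arm sits
in the nominal 93–97% band for every parameter.

What the synthetic data do **not** emulate: operator learning curves,
anatomical covariates (vein diameter/position), within-patient correlation
of complications across attempts, emergency-department settings, and
catheter-related infection or mortality. Passing tests show internal
consistency of the pipeline under its stated assumptions, not external
validity for populations outside the underlying trials.

## Numerical choices and problem sizes

Branch probabilities must sum to 1 within 1e−9; moment-matching identities
are enforced at 1e−9; rollback-vs-closed-form agreement at 1e−12. The
oracle-equivalence suite uses 1,000 random parameter sets with
microsimulation at n = 10⁴ per set plus n = 10⁶ at the base case — the
3-Monte-Carlo-SE criterion is equally stringent at any n, and these sizes
keep the full suite comfortably fast. DSA bounds outside [0, 1] are clamped
with a warning; a PSA standard error exceeding the beta feasibility bound
raises an error naming the parameter. Reports emit headline figures both
unrounded and at reporting precision (costs to €1, probabilities to three
decimals); `report.json` is byte-identical across runs with the same seed
and analytic configuration.
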