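"""Patient-level simulation oracle and synthetic trial round trips."""

import numpy as np
import pytest
from statsmodels.stats.proportion import proportion_confint

from cvc_cea.decision_tree import (
    attribute_cost,
    evaluate_strategy,
    expected_complications_closed_form,
    p_any_complication_closed_form,
)
from cvc_cea.microsim import (
    SyntheticTrial,
    estimate_params,
    simulate_cohort,
    simulate_trial,
    trial_from_cohort,
)

from conftest import make_params


class TestSimulateCohort:
    def test_seeded_determinism(self, lm):
        a = simulate_cohort(lm, 5000, seed=42)
        b = simulate_cohort(lm, 5000, seed=42)
        assert np.array_equal(a.total_cost, b.total_cost)
        assert np.array_equal(a.any_complication, b.any_complication)
        c = simulate_cohort(lm, 5000, seed=43)
        assert not np.array_equal(a.any_complication, c.any_complication)

    def test_empirical_risk_converges_to_closed_form(self, lm):
        n = 200_000
        cohort = simulate_cohort(lm, n, seed=11)
        truth = p_any_complication_closed_form(lm)
        mc_se = np.sqrt(truth * (1 - truth) / n)
        assert abs(cohort.p_any_complication() - truth) < 3 * mc_se

    def test_empirical_cost_converges_to_tree(self, lm):
        n = 200_000
        cohort = simulate_cohort(lm, n, seed=12)
        tree_cost = evaluate_strategy(lm).expected_cost
        mc_se = cohort.total_cost.std(ddof=1) / np.sqrt(n)
        assert abs(cohort.mean_cost() - tree_cost) < 3 * mc_se

    def test_zero_complication_parameters_yield_no_events(self):
        params = make_params(0.3, 0.3, 0.0, 0.0, 0.0, arterial=0.0)
        cohort = simulate_cohort(params, 2000, seed=1)
        assert cohort.p_any_complication() == 0.0
        assert cohort.mean_cost() == 0.0

    def test_forced_failures_use_three_attempts(self):
        params = make_params(1.0, 1.0, 0.0, 0.0, 0.0, arterial=0.0)
        cohort = simulate_cohort(params, 500, seed=1)
        assert (cohort.attempts_used == 3).all()

    def test_records_respect_attempt_bounds(self, lm):
        cohort = simulate_cohort(lm, 200, seed=3)
        for rec in cohort.records():
            assert 1 <= rec.attempts_used <= 3
            for attempt, name in rec.complications:
                assert attempt <= rec.attempts_used
                assert name in lm.cost_map

    def test_csv_export(self, lm, tmp_path):
        cohort = simulate_cohort(lm, 100, seed=3)
        path = tmp_path / "cohort.csv"
        cohort.write_csv(path)
        import pandas as pd

        frame = pd.read_csv(path)
        assert len(frame) == 100
        assert frame.total_cost.sum() == pytest.approx(cohort.total_cost.sum())

    def test_invalid_sizes_rejected(self, lm):
        with pytest.raises(ValueError):
            simulate_cohort(lm, 0, seed=1)


class TestSyntheticTrials:
    def test_binomial_and_cohort_routes_agree_in_distribution(self, lm):
        # means of the aggregated counts from both generators should match
        n, reps = 20_000, 5
        binom = [simulate_trial(lm, n, seed=100 + i) for i in range(reps)]
        cohorts = [
            trial_from_cohort(simulate_cohort(lm, n, seed=200 + i)) for i in range(reps)
        ]
        f1_b = np.mean([t.fail1 / t.n for t in binom])
        f1_c = np.mean([t.fail1 / t.n for t in cohorts])
        assert f1_b == pytest.approx(lm.f1.mean, abs=0.01)
        assert f1_c == pytest.approx(lm.f1.mean, abs=0.01)

    def test_count_consistency_enforced(self):
        with pytest.raises(ValueError):
            SyntheticTrial("X", 100, 50, 10, fail1=50, fail2=10, comp1=120,
                           comp2=5, comp3=2, arterial1=3)

    def test_proportion_point_estimates(self):
        trial = SyntheticTrial(
            "LM", 1000, 400, 80, fail1=400, fail2=80, comp1=114, comp2=60,
            comp3=14, arterial1=80,
        )
        est = estimate_params(trial)
        assert est.c1.mean == pytest.approx(0.114, abs=1e-9)
        assert est.f1.mean == pytest.approx(0.4)
        assert est.c2.mean == pytest.approx(0.15)

    def test_wilson_interval_matches_statsmodels(self):
        trial = SyntheticTrial(
            "LM", 1000, 400, 80, fail1=400, fail2=80, comp1=114, comp2=60,
            comp3=14, arterial1=80,
        )
        est = estimate_params(trial, ci_method="wilson")
        lo, hi = proportion_confint(114, 1000, alpha=0.05, method="wilson")
        assert est.c1.ci_low == pytest.approx(lo, abs=1e-9)
        assert est.c1.ci_high == pytest.approx(hi, abs=1e-9)

    def test_round_trip_recovers_generating_probabilities(self, lm):
        n = 100_000
        trial = simulate_trial(lm, n, seed=77)
        est = estimate_params(trial)
        for key, truth in lm.probabilities.items():
            # binomial SE bound at the smallest denominator involved
            assert abs(est.probabilities[key].mean - truth.mean) < 0.005

    def test_zero_denominator_rejected(self):
        trial = SyntheticTrial("X", 100, 0, 0, fail1=0, fail2=0, comp1=5,
                               comp2=0, comp3=0, arterial1=2)
        with pytest.raises(ValueError):
            estimate_params(trial)

    def test_ci_coverage_near_nominal(self, lm):
        # 400 replicates at n=20,000: Wilson CI should cover the truth ~95%
        reps, n = 400, 20_000
        covered = {key: 0 for key in lm.probabilities}
        for i in range(reps):
            est = estimate_params(simulate_trial(lm, n, seed=1000 + i))
            for key, truth in lm.probabilities.items():
                p = est.probabilities[key]
                covered[key] += p.ci_low <= truth.mean <= p.ci_high
        for key, hits in covered.items():
            assert 0.91 <= hits / reps <= 0.99, key


class TestCostConsistency:
    def test_sampled_episode_cost_matches_attribution(self, lm):
        # mean cost per complication episode equals the analytic attribution
        cohort = simulate_cohort(lm, 300_000, seed=5)
        n_episodes = cohort.n_complications.sum()
        mean_episode_cost = cohort.total_cost.sum() / n_episodes
        assert mean_episode_cost == pytest.approx(attribute_cost(lm), rel=0.02)

    def test_expected_episode_count(self, lm):
        cohort = simulate_cohort(lm, 300_000, seed=6)
        truth = expected_complications_closed_form(lm)
        assert cohort.n_complications.mean() == pytest.approx(truth, rel=0.02)
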