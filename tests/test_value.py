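"""TMLE value estimation, rule comparisons, and the report arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rxrule
from rxrule.itr import OutcomeSurfaces, PropensityMatrix
from rxrule.value import (
    RuleValueEstimate,
    compare_rules,
    concordance_ratio,
    contribution_decomposition,
    distribution_table,
    medication_specific_summary,
    nnt,
    observed_success_rate,
    proportional_ratio,
    stochastic_rule_value,
    tmle_rule_value,
)


def _gmat(raw, bound=0.01):
    return PropensityMatrix(values=np.clip(raw, bound, None), raw=raw,
                            truncation_bound=bound, truncated_count=0)


class TestTmle:
    def test_everyone_treated_equals_sample_mean(self):
        # all patients on arm 0, rule = static(0), g == 1: the score
        # equation forces the estimate onto the empirical mean exactly
        rng = np.random.default_rng(0)
        n = 400
        y = rng.integers(0, 2, n).astype(float)
        arms = np.zeros(n, dtype=np.int64)
        raw = np.column_stack([np.ones(n), np.zeros(n)])
        Q = np.column_stack([np.full(n, 0.3), np.full(n, 0.5)])
        est = tmle_rule_value(y, arms, arms, _gmat(raw), Q)
        assert est.value == pytest.approx(y.mean(), abs=1e-9)

    def test_score_already_solved_keeps_epsilon_zero(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        arms = np.zeros(4, dtype=np.int64)
        raw = np.column_stack([np.ones(4), np.zeros(4)])
        Q = np.column_stack([np.full(4, 0.5), np.full(4, 0.2)])
        est = tmle_rule_value(y, arms, arms, _gmat(raw), Q)
        assert est.epsilon == 0.0
        assert est.value == pytest.approx(0.5)

    def test_influence_values_mean_zero_and_score_solved(self, default_run):
        for name in ("itr", "observed"):
            est = default_run["ev"][name]
            assert abs(est.influence_values.mean()) < 1e-8
        assert abs(default_run["ev"]["itr"].score_residual) < 1e-6

    def test_rule_outside_arm_set_rejected(self):
        y = np.zeros(5)
        arms = np.zeros(5, dtype=np.int64)
        raw = np.full((5, 2), 0.5)
        with pytest.raises(ValueError):
            tmle_rule_value(y, arms, np.full(5, 2), _gmat(raw), raw)

    def test_static_rule_tracks_oracle_with_true_nuisances(self):
        cfg = rxrule.default_config(n_patients=20_000, seed=41)
        X = rxrule.generate_covariates(cfg)
        arms, g_true = rxrule.assign_treatments(cfg, X)
        y, mu, _ = rxrule.simulate_outcomes(cfg, X, arms)
        est = tmle_rule_value(y, arms, np.full(len(y), 1), _gmat(g_true), mu)
        oracle = mu[:, 1].mean()
        assert abs(est.value - oracle) < 3 * est.se


class TestStochasticValue:
    def _fake(self, value, n=100, seed=0):
        ic = np.random.default_rng(seed).normal(size=n)
        ic -= ic.mean()
        return RuleValueEstimate(value=value, se=float(ic.std() / np.sqrt(n)),
                                 ci95=(0, 1), influence_values=ic, n=n)

    def test_point_mass_identical_to_single_arm(self):
        est = {0: self._fake(0.4), 1: self._fake(0.6, seed=1)}
        out = stochastic_rule_value(est, np.array([1.0, 0.0]))
        assert out.value == est[0].value
        assert np.allclose(out.influence_values, est[0].influence_values)

    def test_linearity(self):
        est = {0: self._fake(0.4), 1: self._fake(0.6, seed=1)}
        out = stochastic_rule_value(est, np.array([0.5, 0.5]))
        assert out.value == pytest.approx(0.5)

    def test_missing_arm_rejected(self):
        est = {0: self._fake(0.4)}
        with pytest.raises(ValueError):
            stochastic_rule_value(est, np.array([0.5, 0.5]))

    def test_uniform_matches_oracle_grand_mean(self, default_run):
        ev, truth = default_run["ev"], default_run["truth"]
        mu = truth.true_success_probs[default_run["hold_ids"]]
        arms_avail = sorted(ev["static"])
        oracle = mu[:, arms_avail].mean()
        est = ev["uniform"]
        assert abs(est.value - oracle) < 3 * est.se + 0.01


class TestObservedRate:
    def test_all_successes(self):
        est = observed_success_rate(np.ones(10))
        assert est.value == 1.0 and est.se == 0.0

    def test_simple_mean(self):
        assert observed_success_rate(np.array([1, 0, 1, 0])).value == 0.5

    def test_matches_assigned_arm_truth(self, default_run):
        mu = default_run["truth"].true_success_probs[default_run["hold_ids"]]
        arms = default_run["hold"].arms
        target = mu[np.arange(len(arms)), arms].mean()
        est = default_run["ev"]["observed"]
        assert abs(est.value - target) < 3 * est.se


class TestCompareRules:
    def _est(self, value, se, n=1000, seed=0):
        ic = np.random.default_rng(seed).normal(size=n)
        ic = (ic - ic.mean()) / ic.std(ddof=0) * se * np.sqrt(n)
        return RuleValueEstimate(value=value, se=se, ci95=(0, 1),
                                 influence_values=ic, n=n)

    def test_identical_estimates(self):
        e = self._est(0.5, 0.01)
        cmp = compare_rules(e, e)
        assert cmp.z == 0.0 and cmp.p_one_sided == 0.5

    def test_z_1645_gives_p_005(self):
        e1 = self._est(0.5 + 1.645 * 0.01, 0.01, seed=1)
        e2 = self._est(0.5, 0.0, seed=2)
        e2.influence_values[:] = 0.0
        cmp = compare_rules(e1, e2, correlated=False)
        assert cmp.p_one_sided == pytest.approx(0.05, abs=1e-3)

    def test_correlated_contrast_uses_difference_ic(self, default_run):
        ev = default_run["ev"]
        cmp = ev["comparisons"]["uniform"]
        ic = ev["itr"].influence_values - ev["uniform"].influence_values
        manual_se = ic.std(ddof=0) / np.sqrt(ev["itr"].n)
        assert cmp.se_contrast == pytest.approx(manual_se)


class TestReportArithmetic:
    def test_nnt_printed_values(self):
        assert nnt(51.7, 44.5) == 13.9
        assert nnt(100.0, 50.0) == 2.0
        assert nnt(44.5, 51.7) == -13.9

    def test_nnt_equal_rates_undefined(self):
        with pytest.raises(ValueError):
            nnt(50.0, 50.0)

    def test_proportional_ratio_printed_values(self):
        assert proportional_ratio(51.7, 44.5) == 1.16
        assert proportional_ratio(86.9, 81.7) == 1.06
        assert proportional_ratio(54.0, 46.4) == 1.16
        assert proportional_ratio(57.0, 49.5) == 1.15
        assert proportional_ratio(40.0, 40.0) == 1.0

    def test_proportional_ratio_bad_reference(self):
        with pytest.raises(ValueError):
            proportional_ratio(50.0, 0.0)

    def test_concordance_printed_values(self):
        assert concordance_ratio(26.2, 9.7) == 2.7
        assert concordance_ratio(7.6, 5.8) == 1.3
        assert concordance_ratio(3.2, 5.2) == 0.6
        assert concordance_ratio(0.0, 1.1) == 0.0
        assert concordance_ratio(0.0, 0.0) == 0.0

    def test_concordance_zero_denominator(self):
        with pytest.raises(ValueError):
            concordance_ratio(5.0, 0.0)

    def test_contribution_reproduces_published_decomposition(self):
        from rxrule.reference_example import CONTRIBUTION_INPUTS
        meds = list(CONTRIBUTION_INPUTS)
        d = np.array([CONTRIBUTION_INPUTS[m][0] for m in meds])
        c = np.array([CONTRIBUTION_INPUTS[m][1] for m in meds])
        contrib = contribution_decomposition(d, c)
        table = dict(zip(meds, contrib))
        assert table["sulpiride"] == pytest.approx(51.3, abs=0.05)
        assert table["olanzapine"] == pytest.approx(15.0, abs=0.05)
        assert table["zotepine"] == pytest.approx(10.6, abs=0.05)
        assert table["chlorpromazine"] == pytest.approx(10.1, abs=0.05)
        assert contrib.sum() == pytest.approx(100.0, abs=1e-8)

    def test_contribution_symmetry(self):
        contrib = contribution_decomposition(np.full(13, 2.0), np.full(13, 7))
        assert np.allclose(contrib, 100.0 / 13)

    @given(st.lists(st.tuples(st.floats(-30, 30), st.integers(1, 5000)),
                    min_size=2, max_size=15))
    @settings(max_examples=50, deadline=None)
    def test_contributions_always_sum_to_hundred(self, pairs):
        d = np.array([p[0] for p in pairs])
        c = np.array([p[1] for p in pairs], dtype=float)
        if abs((d * c).sum()) < 1e-6:
            return
        assert contribution_decomposition(d, c).sum() == pytest.approx(100.0, abs=1e-6)

    def test_contribution_zero_total_rejected(self):
        with pytest.raises(ValueError):
            contribution_decomposition(np.array([1.0, -1.0]), np.array([5, 5]))


class TestDistributionTable:
    def test_published_recommended_share(self):
        from rxrule.reference_example import RECOMMENDED_COUNTS
        meds = list(RECOMMENDED_COUNTS)
        counts = np.array([RECOMMENDED_COUNTS[m] for m in meds], dtype=float)
        tab, _, _ = distribution_table(meds, counts)
        ami = tab.loc[tab.medication == "amisulpride", "observed_pct"].iloc[0]
        assert ami == 30.2

    def test_empty_input(self):
        tab, chi2, p = distribution_table([], np.array([]))
        assert tab.empty

    def test_identical_distributions_chi2_zero(self):
        counts = np.array([10.0, 20.0, 30.0])
        _, chi2, _ = distribution_table(["a", "b", "c"], counts, counts)
        assert chi2 == 0.0


class TestMedicationSummary:
    def test_factual_rule_columns_coincide(self):
        rng = np.random.default_rng(5)
        n, K = 500, 3
        y = rng.integers(0, 2, n).astype(float)
        arms = rng.integers(0, K, n)
        raw = np.full((n, K), 1 / K)
        Q = np.tile(y.reshape(-1, 1), (1, K)) * 0.5 + 0.25
        static = {a: tmle_rule_value(y, arms, np.full(n, a), _gmat(raw), Q)
                  for a in range(K)}
        tab = medication_specific_summary(y, arms, arms, ["a", "b", "c"], static)
        # with the factual rule, the recommended subset IS the recipient set
        assert np.allclose(tab["obs_success_pct"], tab["subset_obs_success_pct"])
        assert np.array_equal(tab["n_recipients"], tab["n_recommended"])

    def test_unsupported_arm_marked_unavailable(self):
        y = np.array([1.0, 0.0])
        arms = np.array([0, 1])
        static = {0: RuleValueEstimate(0.5, 0.1, (0, 1), np.zeros(2), 2)}
        tab = medication_specific_summary(y, arms, arms, ["a", "b"], static)
        assert not tab.loc[tab.medication == "b", "available"].iloc[0]
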