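"""Two-stage ITR estimator: propensities, surfaces, difference scores, rule."""

import numpy as np
import pytest

import rxrule
from rxrule.config import CovariateSpec, SimulationConfig
from rxrule.itr import (
    PropensityMatrix,
    build_itr,
    compute_difference_scores,
    eligible_arm_set,
    estimate_outcome_surfaces,
    estimate_propensities,
    fit_cate_models,
    make_rule,
    OutcomeSurfaces,
)
from rxrule.superlearner import LearnerSpec, fast_roster, linear_roster, predict_super_learner


def _uniform_two_arm(n=5000, seed=0):
    covs = (CovariateSpec("x1", "continuous", {"mean": 0.0, "sd": 1.0}),
            CovariateSpec("x2", "binary", {"p": 0.4}))
    return SimulationConfig(
        n_patients=n, arms=("a", "b"), covariates=covs,
        propensity_intercepts=(0.0, 0.0), propensity_coefficients=({}, {}),
        outcome_intercepts=(0.0, 0.0), outcome_main={"x1": -0.3},
        outcome_interactions=({}, {}), seed=seed)


class TestPropensities:
    def test_randomized_two_arm_fits_near_half(self):
        cfg = _uniform_two_arm(n=5000, seed=1)
        X = rxrule.generate_covariates(cfg)
        arms, _ = rxrule.assign_treatments(cfg, X)
        g = estimate_propensities(X.to_numpy(), arms, fast_roster(), 2, seed=1)
        assert g.raw.min() >= 0.45 - 1e-9
        assert g.raw.max() <= 0.55 + 1e-9

    def test_rows_sum_to_one_pre_truncation(self, default_run):
        g = default_run["fit"].g
        assert np.allclose(g.raw.sum(axis=1), 1.0, atol=1e-8)

    def test_truncation_clips_and_counts(self):
        # strongly separated arms force fitted propensities below the bound
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.normal(size=(n, 1))
        arms = (x[:, 0] > 0).astype(np.int64)
        g = estimate_propensities(x, arms, fast_roster(), 2, seed=3, truncation=0.01)
        assert g.truncated_count > 0
        assert g.values.min() >= 0.01 - 1e-12
        assert g.raw.min() < 0.01  # raw keeps the unclipped probabilities

    def test_single_arm_rejected(self):
        x = np.zeros((50, 1))
        with pytest.raises(ValueError):
            estimate_propensities(x, np.zeros(50, dtype=int), fast_roster(), 2)

    def test_invalid_truncation_bound(self):
        raw = np.full((4, 4), 0.25)
        with pytest.raises(ValueError):
            PropensityMatrix(values=raw, raw=raw, truncation_bound=0.3,
                             truncated_count=0)


class TestOutcomeSurfaces:
    def test_degenerate_all_success(self):
        x = np.random.default_rng(0).normal(size=(100, 2))
        arms = np.random.default_rng(1).integers(0, 2, 100)
        with pytest.warns(UserWarning, match="degenerate"):
            s = estimate_outcome_surfaces(x, arms, np.ones(100), fast_roster(), 2)
        assert np.all(s.Q == 1.0) and np.all(s.m == 1.0)

    def test_surfaces_track_truth(self, default_run):
        # mean absolute error of the fitted arm-specific success surface
        truth = default_run["truth"]
        mu = truth.true_success_probs[default_run["train_ids"]]
        mae = np.abs(default_run["fit"].surfaces.Q - mu).mean()
        assert mae <= 0.05

    def test_population_surface_matches_mixture_identity(self, default_run):
        # m(x) should approximate sum_a g_a(x) Q_a(x)
        fit = default_run["fit"]
        mixture = (fit.g.raw * fit.surfaces.Q).sum(axis=1)
        assert np.abs(fit.surfaces.m - mixture).mean() <= 0.05


class TestDifferenceScores:
    def _manual(self, n=6, K=3, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n).astype(float)
        arms = rng.integers(0, K, n)
        raw = rng.dirichlet(np.ones(K), size=n)
        g = PropensityMatrix(values=np.clip(raw, 0.05, None), raw=raw,
                             truncation_bound=0.05, truncated_count=0)
        Q = rng.random((n, K))
        m = rng.random(n)
        return y, arms, g, OutcomeSurfaces(Q=Q, m=m)

    def test_exact_cancellation(self):
        n, K = 8, 3
        c = 0.4
        raw = np.full((n, K), 1 / K)
        g = PropensityMatrix(values=raw, raw=raw, truncation_bound=0.01,
                             truncated_count=0)
        surf = OutcomeSurfaces(Q=np.full((n, K), c), m=np.full(n, c))
        D = compute_difference_scores(np.full(n, c), np.zeros(n, dtype=int), g, surf)
        assert np.allclose(D, 0.0)

    def test_plug_in_single_patient(self):
        raw = np.array([[1.0, 0.0]])
        g = PropensityMatrix(values=np.clip(raw, 0.01, None), raw=raw,
                             truncation_bound=0.01, truncated_count=0)
        surf = OutcomeSurfaces(Q=np.array([[0.0, 0.3]]), m=np.array([0.0]))
        D = compute_difference_scores(np.array([1.0]), np.array([0]), g, surf)
        assert D[0, 0] == pytest.approx(1.0)

    def test_aipw_matches_formula(self):
        y, arms, g, surf = self._manual()
        D = compute_difference_scores(y, arms, g, surf)
        n, K = surf.Q.shape
        for i in range(n):
            for a in range(K):
                expected = surf.Q[i, a] - surf.m[i]
                if arms[i] == a:
                    expected += (y[i] - surf.Q[i, a]) / g.values[i, a]
                assert D[i, a] == pytest.approx(expected, abs=1e-12)

    def test_column_means_unbiased_with_true_nuisances(self):
        # Monte-Carlo check of the augmented estimator's unbiasedness
        cfg = rxrule.default_config(n_patients=30_000, seed=31)
        X = rxrule.generate_covariates(cfg)
        arms, g_true = rxrule.assign_treatments(cfg, X)
        y, mu, _ = rxrule.simulate_outcomes(cfg, X, arms)
        m_true = (g_true * mu).sum(axis=1)
        g = PropensityMatrix(values=np.clip(g_true, 0.01, None), raw=g_true,
                             truncation_bound=0.01, truncated_count=0)
        D = compute_difference_scores(y, arms, g, OutcomeSurfaces(Q=mu, m=m_true))
        target = mu.mean(axis=0) - m_true.mean()
        mc_se = D.std(axis=0) / np.sqrt(len(y))
        assert np.all(np.abs(D.mean(axis=0) - target) < 3 * mc_se)


class TestCateAndRule:
    def test_constant_column_predicts_constant(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 3))
        D = np.column_stack([np.full(200, 0.25), rng.normal(size=200)])
        fits = fit_cate_models(X, D, linear_roster(), n_folds=5, seed=1)
        pred = predict_super_learner(fits[0], X)
        assert np.allclose(pred, 0.25, atol=1e-8)

    def test_fitted_difference_monotone_in_driving_covariate(self):
        # one continuous covariate drives the only interaction
        covs = (CovariateSpec("x1", "continuous", {"mean": 0.0, "sd": 1.0}),
                CovariateSpec("x2", "binary", {"p": 0.5}))
        cfg = SimulationConfig(
            n_patients=20_000, arms=("a", "b"), covariates=covs,
            propensity_intercepts=(0.0, 0.0), propensity_coefficients=({}, {}),
            outcome_intercepts=(0.0, 0.0), outcome_main={},
            outcome_interactions=({"x1": 0.5}, {}), seed=7)
        X = rxrule.generate_covariates(cfg)
        arms, g_true = rxrule.assign_treatments(cfg, X)
        y, mu, _ = rxrule.simulate_outcomes(cfg, X, arms)
        m_true = (g_true * mu).sum(axis=1)
        g = PropensityMatrix(values=np.clip(g_true, 0.01, None), raw=g_true,
                             truncation_bound=0.01, truncated_count=0)
        D = compute_difference_scores(y, arms, g, OutcomeSurfaces(Q=mu, m=m_true))
        fits = fit_cate_models(X.to_numpy(), D, linear_roster(), seed=2)
        lo, hi = np.quantile(X["x1"], [0.1, 0.9])
        grid = np.column_stack([np.linspace(lo, hi, 25), np.full(25, 0.5)])
        pred = predict_super_learner(fits[0], grid)
        assert pred[-1] > pred[0]
        assert np.all(np.diff(pred) > -1e-6)

    def test_antisymmetric_two_arm_scenario(self):
        # mu_1 - m = -(mu_2 - m) by construction; fitted surfaces mirror it
        covs = (CovariateSpec("x1", "binary", {"p": 0.5}),
                CovariateSpec("x2", "continuous", {"mean": 0.0, "sd": 1.0}))
        cfg = SimulationConfig(
            n_patients=20_000, arms=("a", "b"), covariates=covs,
            propensity_intercepts=(0.0, 0.0), propensity_coefficients=({}, {}),
            outcome_intercepts=(0.0, 0.0), outcome_main={},
            outcome_interactions=({"x1": 0.4}, {"x1": -0.4}), seed=9)
        X = rxrule.generate_covariates(cfg)
        arms, _ = rxrule.assign_treatments(cfg, X)
        y, _, _ = rxrule.simulate_outcomes(cfg, X, arms)
        fit = rxrule.fit_itr(X.to_numpy(), arms, y, 2, roster=fast_roster(), seed=3)
        f1 = predict_super_learner(fit.cate_fits[0], X.to_numpy())
        f2 = predict_super_learner(fit.cate_fits[1], X.to_numpy())
        assert np.corrcoef(f1, -f2)[0, 1] >= 0.8

    def test_tie_break_lowest_arm_index(self):
        class _Const:
            def __init__(self, c):
                self.c = c

            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.full(len(X), self.c)

        from rxrule.superlearner import fit_super_learner
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        same = [fit_super_learner(X, y, [LearnerSpec("c", lambda s: _Const(0.3))],
                                  n_folds=4, task="unbounded") for _ in range(3)]
        rule = build_itr([None, same[0], None, None, same[1]], 5)
        rec = rule.recommend(X)
        assert np.all(rec == 1)  # exact tie between arms 1 and 4 -> arm 1

    def test_rule_stays_in_eligible_set(self, default_run):
        rec = default_run["ev"]["recommended_arms"]
        assert set(np.unique(rec)) <= set(default_run["fit"].eligible_arms.tolist())

    def test_rule_recovers_oracle(self, default_run):
        rec = default_run["ev"]["recommended_arms"]
        oracle = default_run["truth"].oracle_arm[default_run["hold_ids"]]
        assert (rec == oracle).mean() >= 0.85


class TestMakeRule:
    def test_static(self):
        rule = make_rule("static", 5, 3)
        assert np.all(rule.recommend(np.zeros((7, 2))) == 3)

    def test_static_out_of_range(self):
        with pytest.raises(ValueError):
            make_rule("static", 5, 5)

    def test_stochastic_uniform_and_proportional(self):
        r = make_rule("stochastic", 15, np.full(15, 1 / 15))
        assert np.allclose(r.weights, 1 / 15)
        shares = np.array([0.069, 0.101, 0.298, 0.532])
        r2 = make_rule("stochastic", 4, shares / shares.sum())
        assert np.allclose(r2.weights, shares / shares.sum())

    def test_stochastic_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            make_rule("stochastic", 3, np.array([0.5, 0.6, 0.1]))
        with pytest.raises(ValueError):
            make_rule("stochastic", 3, np.array([0.7, 0.4, -0.1]))

    def test_factual_returns_observed(self):
        rule = make_rule("factual", 4)
        arms = np.array([0, 3, 1])
        assert np.array_equal(rule.recommend(np.zeros((3, 1)), observed_arms=arms), arms)


def test_eligible_arm_set_threshold():
    arms = np.array([0] * 50 + [1] * 3 + [2] * 40)
    with pytest.warns(UserWarning, match="support"):
        keep = eligible_arm_set(arms, 4, min_support=10)
    assert keep.tolist() == [0, 2]
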