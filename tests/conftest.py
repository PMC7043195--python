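import numpy as np
import pytest
from hypothesis import settings

import rxrule

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from rxrule.cohort import OutcomeDefinition, build_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A modest default-scenario cohort shared by estimator tests."""
    cfg = rxrule.default_config(n_patients=4000, seed=11)
    patients, events, truth = rxrule.generate_raw_records(cfg)
    return cfg, patients, events, truth


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    cfg, patients, events, truth = small_sim
    cohort = build_cohort(patients, events, cfg.covariate_names, list(cfg.arms),
                          OutcomeDefinition(), train_fraction=0.7, seed=17)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def default_run():
    """One full default-scenario analysis (n=20 000, default roster),
    shared by the rule-recovery and value-comparison tests."""
    import warnings

    from rxrule.pipeline import evaluate_rules, fit_itr

    cfg = rxrule.default_config(n_patients=20_000, seed=101)
    patients, events, truth = rxrule.generate_raw_records(cfg)
    cohort = build_cohort(patients, events, cfg.covariate_names, list(cfg.arms),
                          OutcomeDefinition(), train_fraction=0.7, seed=107)
    train, hold = cohort.part("train"), cohort.part("holdout")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_itr(train.X, train.arms, train.outcome, cfg.n_arms, seed=101)
        ev = evaluate_rules(hold.X, hold.arms, hold.outcome, fit.rule, cfg.n_arms,
                            seed=113)
    ids = cohort.patients["patient_id"].to_numpy()
    return {
        "cfg": cfg, "truth": truth, "cohort": cohort,
        "train": train, "hold": hold, "fit": fit, "ev": ev,
        "train_ids": ids[cohort.split == "train"],
        "hold_ids": ids[cohort.split == "holdout"],
    }


@pytest.fixture(scope="session")
def regression_task():
    """A small linear-signal regression task for Super Learner tests."""
    rng = np.random.default_rng(42)
    n, p = 600, 4
    X = rng.normal(size=(n, p))
    beta = np.array([1.0, -0.5, 0.25, 0.0])
    y = X @ beta + rng.normal(scale=0.5, size=n)
    return X, y
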