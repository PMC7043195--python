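"""Synthetic claims-like cohort generator with known ground truth.

Every downstream stage (eligibility filtering, outcome labeling, the
two-stage ITR estimator, TMLE evaluation, permutation importance) is
exercised against cohorts produced here, for which the true assignment
propensities g_a(x), the true arm-specific success probabilities mu_a(x),
the oracle rule argmax_a mu_a(x), and the oracle value E[max_a mu_a(X)]
are all available in closed form.

Event streams are generated to be *consistent by construction* with the
binary success label: a failure carries at least one failure-triggering
event (hospitalization of either kind, medication switch or addition, or
inpatient death) inside the 12-month window, a success carries none.
Discontinuation events are sprinkled independently of the label, since the
primary outcome definition deliberately ignores them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig

# Event vocabulary shared with the cohort pipeline.
FAILURE_EVENTS = (
    "hospitalization_psychiatric",
    "hospitalization_other",
    "med_switch",
    "med_addition",
    "inpatient_death",
)
EVENT_TYPES = FAILURE_EVENTS + ("discontinuation",)

# Relative frequencies of the *first* failure-triggering event for a failed
# treatment episode: treatment change is the most common failure mode in
# first-episode cohorts, inpatient death the rarest.
_FAILURE_MIX = np.array([0.30, 0.18, 0.28, 0.18, 0.06])
_DISCONTINUATION_RATE = 0.30

SECOND_LINE_REGIMENS = ("clozapine", "polypharmacy", "long_acting_injectable")


@dataclass
class GroundTruth:
    """Exact simulation-level quantities the estimators try to recover."""

    true_propensities: np.ndarray  # n x K, rows sum to 1
    true_success_probs: np.ndarray  # n x K, mu_a(x_i)
    oracle_arm: np.ndarray  # n, argmax_a mu_a(x_i)
    oracle_value: float  # mean_i max_a mu_a(x_i)

    def __post_init__(self) -> None:
        row = self.true_propensities.sum(axis=1)
        if self.true_propensities.size and not np.allclose(row, 1.0, atol=1e-10):
            raise ValueError("propensity rows must sum to 1")


def standardize(config: SimulationConfig, X: pd.DataFrame) -> np.ndarray:
    """Standardize covariates by their analytic distribution moments."""
    cols = []
    for spec in config.covariates:
        m, s = spec.moments()
        cols.append((X[spec.name].to_numpy(dtype=float) - m) / s)
    return np.column_stack(cols) if cols else np.empty((len(X), 0))


def generate_covariates(config: SimulationConfig, n: int | None = None,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the baseline covariate table (n x p), deterministic given seed."""
    n = config.n_patients if n is None else n
    rng = np.random.default_rng(config.seed) if rng is None else rng
    data = {}
    for spec in config.covariates:
        if n == 0:
            data[spec.name] = np.array([], dtype=float)
        elif spec.kind == "binary":
            data[spec.name] = rng.binomial(1, spec.params["p"], size=n).astype(float)
        elif spec.kind == "count":
            data[spec.name] = rng.poisson(spec.params["lam"], size=n).astype(float)
        elif "low" in spec.params:
            data[spec.name] = rng.uniform(spec.params["low"], spec.params["high"], size=n)
        else:
            data[spec.name] = rng.normal(spec.params["mean"], spec.params["sd"], size=n)
    return pd.DataFrame(data, columns=config.covariate_names)


def true_propensity_matrix(config: SimulationConfig, X: pd.DataFrame) -> np.ndarray:
    """Softmax of per-arm linear scores on standardized covariates."""
    Z = standardize(config, X)
    B = config.coefficient_matrix(config.propensity_coefficients)
    scores = Z @ B.T + np.asarray(config.propensity_intercepts)
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=1, keepdims=True)


def assign_treatments(config: SimulationConfig, X: pd.DataFrame,
                      seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Draw one arm per patient from the softmax propensities.

    Returns (arms, true_propensities) with arms as 0-based indices into
    config.arms and the exact softmax probabilities used for the draw.
    """
    if config.n_arms < 2:
        raise ConfigurationError("treatment assignment requires at least 2 arms")
    g = true_propensity_matrix(config, X)
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    u = rng.random(len(X))
    arms = (g.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return arms.astype(np.int64), g


def true_success_matrix(config: SimulationConfig, X: pd.DataFrame) -> np.ndarray:
    """mu_a(x) for every patient and arm (expit of logit-scale model)."""
    Z = standardize(config, X)
    beta = np.zeros(Z.shape[1])
    names = config.covariate_names
    for k, v in config.outcome_main.items():
        beta[names.index(k)] = v
    G = config.coefficient_matrix(config.outcome_interactions)
    logits = (Z @ beta)[:, None] + Z @ G.T + np.asarray(config.outcome_intercepts)
    return 1.0 / (1.0 + np.exp(-logits))


def _draw_event_streams(y: np.ndarray, patient_ids: np.ndarray,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Build the event table consistent with the success labels."""
    pid, etype, month = [], [], []
    n = len(y)
    fail_idx = np.flatnonzero(y == 0)
    # primary failure event
    kinds = rng.choice(len(FAILURE_EVENTS), size=len(fail_idx), p=_FAILURE_MIX)
    months = 12.0 * (1.0 - rng.random(len(fail_idx)))  # in (0, 12]
    pid.extend(patient_ids[fail_idx])
    etype.extend(FAILURE_EVENTS[k] for k in kinds)
    month.extend(months)
    # occasional second failure event
    extra = fail_idx[rng.random(len(fail_idx)) < 0.25]
    kinds2 = rng.choice(len(FAILURE_EVENTS), size=len(extra), p=_FAILURE_MIX)
    pid.extend(patient_ids[extra])
    etype.extend(FAILURE_EVENTS[k] for k in kinds2)
    month.extend(12.0 * (1.0 - rng.random(len(extra))))
    # discontinuation, independent of the label
    disc = np.flatnonzero(rng.random(n) < _DISCONTINUATION_RATE)
    pid.extend(patient_ids[disc])
    etype.extend(["discontinuation"] * len(disc))
    month.extend(12.0 * (1.0 - rng.random(len(disc))))
    ev = pd.DataFrame({"patient_id": pid, "event_type": etype, "month": month})
    return ev.sort_values(["patient_id", "month"], kind="stable").reset_index(drop=True)


def simulate_outcomes(config: SimulationConfig, X: pd.DataFrame, arms: np.ndarray,
                      seed: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Draw success labels and matching event streams.

    Y_i ~ Bernoulli(mu_{A_i}(x_i)); the returned event table reproduces the
    labels exactly under the primary outcome definition.
    """
    mu = true_success_matrix(config, X)
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    p_assigned = mu[np.arange(len(X)), arms] if len(X) else np.array([])
    y = (rng.random(len(X)) < p_assigned).astype(np.int64)
    events = _draw_event_streams(y, np.arange(len(X), dtype=np.int64), rng)
    return y, mu, events


def generate_raw_records(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Full raw-record generator: eligible cohort plus labeled decoys.

    Returns (patients, events, truth). `patients` carries the eligibility
    fields the cohort filters test (age, first_regimen, first_rx_inpatient)
    and ground-truth columns `eligible` / `exclusion_class`; decoys violate
    exactly one eligibility rule each. `truth` covers the eligible rows, in
    order, so estimator tests can align to it after filtering.
    """
    n = config.n_patients
    X = generate_covariates(config)
    arms, g = assign_treatments(config, X)
    y, mu, events = simulate_outcomes(config, X, arms)
    oracle_arm = mu.argmax(axis=1) if n else np.array([], dtype=np.int64)
    oracle_value = float(mu.max(axis=1).mean()) if n else float("nan")
    truth = GroundTruth(g, mu, oracle_arm, oracle_value)

    patients = X.copy()
    patients.insert(0, "patient_id", np.arange(n, dtype=np.int64))
    patients["arm"] = arms
    patients["medication"] = [config.arms[a] for a in arms]
    patients["first_regimen"] = patients["medication"]
    patients["first_rx_inpatient"] = False
    patients["outcome"] = y
    patients["eligible"] = True
    patients["exclusion_class"] = ""

    if config.decoy_fraction > 0.0 and n > 0:
        n_decoy = int(round(config.decoy_fraction / (1.0 - config.decoy_fraction) * n)) \
            if config.decoy_fraction < 1.0 else n
        rng = np.random.default_rng(config.seed + 3)
        dX = generate_covariates(config, n=n_decoy, rng=rng)
        decoys = dX.copy()
        decoys.insert(0, "patient_id", np.arange(n, n + n_decoy, dtype=np.int64))
        d_arms = rng.integers(0, config.n_arms, size=n_decoy)
        decoys["arm"] = d_arms
        decoys["medication"] = [config.arms[a] for a in d_arms]
        decoys["first_regimen"] = decoys["medication"]
        decoys["first_rx_inpatient"] = False
        decoys["outcome"] = rng.integers(0, 2, size=n_decoy)
        decoys["eligible"] = False
        classes = ("age_low", "age_high", "second_line", "inpatient_start")
        cls = [classes[i % len(classes)] for i in range(n_decoy)]
        decoys["exclusion_class"] = cls
        for i, c in enumerate(cls):
            if c == "age_low":
                decoys.loc[decoys.index[i], "age"] = float(rng.integers(5, 16))
            elif c == "age_high":
                decoys.loc[decoys.index[i], "age"] = float(rng.integers(75, 95))
            elif c == "second_line":
                reg = SECOND_LINE_REGIMENS[int(rng.integers(0, len(SECOND_LINE_REGIMENS)))]
                decoys.loc[decoys.index[i], "first_regimen"] = reg
                decoys.loc[decoys.index[i], "medication"] = reg
            else:
                decoys.loc[decoys.index[i], "first_rx_inpatient"] = True
        patients = pd.concat([patients, decoys], ignore_index=True)

    return patients, events, truth


def oracle_rule_value(truth: GroundTruth, rule) -> float:
    """True mean success probability if every patient followed `rule`.

    `rule` may be a per-patient array of 0-based arm indices, a weight
    vector over the K arms (stochastic rule), or an object exposing either
    `weights` or `recommend(...)`/an array via numpy coercion.
    """
    mu = truth.true_success_probs
    n, K = mu.shape
    w = getattr(rule, "weights", None)
    if w is not None:
        w = np.asarray(w, dtype=float)
        if w.shape != (K,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("stochastic rule weights must lie on the K-simplex")
        return float((mu @ w).mean())
    arms = np.asarray(rule, dtype=np.int64)
    if arms.shape == ():  # single static arm
        arms = np.full(n, int(arms))
    if arms.shape != (n,):
        raise ValueError("rule must give one arm per patient")
    if n and (arms.min() < 0 or arms.max() >= K):
        raise ValueError("rule recommends an arm outside [0, K)")
    return float(mu[np.arange(n), arms].mean())
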