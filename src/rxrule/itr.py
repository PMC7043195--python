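"""Two-stage estimation of the individualized treatment rule (ITR).

Stage 1 estimates the nuisances on the training sample with Super
Learners: one-vs-rest assignment propensities g_a(x) for each of the K
medications (rows renormalized to sum to one, then clipped below at a
truncation bound delta for use in inverse weights), the arm-specific
success surfaces Q_a(x) from a single fit on (x, arm indicators), and the
population success surface m(x) from a fit on x alone.

Stage 2 forms, for every patient i and arm a, the doubly robust (AIPW)
difference score

    D_ia = 1{A_i = a} / g_a(x_i) * (Y_i - Q_a(x_i)) + Q_a(x_i) - m(x_i),

an approximately unbiased estimate of mu_a(x_i) - m(x_i), and regresses
each column on x with an unbounded-task Super Learner. The learned rule
recommends, for each patient, the eligible arm with the highest fitted
difference score (ties broken by the configured medication order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .superlearner import (
    LearnerSpec,
    SuperLearnerFit,
    fit_super_learner,
    make_cv_folds,
    predict_super_learner,
)

DEFAULT_TRUNCATION = 0.01


@dataclass
class PropensityMatrix:
    """Per-patient, per-arm assignment probabilities with truncation metadata."""

    values: np.ndarray  # n x K, truncated (every cell >= delta)
    raw: np.ndarray  # n x K, renormalized pre-truncation (rows sum to 1)
    truncation_bound: float
    truncated_count: int
    fits: list | None = None  # one SuperLearnerFit per arm, if fitted

    def __post_init__(self) -> None:
        K = self.raw.shape[1]
        if not 0.0 < self.truncation_bound < 1.0 / K:
            raise ValueError("truncation bound must lie in (0, 1/K)")
        if self.raw.size and not np.allclose(self.raw.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("pre-truncation propensity rows must sum to 1")
        if self.values.size and self.values.min() < self.truncation_bound - 1e-12:
            raise ValueError("truncated propensities must be >= the bound")


@dataclass
class OutcomeSurfaces:
    """Estimated success probabilities under each arm and in the population."""

    Q: np.ndarray  # n x K
    m: np.ndarray  # n
    q_fit: SuperLearnerFit | None = None
    m_fit: SuperLearnerFit | None = None


@dataclass
class TreatmentRule:
    """A treatment policy: learned argmax, static arm, stochastic, or factual."""

    kind: str  # learned | static | stochastic | factual
    n_arms: int
    arm: int | None = None  # static
    weights: np.ndarray | None = None  # stochastic
    cate_fits: list | None = None  # learned: one fit per arm (None if ineligible)
    eligible_arms: np.ndarray | None = None  # learned

    def recommend(self, X: np.ndarray, observed_arms: np.ndarray | None = None) -> np.ndarray:
        """Per-patient 0-based recommended arm (deterministic kinds only)."""
        X = np.asarray(X, dtype=float)
        n = len(X)
        if self.kind == "static":
            return np.full(n, self.arm, dtype=np.int64)
        if self.kind == "factual":
            if observed_arms is None:
                raise ValueError("factual rule needs the observed arms")
            return np.asarray(observed_arms, dtype=np.int64)
        if self.kind == "learned":
            scores = self.decision_scores(X)
            # argmax over eligible arms; ineligible columns are -inf.
            # np.argmax takes the first maximum -> lowest arm index on ties.
            return scores.argmax(axis=1).astype(np.int64)
        raise ValueError(f"rule of kind {self.kind!r} has no deterministic recommendation")

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Fitted difference scores per arm (-inf for ineligible arms)."""
        if self.kind != "learned":
            raise ValueError("decision scores exist only for learned rules")
        n = len(X)
        scores = np.full((n, self.n_arms), -np.inf)
        for a in range(self.n_arms):
            if self.cate_fits[a] is not None:
                scores[:, a] = predict_super_learner(self.cate_fits[a], X)
        return scores


def estimate_propensities(
    X: np.ndarray,
    arms: np.ndarray,
    roster: list[LearnerSpec],
    n_arms: int,
    n_folds: int = 10,
    seed: int = 0,
    truncation: float = DEFAULT_TRUNCATION,
    folds: np.ndarray | None = None,
) -> PropensityMatrix:
    """One-vs-rest Super Learner propensities, renormalized then truncated.

    Clipping at `truncation` applies only to the stored inverse-weight
    matrix (`values`); the renormalized probabilities are kept in `raw`.
    """
    X = np.asarray(X, dtype=float)
    arms = np.asarray(arms, dtype=np.int64)
    if len(np.unique(arms)) < 2:
        raise ValueError("propensity estimation requires >= 2 arms present")
    n = len(arms)
    if folds is None:
        folds = make_cv_folds(n, n_folds, seed, stratify_labels=arms)
    G = np.zeros((n, n_arms))
    fits = []
    for a in range(n_arms):
        ind = (arms == a).astype(float)
        if ind.sum() == 0:
            warnings.warn(f"arm {a} has no training patients; propensity fixed at 0",
                          stacklevel=2)
            fits.append(None)
            continue
        fit = fit_super_learner(X, ind, roster, n_folds=n_folds,
                                seed=seed + 17 * (a + 1), task="bounded", folds=folds)
        fits.append(fit)
        G[:, a] = predict_super_learner(fit, X)
    rowsum = G.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    raw = G / rowsum
    values = np.clip(raw, truncation, None)
    truncated = int((raw < truncation).sum())
    return PropensityMatrix(values=values, raw=raw, truncation_bound=truncation,
                            truncated_count=truncated, fits=fits)


def estimate_outcome_surfaces(
    X: np.ndarray,
    arms: np.ndarray,
    y: np.ndarray,
    roster: list[LearnerSpec],
    n_arms: int,
    n_folds: int = 10,
    seed: int = 0,
    folds: np.ndarray | None = None,
) -> OutcomeSurfaces:
    """Q_a(x) from one fit on (x, arm dummies) evaluated at each arm; m(x) on x alone."""
    X = np.asarray(X, dtype=float)
    arms = np.asarray(arms, dtype=np.int64)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if folds is None:
        folds = make_cv_folds(n, n_folds, seed, stratify_labels=y.astype(int))
    if len(np.unique(y)) == 1:
        warnings.warn("degenerate outcome (constant); surfaces are constant",
                      stacklevel=2)
        c = float(y[0])
        return OutcomeSurfaces(Q=np.full((n, n_arms), c), m=np.full(n, c))
    dummies = np.eye(n_arms)[arms]
    XA = np.column_stack([X, dummies])
    q_fit = fit_super_learner(XA, y, roster, n_folds=n_folds, seed=seed + 101,
                              task="bounded", folds=folds)
    Q = np.empty((n, n_arms))
    for a in range(n_arms):
        cf = np.column_stack([X, np.tile(np.eye(n_arms)[a], (n, 1))])
        Q[:, a] = predict_super_learner(q_fit, cf)
    m_fit = fit_super_learner(X, y, roster, n_folds=n_folds, seed=seed + 202,
                              task="bounded", folds=folds)
    m = predict_super_learner(m_fit, X)
    return OutcomeSurfaces(Q=Q, m=m, q_fit=q_fit, m_fit=m_fit)


def compute_difference_scores(
    y: np.ndarray,
    arms: np.ndarray,
    g: PropensityMatrix,
    surfaces: OutcomeSurfaces,
    augmented: bool = True,
) -> np.ndarray:
    """AIPW difference scores D (n x K); plug-in Q_a - m when augmented=False."""
    y = np.asarray(y, dtype=float)
    arms = np.asarray(arms, dtype=np.int64)
    n, K = surfaces.Q.shape
    D = surfaces.Q - surfaces.m[:, None]
    if augmented:
        if g.values.min() < g.truncation_bound - 1e-12:
            raise RuntimeError("propensity matrix contains cells below the truncation bound")
        ind = np.zeros((n, K))
        ind[np.arange(n), arms] = 1.0
        D = D + ind / g.values * (y[:, None] - surfaces.Q)
    if not np.all(np.isfinite(D)):
        raise RuntimeError("difference scores must be finite")
    return D


def fit_cate_models(
    X: np.ndarray,
    D: np.ndarray,
    roster: list[LearnerSpec],
    n_folds: int = 10,
    seed: int = 0,
    eligible_arms: np.ndarray | None = None,
    folds: np.ndarray | None = None,
) -> list:
    """One unbounded-task Super Learner per arm, regressing D[:, a] on X."""
    X = np.asarray(X, dtype=float)
    D = np.asarray(D, dtype=float)
    n, K = D.shape
    if eligible_arms is None:
        eligible_arms = np.arange(K)
    if folds is None:
        folds = make_cv_folds(n, n_folds, seed)
    fits: list = [None] * K
    for a in eligible_arms:
        fits[a] = fit_super_learner(X, D[:, a], roster, seed=seed + 31 * (a + 1),
                                    task="unbounded", folds=folds)
    return fits


def build_itr(cate_fits: list, n_arms: int) -> TreatmentRule:
    """Learned rule: argmax of fitted difference scores over eligible arms."""
    eligible = np.array([a for a in range(n_arms) if cate_fits[a] is not None])
    if len(eligible) == 0:
        raise ValueError("at least one eligible arm is required")
    return TreatmentRule(kind="learned", n_arms=n_arms, cate_fits=cate_fits,
                         eligible_arms=eligible)


def make_rule(kind: str, n_arms: int, parameter=None) -> TreatmentRule:
    """Static single-arm, stochastic (weights on the simplex), or factual rule."""
    if kind == "static":
        a = int(parameter)
        if not 0 <= a < n_arms:
            raise ValueError(f"static arm {a} outside [0, {n_arms})")
        return TreatmentRule(kind="static", n_arms=n_arms, arm=a)
    if kind == "stochastic":
        w = np.asarray(parameter, dtype=float)
        if w.shape != (n_arms,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("stochastic weights must be a length-K vector on the simplex")
        return TreatmentRule(kind="stochastic", n_arms=n_arms, weights=w)
    if kind == "factual":
        return TreatmentRule(kind="factual", n_arms=n_arms)
    raise ValueError(f"unknown rule kind {kind!r}")


def eligible_arm_set(arms: np.ndarray, n_arms: int, min_support: int = 1) -> np.ndarray:
    """Arms with at least `min_support` training patients."""
    counts = np.bincount(np.asarray(arms, dtype=np.int64), minlength=n_arms)
    keep = np.flatnonzero(counts >= min_support)
    if len(keep) < len(np.flatnonzero(counts)):
        dropped = [a for a in range(n_arms) if 0 < counts[a] < min_support]
        warnings.warn(f"arms {dropped} below the support minimum were dropped "
                      "from the eligible set", stacklevel=2)
    return keep
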