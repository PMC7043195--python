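"""Cross-validated stacking (Super Learner) under squared-error meta-loss.

Candidate learners produce out-of-fold predictions via V-fold
cross-validation; a convex weight vector over the candidates is then chosen
to minimize the cross-validated mean squared error of the weighted
prediction. Because every vertex of the simplex is a feasible weight
vector, the ensemble's CV risk can never exceed that of the best single
candidate — an inequality this implementation enforces exactly by
comparing the optimized point against all vertices and keeping the best.

Binary outcomes are fit as probability regressions under squared error
(the meta-criterion used throughout this pipeline), with final predictions
clipped to [0, 1] for bounded tasks. Second-stage difference-score targets
use the unbounded task and are never clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import minimize, nnls
from sklearn.base import clone
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.linear_model import Lasso, Ridge
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler


@dataclass(frozen=True)
class LearnerSpec:
    """A named candidate learner: `build(seed)` returns an unfitted estimator."""

    name: str
    build: Callable[[int], object]


def default_roster() -> list[LearnerSpec]:
    """Diverse default candidates: mean, L1/L2 GLMs, trees, kNN, splines."""
    return [
        LearnerSpec("mean", lambda s: DummyRegressor(strategy="mean")),
        LearnerSpec("ridge", lambda s: make_pipeline(StandardScaler(), Ridge(alpha=1.0))),
        LearnerSpec("lasso", lambda s: make_pipeline(
            StandardScaler(), Lasso(alpha=0.005, max_iter=20_000))),
        LearnerSpec("gbm", lambda s: HistGradientBoostingRegressor(
            max_depth=3, max_iter=300, learning_rate=0.1, random_state=s,
            early_stopping=True, n_iter_no_change=10, validation_fraction=0.15)),
        LearnerSpec("knn", lambda s: make_pipeline(
            StandardScaler(), KNeighborsRegressor(n_neighbors=50))),
        LearnerSpec("spline", lambda s: make_pipeline(
            StandardScaler(), SplineTransformer(n_knots=5, degree=3), Ridge(alpha=10.0))),
    ]


def fast_roster() -> list[LearnerSpec]:
    """Small roster for replicate-heavy simulations: mean, ridge, shallow trees."""
    return [
        LearnerSpec("mean", lambda s: DummyRegressor(strategy="mean")),
        LearnerSpec("ridge", lambda s: make_pipeline(StandardScaler(), Ridge(alpha=1.0))),
        LearnerSpec("gbm", lambda s: HistGradientBoostingRegressor(
            max_depth=2, max_iter=150, learning_rate=0.15, random_state=s,
            early_stopping=True, n_iter_no_change=10, validation_fraction=0.15)),
    ]


def linear_roster() -> list[LearnerSpec]:
    """Mean + ridge only; for null-calibration replicates."""
    return [
        LearnerSpec("mean", lambda s: DummyRegressor(strategy="mean")),
        LearnerSpec("ridge", lambda s: make_pipeline(StandardScaler(), Ridge(alpha=1.0))),
    ]


def make_cv_folds(n: int, n_folds: int = 10, seed: int = 0,
                  stratify_labels: np.ndarray | None = None) -> np.ndarray:
    """Per-observation fold ids in [0, n_folds); sizes differ by at most 1."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n < n_folds:
        raise ValueError(f"cannot make {n_folds} folds from {n} observations")
    X_dummy = np.zeros((n, 1))
    if stratify_labels is not None:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X_dummy, np.asarray(stratify_labels))
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X_dummy)
    folds = np.empty(n, dtype=np.int64)
    for v, (_, test_idx) in enumerate(splits):
        folds[test_idx] = v
    return folds


@dataclass
class SuperLearnerFit:
    learner_names: list[str]
    folds: np.ndarray
    cv_predictions: np.ndarray  # n x J out-of-fold predictions
    weights: np.ndarray  # convex, length J; failed learners get 0
    learner_risks: np.ndarray  # CV MSE per learner (nan for failed)
    ensemble_risk: float
    models: list  # refit on full data (None for failed learners)
    failed: np.ndarray  # bool per learner
    task: str  # "bounded" or "unbounded"
    n_features: int


def _simplex_weights(Z: np.ndarray, y: np.ndarray, ok: np.ndarray) -> np.ndarray:
    """CV-MSE-minimizing convex weights over the usable candidates.

    Candidates: normalized NNLS solution, an SLSQP polish of it, and each
    vertex; the minimizer among them is returned, so the meta-level oracle
    inequality holds exactly.
    """
    J = Z.shape[1]
    idx = np.flatnonzero(ok)
    Zu = Z[:, idx]
    risk = lambda w: float(np.mean((Zu @ w - y) ** 2))

    candidates = []
    for j in range(len(idx)):  # vertices
        e = np.zeros(len(idx))
        e[j] = 1.0
        candidates.append(e)
    w_nnls, _ = nnls(Zu, y)
    if w_nnls.sum() > 0:
        candidates.append(w_nnls / w_nnls.sum())
        res = minimize(
            risk, w_nnls / w_nnls.sum(), jac=lambda w: 2.0 * Zu.T @ (Zu @ w - y) / len(y),
            method="SLSQP",
            bounds=[(0.0, 1.0)] * len(idx),
            constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if res.success and np.all(res.x >= -1e-9):
            w = np.clip(res.x, 0.0, None)
            candidates.append(w / w.sum())
    best = min(candidates, key=risk)
    w_full = np.zeros(J)
    w_full[idx] = best
    return w_full


def fit_super_learner(
    X: np.ndarray,
    y: np.ndarray,
    roster: list[LearnerSpec],
    n_folds: int = 10,
    seed: int = 0,
    task: str = "bounded",
    folds: np.ndarray | None = None,
) -> SuperLearnerFit:
    """Fit the stacking ensemble.

    A learner that raises on any fold (or on the full-data refit) is
    dropped with a warning and receives weight zero rather than aborting
    the fit; at least one learner must survive.
    """
    if not roster:
        raise ValueError("roster must be nonempty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    n = len(y)
    if folds is None:
        folds = make_cv_folds(n, n_folds, seed)
    n_folds = int(folds.max()) + 1
    J = len(roster)
    Z = np.zeros((n, J))
    failed = np.zeros(J, dtype=bool)
    for j, spec in enumerate(roster):
        try:
            for v in range(n_folds):
                tr = folds != v
                est = spec.build(seed + 1000 * j)
                est.fit(X[tr], y[tr])
                Z[~tr, j] = est.predict(X[~tr])
            if not np.all(np.isfinite(Z[:, j])):
                raise FloatingPointError("non-finite fold predictions")
        except Exception as exc:  # noqa: BLE001 - any learner failure -> weight 0
            warnings.warn(f"learner {spec.name!r} failed and was dropped: {exc}",
                          stacklevel=2)
            failed[j] = True
            Z[:, j] = 0.0
    if failed.all():
        raise RuntimeError("every candidate learner failed")
    if task == "bounded":
        Z[:, ~failed] = np.clip(Z[:, ~failed], 0.0, 1.0)

    weights = _simplex_weights(Z, y, ~failed)
    learner_risks = np.full(J, np.nan)
    learner_risks[~failed] = np.mean((Z[:, ~failed] - y[:, None]) ** 2, axis=0)
    ensemble_risk = float(np.mean((Z @ weights - y) ** 2))

    models: list = [None] * J
    for j, spec in enumerate(roster):
        if failed[j] or weights[j] == 0.0:
            continue
        try:
            est = spec.build(seed + 1000 * j)
            est.fit(X, y)
            models[j] = est
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"learner {spec.name!r} failed on refit: {exc}", stacklevel=2)
            failed[j] = True
            weights[j] = 0.0
    if weights.sum() == 0:
        raise RuntimeError("no learner survived the full-data refit")
    weights = weights / weights.sum()

    return SuperLearnerFit(
        learner_names=[s.name for s in roster],
        folds=folds,
        cv_predictions=Z,
        weights=weights,
        learner_risks=learner_risks,
        ensemble_risk=ensemble_risk,
        models=models,
        failed=failed,
        task=task,
        n_features=X.shape[1],
    )


def predict_super_learner(fit: SuperLearnerFit, X_new: np.ndarray) -> np.ndarray:
    """Weighted combination of the refit learners; clipped for bounded tasks."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != fit.n_features:
        raise ValueError(
            f"expected {fit.n_features} features, got shape {X_new.shape}")
    out = np.zeros(len(X_new))
    for w, model in zip(fit.weights, fit.models):
        if w == 0.0 or model is None:
            continue
        pred = model.predict(X_new)
        if fit.task == "bounded":
            pred = np.clip(pred, 0.0, 1.0)
        out += w * pred
    if fit.task == "bounded":
        out = np.clip(out, 0.0, 1.0)
    return out


def cv_risk_table(fit: SuperLearnerFit):
    """Per-learner and ensemble CV risks with the fitted weights."""
    import pandas as pd

    rows = [
        {"learner": name, "weight": float(w), "cv_mse": float(r), "failed": bool(f)}
        for name, w, r, f in zip(
            fit.learner_names, fit.weights, fit.learner_risks, fit.failed)
    ]
    rows.append({"learner": "ensemble", "weight": 1.0,
                 "cv_mse": fit.ensemble_risk, "failed": False})
    return pd.DataFrame(rows)
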