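"""Permutation importance of prescriptive predictors.

For each second-stage (difference-score) model and each predictor, the
predictor's column is shuffled and the increase in prediction mean-squared
error against the difference-score targets is recorded, averaged over
repetitions. Large increases flag predictors the rule actually uses to
discriminate between medications; irrelevant predictors fluctuate around
zero (and may go slightly negative).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .superlearner import predict_super_learner


def permutation_importance(
    fit,
    X: np.ndarray,
    target: np.ndarray,
    predictor_names: list[str],
    n_repetitions: int = 20,
    seed: int = 0,
    arm_label: str | int = 0,
    max_rows: int | None = 5000,
) -> pd.DataFrame:
    """Mean MSE increase per predictor for one arm's difference-score model.

    Returns a long-format table (arm, predictor, baseline_mse,
    permuted_mse, increase, rank); ranks are 1..p by decreasing increase,
    ties broken by predictor order. When the sample exceeds `max_rows`,
    the MSE comparison runs on a seeded row subsample (the permutation
    null is unaffected; only Monte-Carlo resolution changes).
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    X = np.asarray(X, dtype=float)
    target = np.asarray(target, dtype=float)
    if max_rows is not None and len(X) > max_rows:
        idx = np.random.default_rng(seed + 999).choice(len(X), max_rows,
                                                       replace=False)
        X, target = X[idx], target[idx]
    n, p = X.shape
    if len(predictor_names) != p:
        raise ValueError("predictor_names must match the number of columns")
    baseline = float(np.mean((predict_super_learner(fit, X) - target) ** 2))
    rng = np.random.default_rng(seed)
    permuted = np.empty(p)
    for j in range(p):
        mses = np.empty(n_repetitions)
        for r in range(n_repetitions):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(n), j]
            mses[r] = np.mean((predict_super_learner(fit, Xp) - target) ** 2)
        permuted[j] = mses.mean()
    increase = permuted - baseline
    order = np.lexsort((np.arange(p), -increase))  # decreasing, stable in column order
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    return pd.DataFrame({
        "arm": arm_label,
        "predictor": predictor_names,
        "baseline_mse": baseline,
        "permuted_mse": permuted,
        "increase": increase,
        "rank": rank,
    })


def importance_report(
    cate_fits: list,
    X: np.ndarray,
    D: np.ndarray,
    predictor_names: list[str],
    arm_names: list[str],
    n_repetitions: int = 20,
    seed: int = 0,
    max_rows: int | None = 5000,
) -> pd.DataFrame:
    """Permutation importance for every eligible arm's second-stage model."""
    parts = []
    for a, fit in enumerate(cate_fits):
        if fit is None:
            continue
        parts.append(permutation_importance(
            fit, X, D[:, a], predictor_names, n_repetitions=n_repetitions,
            seed=seed + 7 * (a + 1), arm_label=arm_names[a], max_rows=max_rows))
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["arm", "predictor", "baseline_mse", "permuted_mse", "increase", "rank"])


def top_k_table(report: pd.DataFrame, k: int) -> pd.DataFrame:
    """The k predictors with the largest mean MSE increase, per arm."""
    if report.empty:
        return report.copy()
    return (report[report["rank"] <= k]
            .sort_values(["arm", "rank"], kind="stable")
            .reset_index(drop=True))
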