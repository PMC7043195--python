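"""Policy-value estimation by TMLE and the comparison/report arithmetic.

The value of a deterministic rule d is E[Y(d(X))], estimated on the
holdout sample by targeted minimum loss-based estimation: the outcome
surface Q(a, x) is fluctuated along the clever covariate

    H(a, x) = 1{a = d(x)} / g_{d(x)}(x)

on the logit scale, with the one-dimensional fluctuation parameter chosen
to solve the efficient-influence-curve score equation
sum_i H(A_i, x_i) (Y_i - Q*(A_i, x_i)) = 0. The point estimate is the mean
of Q*(d(x_i), x_i), and the standard error comes from the sample standard
deviation of the influence values

    IC_i = H(A_i, x_i)(Y_i - Q*(A_i, x_i)) + Q*(d(x_i), x_i) - value.

Stochastic allocation schemes (uniform randomization, randomization in the
observed prescription shares) are valued as weight-combinations of the
single-arm estimates, with influence values combined linearly so contrast
standard errors account for correlation on the shared holdout sample.

Report helpers reproduce the summary arithmetic of a comparative ITR
analysis: number needed to treat, proportional success ratios, prescribed
concordance ratios, and the decomposition of the ITR's aggregate gain into
per-medication contributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .itr import PropensityMatrix, TreatmentRule

_PCLIP = 1e-6  # keep logits finite
_SCORE_TOL = 1e-10


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RuleValueEstimate:
    """TMLE (or empirical) estimate of mean treatment success under a rule."""

    value: float
    se: float
    ci95: tuple[float, float]
    influence_values: np.ndarray
    n: int
    epsilon: float = 0.0
    score_residual: float = 0.0
    q_star_rule: np.ndarray | None = None  # per-patient Q*(d(x_i), x_i)

    @property
    def value_pct(self) -> float:
        return 100.0 * self.value


@dataclass
class RuleComparison:
    value_rule: float
    value_reference: float
    z: float
    p_one_sided: float
    se_contrast: float
    nnt: float
    proportional_ratio: float


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _PCLIP, 1.0 - _PCLIP)
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


def tmle_rule_value(
    y: np.ndarray,
    arms: np.ndarray,
    rule_arms: np.ndarray,
    g: PropensityMatrix,
    Q: np.ndarray,
    max_abs_eps: float = 100.0,
) -> RuleValueEstimate:
    """TMLE of the mean outcome under the deterministic rule `rule_arms`.

    `rule_arms` is the 0-based recommended arm per holdout patient; `g` and
    `Q` are nuisance estimates evaluated on the holdout covariates.
    """
    y = np.asarray(y, dtype=float)
    arms = np.asarray(arms, dtype=np.int64)
    rule_arms = np.asarray(rule_arms, dtype=np.int64)
    n, K = Q.shape
    if rule_arms.min() < 0 or rule_arms.max() >= K:
        raise ValueError("rule recommends an arm outside the arm set")
    idx = np.arange(n)
    g_rule = g.values[idx, rule_arms]  # truncated, so bounded away from 0
    follows = (arms == rule_arms).astype(float)
    H_obs = follows / g_rule  # H(A_i, x_i)
    H_rule = 1.0 / g_rule  # H(d(x_i), x_i)

    logit_Q_obs = _logit(Q[idx, arms])
    logit_Q_rule = _logit(Q[idx, rule_arms])

    def score(eps: float) -> float:
        q = _expit(logit_Q_obs + eps * H_obs)
        return float(np.sum(H_obs * (y - q)))

    if np.all(H_obs == 0.0):
        # nobody followed the rule: no targeting information, keep eps = 0
        eps = 0.0
    elif abs(score(0.0)) <= _SCORE_TOL:
        eps = 0.0
    else:
        lo, hi = -1.0, 1.0
        while score(lo) * score(hi) > 0:
            lo *= 2.0
            hi *= 2.0
            if hi > max_abs_eps:
                raise RuntimeError(
                    f"TMLE fluctuation did not bracket a root within |eps| <= {max_abs_eps}; "
                    f"score(0) = {score(0.0):.3g}, min g along rule = {g_rule.min():.3g}")
        eps = brentq(score, lo, hi, xtol=1e-12, maxiter=200)

    q_star_obs = _expit(logit_Q_obs + eps * H_obs)
    q_star_rule = _expit(logit_Q_rule + eps * H_rule)
    value = float(q_star_rule.mean())
    ic = H_obs * (y - q_star_obs) + q_star_rule - value
    se = float(ic.std(ddof=0) / np.sqrt(n))
    resid = float(np.sum(H_obs * (y - q_star_obs)))
    return RuleValueEstimate(
        value=value, se=se, ci95=(value - 1.96 * se, value + 1.96 * se),
        influence_values=ic, n=n, epsilon=float(eps), score_residual=resid,
        q_star_rule=q_star_rule,
    )


def stochastic_rule_value(static_estimates: dict[int, RuleValueEstimate],
                          weights: np.ndarray) -> RuleValueEstimate:
    """Value of a stochastic allocation as a weighted mix of single-arm TMLEs."""
    weights = np.asarray(weights, dtype=float)
    support = np.flatnonzero(weights > 0)
    missing = [int(a) for a in support if a not in static_estimates]
    if missing:
        raise ValueError(f"no static-arm estimate for arms {missing}")
    n = static_estimates[int(support[0])].n
    value = float(sum(weights[a] * static_estimates[int(a)].value for a in support))
    ic = np.zeros(n)
    for a in support:
        est = static_estimates[int(a)]
        if est.n != n:
            raise ValueError("all static estimates must share the holdout sample")
        ic += weights[a] * est.influence_values
    se = float(ic.std(ddof=0) / np.sqrt(n))
    return RuleValueEstimate(value=value, se=se,
                             ci95=(value - 1.96 * se, value + 1.96 * se),
                             influence_values=ic, n=n)


def observed_success_rate(y: np.ndarray) -> RuleValueEstimate:
    """Empirical holdout success rate with binomial-style standard error."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    p = float(y.mean())
    se = float(np.sqrt(p * (1.0 - p) / n))
    ic = y - p
    return RuleValueEstimate(value=p, se=se, ci95=(p - 1.96 * se, p + 1.96 * se),
                             influence_values=ic, n=n)


def compare_rules(est_rule: RuleValueEstimate, est_reference: RuleValueEstimate,
                  correlated: bool = True) -> RuleComparison:
    """One-sided comparison of two rule values on the same holdout sample."""
    diff = est_rule.value - est_reference.value
    if correlated:
        if est_rule.n != est_reference.n:
            raise ValueError("correlated contrast needs estimates on the same sample")
        ic = est_rule.influence_values - est_reference.influence_values
        se = float(ic.std(ddof=0) / np.sqrt(est_rule.n))
    else:
        se = float(np.sqrt(est_rule.se ** 2 + est_reference.se ** 2))
    if se == 0.0:
        if diff == 0.0:
            # identical estimates: no evidence either way
            return RuleComparison(est_rule.value, est_reference.value, 0.0, 0.5,
                                  0.0, float("nan"), float("nan"))
        raise ValueError("zero contrast variance with nonzero difference")
    z = diff / se
    p = float(1.0 - stats.norm.cdf(z))
    nnt_val = nnt(100.0 * est_rule.value, 100.0 * est_reference.value) if diff != 0 else float("nan")
    pr = proportional_ratio(100.0 * est_rule.value, 100.0 * est_reference.value) \
        if est_reference.value > 0 else float("nan")
    return RuleComparison(est_rule.value, est_reference.value, float(z), p,
                          se, nnt_val, pr)


def nnt(p_rule_pct: float, p_reference_pct: float) -> float:
    """Number needed to treat: 100 / (percentage-point difference), 1 decimal.

    The sign follows the direction of the difference, so a harmful rule
    yields a negative NNT.
    """
    diff = p_rule_pct - p_reference_pct
    if diff == 0.0:
        raise ValueError("NNT undefined for equal success rates")
    return _round_half_up(100.0 / diff, 1)


def proportional_ratio(p_rule_pct: float, p_reference_pct: float) -> float:
    """Ratio of success rates (1 + relative increase), 2 decimals."""
    if p_reference_pct <= 0.0:
        raise ValueError("reference rate must be positive")
    return _round_half_up(p_rule_pct / p_reference_pct, 2)


def concordance_ratio(pct_prescribed_when_recommended: float,
                      pct_prescribed_when_not: float) -> float:
    """Prescribed-share ratio for recommended vs non-recommended patients."""
    num, den = pct_prescribed_when_recommended, pct_prescribed_when_not
    if not (0.0 <= num <= 100.0 and 0.0 <= den <= 100.0):
        raise ValueError("inputs are percentages in [0, 100]")
    if num == 0.0:
        return 0.0
    if den == 0.0:
        raise ValueError("ratio undefined: nonzero numerator over zero denominator")
    return _round_half_up(num / den, 1)


def contribution_decomposition(success_rate_differences: np.ndarray,
                               counts_without_recommended: np.ndarray) -> np.ndarray:
    """Per-medication share (%) of the ITR's aggregate expected gain.

    contribution_m = 100 * diff_m * count_m / sum_m' diff_m' * count_m'.
    Negative contributions are legitimate (medications for which observed
    prescribing beat the rule).
    """
    d = np.asarray(success_rate_differences, dtype=float)
    c = np.asarray(counts_without_recommended, dtype=float)
    if d.shape != c.shape:
        raise ValueError("differences and counts must align")
    products = d * c
    total = products.sum()
    if total == 0.0:
        raise ValueError("contribution decomposition undefined: zero total product")
    return 100.0 * products / total


def distribution_table(arm_names: list[str],
                       counts_a: np.ndarray,
                       counts_b: np.ndarray | None = None,
                       labels: tuple[str, str] = ("observed", "recommended"),
                       ) -> tuple[pd.DataFrame, float, float]:
    """Per-arm counts and percentages (with SEs), plus a chi-square
    homogeneity test between the two distributions when both are given."""
    counts_a = np.asarray(counts_a, dtype=float)
    if counts_a.size == 0:
        return pd.DataFrame(), float("nan"), float("nan")
    rows = {"medication": list(arm_names)}
    for label, counts in ((labels[0], counts_a),) + (
            ((labels[1], np.asarray(counts_b, dtype=float)),) if counts_b is not None else ()):
        n = counts.sum()
        pct = 100.0 * counts / n if n else np.zeros_like(counts)
        se = 100.0 * np.sqrt(np.clip(pct / 100 * (1 - pct / 100), 0, None) / n) if n else pct
        rows[f"{label}_n"] = counts.astype(int)
        rows[f"{label}_pct"] = [_round_half_up(v, 1) for v in pct]
        rows[f"{label}_pct_se"] = [_round_half_up(v, 1) for v in se]
    table = pd.DataFrame(rows)
    chi2, p = float("nan"), float("nan")
    if counts_b is not None:
        cb = np.asarray(counts_b, dtype=float)
        keep = (counts_a + cb) > 0
        if np.array_equal(counts_a, cb):
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(np.vstack([counts_a[keep], cb[keep]]))
            chi2, p = float(chi2), float(p)
    return table, chi2, p


def medication_specific_summary(
    y: np.ndarray,
    arms: np.ndarray,
    rule_arms: np.ndarray,
    arm_names: list[str],
    static_estimates: dict[int, RuleValueEstimate],
    itr_estimate: RuleValueEstimate | None = None,
) -> pd.DataFrame:
    """Per-medication success summary on the holdout sample.

    Columns: observed success among recipients; TMLE-estimated success if
    everyone received the medication; the ITR-vs-static difference with a
    correlated-contrast SE; and the estimated/observed success over the
    subset of patients for whom the medication was recommended. Arms
    without a static estimate (too little support) are marked unavailable.
    """
    y = np.asarray(y, dtype=float)
    arms = np.asarray(arms, dtype=np.int64)
    rule_arms = np.asarray(rule_arms, dtype=np.int64)
    rows = []
    for a, name in enumerate(arm_names):
        rec = arms == a
        sub = rule_arms == a
        n_rec, n_sub = int(rec.sum()), int(sub.sum())
        obs = 100.0 * y[rec].mean() if n_rec else np.nan
        obs_se = 100.0 * np.sqrt(y[rec].mean() * (1 - y[rec].mean()) / n_rec) if n_rec else np.nan
        est = static_estimates.get(a)
        if est is None:
            est_all = est_all_se = diff = diff_se = np.nan
            available = False
        else:
            est_all = 100.0 * est.value
            est_all_se = 100.0 * est.se
            available = True
            if itr_estimate is not None:
                ic = itr_estimate.influence_values - est.influence_values
                diff = 100.0 * (itr_estimate.value - est.value)
                diff_se = 100.0 * float(ic.std(ddof=0) / np.sqrt(est.n))
            else:
                diff = diff_se = np.nan
        sub_obs = 100.0 * y[sub].mean() if n_sub else np.nan
        if est is not None and est.q_star_rule is not None and n_sub:
            sub_est = 100.0 * float(est.q_star_rule[sub].mean())
        else:
            sub_est = np.nan
        rows.append({
            "medication": name, "available": available,
            "n_recipients": n_rec, "obs_success_pct": obs, "obs_success_se": obs_se,
            "est_success_all_pct": est_all, "est_success_all_se": est_all_se,
            "itr_minus_static_pct": diff, "itr_minus_static_se": diff_se,
            "n_recommended": n_sub, "subset_obs_success_pct": sub_obs,
            "subset_est_success_pct": sub_est,
        })
    return pd.DataFrame(rows)
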