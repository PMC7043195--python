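"""Worked example on published summary statistics.

The headline arithmetic of a comparative ITR analysis — number needed to
treat, proportional success ratios, concordance ratios, and the
per-medication contribution decomposition — is fully determined by the
summary numbers such an analysis reports. This module packages, as plain
data, the printed summary inputs from a large national-claims
first-episode schizophrenia study (15 antipsychotics; 22 601-patient
training and 9 676-patient holdout samples) and recomputes every derived
quantity from them with the same report functions used on synthetic runs.

Only *inputs* are stored (rates, proportions, counts); every derived
number is computed at call time by :func:`worked_examples`.
"""

from __future__ import annotations

import numpy as np

from .value import concordance_ratio, contribution_decomposition, nnt, proportional_ratio

HOLDOUT_N = 9676
TRAIN_N = 22601

# Aggregate success rates (%) on the holdout sample under each allocation.
SUCCESS_RATES = {
    "itr": 51.7,
    "observed": 44.5,
    "uniform_randomization": 41.3,
    "proportional_randomization": 43.5,
}

# Sensitivity outcome definitions: (ITR rate %, observed rate %).
SENSITIVITY_RATES = {
    "psych_hosp_or_change": (54.0, 46.4),
    "psych_hosp_only": (86.9, 81.7),
    "change_only": (57.0, 49.5),
}

# Prescribed share (%) among patients for whom the medication was / was not
# recommended by the rule.
PRESCRIBED_SHARES = {
    "amisulpride": (7.8, 6.6),
    "aripiprazole": (7.6, 5.8),
    "chlorpromazine": (0.0, 1.1),
    "clothiapine": (0.0, 0.5),
    "flupentixol": (0.0, 1.6),
    "haloperidol": (3.2, 5.2),
    "olanzapine": (3.3, 4.5),
    "paliperidone": (0.8, 1.2),
    "quetiapine": (26.2, 9.7),
    "risperidone": (39.6, 28.8),
    "sulpiride": (27.6, 28.4),
    "thioridazine": (0.0, 0.0),
    "trifluoperazine": (1.8, 1.1),
    "ziprasidone": (0.0, 0.0),
    "zotepine": (4.1, 1.4),
}

# Per-medication (success-rate difference %, number of patients prescribed
# the medication without it being recommended): the inputs of the
# contribution decomposition over the 13 sufficiently prescribed drugs.
CONTRIBUTION_INPUTS = {
    "amisulpride": (3.8, 447),
    "aripiprazole": (5.4, 380),
    "chlorpromazine": (28.1, 103),
    "flupentixol": (14.2, 158),
    "haloperidol": (1.8, 501),
    "olanzapine": (10.3, 417),
    "paliperidone": (20.3, 109),
    "quetiapine": (-4.5, 903),
    "risperidone": (-1.8, 2482),
    "sulpiride": (5.4, 2718),
    "trifluoperazine": (16.4, 100),
    "ziprasidone": (14.7, 101),
    "zotepine": (23.7, 128),
}

# Holdout counts: recommended by the rule / prescribed in practice.
RECOMMENDED_COUNTS = {
    "amisulpride": 2920, "aripiprazole": 3088, "chlorpromazine": 119,
    "clothiapine": 2, "flupentixol": 55, "haloperidol": 62, "olanzapine": 479,
    "paliperidone": 831, "quetiapine": 385, "risperidone": 1069,
    "sulpiride": 105, "thioridazine": 0, "trifluoperazine": 339,
    "ziprasidone": 0, "zotepine": 222,
}
PRESCRIBED_COUNTS = {
    "amisulpride": 674, "aripiprazole": 614, "chlorpromazine": 103,
    "clothiapine": 47, "flupentixol": 158, "haloperidol": 503,
    "olanzapine": 433, "paliperidone": 116, "quetiapine": 1004,
    "risperidone": 2905, "sulpiride": 2747, "thioridazine": 28,
    "trifluoperazine": 106, "ziprasidone": 101, "zotepine": 137,
}

# Observed successes among recipients of selected medications.
OBSERVED_SUCCESSES = {"amisulpride": (303, 674)}


def _round1(x: float) -> float:
    from .value import _round_half_up
    return _round_half_up(x, 1)


def worked_examples() -> dict[str, float]:
    """Recompute every derived quantity from the packaged summary inputs."""
    out: dict[str, float] = {}
    itr = SUCCESS_RATES["itr"]
    obs = SUCCESS_RATES["observed"]
    out["nnt_itr_vs_observed"] = nnt(itr, obs)
    out["proportional_ratio_primary"] = proportional_ratio(itr, obs)
    for name, (r_itr, r_obs) in SENSITIVITY_RATES.items():
        out[f"proportional_ratio_{name}"] = proportional_ratio(r_itr, r_obs)
    for med, (when_rec, when_not) in PRESCRIBED_SHARES.items():
        out[f"concordance_ratio_{med}"] = concordance_ratio(when_rec, when_not)
    meds = list(CONTRIBUTION_INPUTS)
    diffs = np.array([CONTRIBUTION_INPUTS[m][0] for m in meds])
    counts = np.array([CONTRIBUTION_INPUTS[m][1] for m in meds])
    contrib = contribution_decomposition(diffs, counts)
    for med, c in zip(meds, contrib):
        out[f"contribution_pct_{med}"] = _round1(c)
    for med, cnt in RECOMMENDED_COUNTS.items():
        out[f"recommended_share_pct_{med}"] = _round1(100.0 * cnt / HOLDOUT_N)
    for med, cnt in PRESCRIBED_COUNTS.items():
        out[f"prescribed_share_pct_{med}"] = _round1(100.0 * cnt / HOLDOUT_N)
    for med, (succ, n_med) in OBSERVED_SUCCESSES.items():
        out[f"observed_success_pct_{med}"] = _round1(100.0 * succ / n_med)
    return out
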