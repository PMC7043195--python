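"""Cohort construction: eligibility filters, outcome labeling, splitting.

The eligibility screen mirrors an incident-user claims design for
first-episode psychosis: patients aged 16-74 at index, whose first
antipsychotic regimen is a single first-line oral agent (not clozapine,
polypharmacy, or a long-acting injectable), started as an outpatient, on a
medication that is not rarely prescribed cohort-wide. Filters are applied
in that fixed order so per-class exclusion counts are reproducible.

The primary treatment-success outcome is the absence, over the 12 months
after index, of inpatient death, any hospitalization, and any change of
antipsychotic (switch or addition). Discontinuation does not count as
failure under the primary definition; sensitivity variants narrow or widen
the failure set. Events at exactly month 0 are pre-index and ignored — the
window is half-open, (0, 12].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError
from .synthetic import EVENT_TYPES, SECOND_LINE_REGIMENS

OUTCOME_VARIANTS = (
    "primary",
    "psych_hosp_or_change",
    "psych_hosp_only",
    "change_only",
    "primary_plus_discontinuation",
)

# Event types triggering failure, per outcome variant (discontinuation is
# handled separately because it is window-restricted).
_FAILURE_SETS = {
    "primary": {"hospitalization_psychiatric", "hospitalization_other",
                "med_switch", "med_addition", "inpatient_death"},
    "psych_hosp_or_change": {"hospitalization_psychiatric", "med_switch",
                             "med_addition", "inpatient_death"},
    "psych_hosp_only": {"hospitalization_psychiatric", "inpatient_death"},
    "change_only": {"med_switch", "med_addition"},
    "primary_plus_discontinuation": {"hospitalization_psychiatric",
                                     "hospitalization_other", "med_switch",
                                     "med_addition", "inpatient_death"},
}

EXCLUSION_ORDER = ("age", "second_line", "inpatient_start", "rare_drug")


@dataclass(frozen=True)
class OutcomeDefinition:
    variant: str = "primary"
    discontinuation_window: tuple[float, float] = (3.0, 9.0)

    def __post_init__(self) -> None:
        if self.variant not in OUTCOME_VARIANTS:
            raise ConfigurationError(f"unknown outcome variant {self.variant!r}")
        lo, hi = self.discontinuation_window
        if not (0.0 <= lo < hi <= 12.0):
            raise ConfigurationError("discontinuation window must satisfy 0 <= start < end <= 12")


@dataclass
class Cohort:
    """Analysis-ready cohort: patient table, outcome, and split labels."""

    patients: pd.DataFrame
    covariate_names: list[str]
    arm_names: list[str]
    outcome: np.ndarray
    split: np.ndarray | None = None  # "train"/"holdout" per patient

    @property
    def n(self) -> int:
        return len(self.patients)

    @property
    def X(self) -> np.ndarray:
        return self.patients[self.covariate_names].to_numpy(dtype=float)

    @property
    def arms(self) -> np.ndarray:
        return self.patients["arm"].to_numpy(dtype=np.int64)

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(
            patients=self.patients.loc[mask].reset_index(drop=True),
            covariate_names=self.covariate_names,
            arm_names=self.arm_names,
            outcome=self.outcome[mask],
            split=None if self.split is None else self.split[mask],
        )

    def part(self, label: str) -> "Cohort":
        if self.split is None:
            raise ValueError("cohort has no split labels")
        return self.subset(self.split == label)


def apply_eligibility(
    records: pd.DataFrame,
    medication_list: list[str] | tuple[str, ...],
    age_bounds: tuple[float, float] = (16.0, 74.0),
    rare_drug_minimum: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Screen raw records; return (eligible records, per-class exclusion counts).

    Order: age -> second-line first regimen -> inpatient start -> rare drug.
    Rare-drug counts are taken among records surviving the earlier filters.
    Idempotent: re-applying to its own output changes nothing.
    """
    if len(medication_list) == 0:
        raise ConfigurationError("medication list must be nonempty")
    counts = {k: 0 for k in EXCLUSION_ORDER}
    df = records
    lo, hi = age_bounds

    ok = (df["age"] >= lo) & (df["age"] <= hi)
    counts["age"] = int((~ok).sum())
    df = df.loc[ok]

    allowed = set(medication_list)
    ok = df["first_regimen"].isin(allowed) & ~df["first_regimen"].isin(SECOND_LINE_REGIMENS)
    counts["second_line"] = int((~ok).sum())
    df = df.loc[ok]

    ok = ~df["first_rx_inpatient"].astype(bool)
    counts["inpatient_start"] = int((~ok).sum())
    df = df.loc[ok]

    if rare_drug_minimum > 0 and len(df):
        freq = df["first_regimen"].value_counts()
        rare = set(freq.index[freq < rare_drug_minimum])
        ok = ~df["first_regimen"].isin(rare)
        counts["rare_drug"] = int((~ok).sum())
        df = df.loc[ok]

    return df.reset_index(drop=True), counts


def label_outcome(events: pd.DataFrame, n_patients: int,
                  definition: OutcomeDefinition = OutcomeDefinition()) -> np.ndarray:
    """Binary success label per patient from the 12-month event stream.

    `events` has columns (patient_id, event_type, month) with patient_id in
    [0, n_patients); patients with no qualifying event succeed.
    """
    bad = set(events["event_type"].unique()) - set(EVENT_TYPES)
    if bad:
        raise ValueError(f"unknown event types {sorted(bad)}")
    in_window = (events["month"] > 0.0) & (events["month"] <= 12.0)
    trigger = events["event_type"].isin(_FAILURE_SETS[definition.variant]) & in_window
    if definition.variant == "primary_plus_discontinuation":
        lo, hi = definition.discontinuation_window
        disc = (
            (events["event_type"] == "discontinuation")
            & (events["month"] >= lo)
            & (events["month"] <= hi)
        )
        trigger = trigger | disc
    failed = np.zeros(n_patients, dtype=bool)
    ids = events.loc[trigger, "patient_id"].to_numpy(dtype=np.int64)
    failed[ids] = True
    return (~failed).astype(np.int64)


def split_sample(n: int, train_fraction: float = 0.7, seed: int = 0) -> np.ndarray:
    """Simple random train/holdout partition; train size = round(n * fraction)."""
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction must be in (0, 1)")
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)  # both parts nonempty
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[perm[:n_train]] = "train"
    labels[perm[n_train:]] = "holdout"
    return labels.astype(str)


def build_cohort(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    covariate_names: list[str],
    arm_names: list[str],
    definition: OutcomeDefinition = OutcomeDefinition(),
    train_fraction: float = 0.7,
    seed: int = 0,
) -> Cohort:
    """Label outcomes from events, attach a 70/30 split, return a Cohort.

    `patients` must already be eligibility-screened; outcome labels are
    derived from the event stream (never read from a generator column).
    """
    ids = patients["patient_id"].to_numpy(dtype=np.int64)
    ev = events[events["patient_id"].isin(set(ids))]
    # relabel patient ids to positional indices
    pos = {pid: i for i, pid in enumerate(ids)}
    ev = ev.assign(patient_id=ev["patient_id"].map(pos))
    y = label_outcome(ev, len(ids), definition)
    split = split_sample(len(ids), train_fraction, seed)
    pats = patients.reset_index(drop=True)
    return Cohort(pats, list(covariate_names), list(arm_names), y, split)
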