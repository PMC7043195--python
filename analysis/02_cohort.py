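"""Screen eligibility, label the 12-month outcome, split 70/30.

Reads the raw records from 01, applies the incident-user filters (age
16-74, first-line single-agent start, outpatient initiation, no rare
drug), labels treatment success from the event stream under the primary
definition, and attaches the honest train/holdout split.
"""

import argparse
from pathlib import Path

import pandas as pd

import rxrule
from rxrule.cohort import OutcomeDefinition, apply_eligibility, build_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=11)
parser.add_argument("--train-fraction", type=float, default=0.7)
parser.add_argument("--outcome-variant", default="primary")
parser.add_argument("--rare-drug-minimum", type=int, default=20)
parser.add_argument("--dir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

cfg = rxrule.default_config()
patients = pd.read_csv(args.dir / "patients_raw.csv")
events = pd.read_csv(args.dir / "events.csv")

eligible, exclusions = apply_eligibility(patients, list(cfg.arms),
                                         rare_drug_minimum=args.rare_drug_minimum)
cohort = build_cohort(eligible, events, cfg.covariate_names, list(cfg.arms),
                      OutcomeDefinition(args.outcome_variant),
                      args.train_fraction, args.seed)

out = cohort.patients[["patient_id"] + cfg.covariate_names + ["arm"]].copy()
out["outcome"] = cohort.outcome
out["split"] = cohort.split
out.to_csv(args.dir / "cohort.csv", index=False)

print("exclusions:", exclusions)
print(f"eligible: {cohort.n}  train: {(cohort.split == 'train').sum()}  "
      f"holdout: {(cohort.split == 'holdout').sum()}")
print(f"observed success rate: {100 * cohort.outcome.mean():.1f}%")
print(f"wrote cohort.csv to {args.dir}")
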