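"""Fit the two-stage ITR on the training sample.

Estimates one-vs-rest propensities and the outcome surfaces with Super
Learners, forms doubly robust difference scores, fits the per-arm
second-stage models, and writes the training nuisance matrices plus the
rule's recommendation for every cohort patient.
"""

import argparse
from pathlib import Path

import pandas as pd

import rxrule
from rxrule.pipeline import ROSTERS, fit_itr

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--roster", default="default", choices=sorted(ROSTERS))
parser.add_argument("--truncation", type=float, default=0.01)
parser.add_argument("--dir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

cfg = rxrule.default_config()
cohort = pd.read_csv(args.dir / "cohort.csv")
train = cohort[cohort["split"] == "train"]
X_train = train[cfg.covariate_names].to_numpy()

fit = fit_itr(X_train, train["arm"].to_numpy(), train["outcome"].to_numpy(),
              cfg.n_arms, roster=ROSTERS[args.roster](), seed=args.seed,
              truncation=args.truncation, min_support=20)

arms = list(cfg.arms)
pd.DataFrame(fit.g.values, columns=arms).to_csv(args.dir / "propensities_train.csv", index=False)
pd.DataFrame(fit.surfaces.Q, columns=arms).to_csv(args.dir / "q_surfaces_train.csv", index=False)
pd.DataFrame(fit.D, columns=arms).to_csv(args.dir / "difference_scores_train.csv", index=False)

rec = fit.rule.recommend(cohort[cfg.covariate_names].to_numpy())
pd.DataFrame({"patient_id": cohort["patient_id"], "recommended_arm": rec}
             ).to_csv(args.dir / "recommendations.csv", index=False)

shares = pd.Series(rec, name="arm").value_counts(normalize=True).sort_index()
print(f"propensity cells truncated at {fit.g.truncation_bound}: {fit.g.truncated_count}")
print("recommended shares:",
      {arms[a]: round(float(s), 3) for a, s in shares.items()})
print(f"wrote nuisance matrices and recommendations.csv to {args.dir}")
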