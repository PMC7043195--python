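"""Permutation importance of prescriptive predictors.

Refits the second-stage difference-score models from the persisted
training difference scores, permutes one predictor at a time, and writes
the per-arm MSE-increase ranking.
"""

import argparse
from pathlib import Path

import pandas as pd

import rxrule
from rxrule.importance import importance_report, top_k_table
from rxrule.itr import fit_cate_models
from rxrule.pipeline import ROSTERS

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=89)
parser.add_argument("--roster", default="default", choices=sorted(ROSTERS))
parser.add_argument("--repetitions", type=int, default=10)
parser.add_argument("--top-k", type=int, default=10)
parser.add_argument("--dir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

cfg = rxrule.default_config()
cohort = pd.read_csv(args.dir / "cohort.csv")
train = cohort[cohort["split"] == "train"]
X = train[cfg.covariate_names].to_numpy()
D = pd.read_csv(args.dir / "difference_scores_train.csv").to_numpy()

roster = [s for s in ROSTERS[args.roster]() if s.name != "mean"]
fits = fit_cate_models(X, D, roster, seed=args.seed)
report = importance_report(fits, X, D, cfg.covariate_names, list(cfg.arms),
                           n_repetitions=args.repetitions, seed=args.seed)
report.to_csv(args.dir / "importance.csv", index=False)
top = top_k_table(report, args.top_k)
top.to_csv(args.dir / "importance_topk.csv", index=False)

for arm in list(cfg.arms):
    sub = top[top["arm"] == arm].head(3)
    named = ", ".join(f"{r.predictor} (+{r.increase:.4f})" for r in sub.itertuples())
    print(f"{arm}: {named}")
print(f"wrote importance.csv and importance_topk.csv to {args.dir}")
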