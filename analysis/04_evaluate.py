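"""TMLE evaluation of the learned rule on the holdout sample.

Refits nuisances on the holdout, estimates the mean success rate under the
learned rule, the observed allocation, uniform and prescription-share
randomization, and every sufficiently supported single-arm scheme, and
writes the five report tables.
"""

import argparse
from pathlib import Path

import pandas as pd

import rxrule
from rxrule.cohort import Cohort
from rxrule.pipeline import ROSTERS, evaluate_rules, render_tables

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=113)
parser.add_argument("--roster", default="default", choices=sorted(ROSTERS))
parser.add_argument("--dir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

cfg = rxrule.default_config()
cohort = pd.read_csv(args.dir / "cohort.csv")
rec_all = pd.read_csv(args.dir / "recommendations.csv")
hold_mask = cohort["split"] == "holdout"
hold = cohort[hold_mask].reset_index(drop=True)
rec = rec_all.loc[hold_mask.to_numpy(), "recommended_arm"].to_numpy()

ev = evaluate_rules(hold[cfg.covariate_names].to_numpy(), hold["arm"].to_numpy(),
                    hold["outcome"].to_numpy(), rule=None, n_arms=cfg.n_arms,
                    roster=ROSTERS[args.roster](), seed=args.seed,
                    recommended_arms=rec)

hold_cohort = Cohort(hold, cfg.covariate_names, list(cfg.arms),
                     hold["outcome"].to_numpy())
tables = render_tables(hold_cohort, ev, list(cfg.arms))
for name, tab in tables.items():
    tab.to_csv(args.dir / f"{name}.csv", index=False)

itr, obs = ev["itr"], ev["observed"]
cmp_obs = ev["comparisons"]["observed"]
print(f"ITR value:      {100 * itr.value:.1f}% (SE {100 * itr.se:.1f}%)")
print(f"observed:       {100 * obs.value:.1f}% (SE {100 * obs.se:.1f}%)   "
      f"z={cmp_obs.z:.1f} p={cmp_obs.p_one_sided:.2g} "
      f"NNT={cmp_obs.nnt} ratio={cmp_obs.proportional_ratio}")
print(f"uniform:        {100 * ev['uniform'].value:.1f}%")
print(f"proportional:   {100 * ev['proportional'].value:.1f}%")
print(f"wrote report tables to {args.dir}")
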