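"""End-to-end orchestration: simulate -> cohort -> fit ITR -> evaluate -> importance.

`run_pipeline` drives the whole analysis from one declarative config dict
(or YAML file), writes every artifact as a delimited table under an output
directory, and returns a reproducibility manifest (config digest, derived
seed tuple, per-stage row counts, artifact inventory with file digests).
Per-stage seeds are derived from a single master seed by fixed offsets, so
a rerun with an identical config reproduces identical outputs.

The intermediate fitting and evaluation steps (`fit_itr`,
`evaluate_rules`) are plain library functions so tests and replicate
simulations can call them without touching the filesystem.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as coh
from . import itr as itrmod
from . import superlearner as sl
from . import value as val
from .config import ConfigurationError, default_config, load_config
from .importance import importance_report, top_k_table
from .reference_example import worked_examples
from .synthetic import GroundTruth, generate_raw_records

ROSTERS = {
    "default": sl.default_roster,
    "fast": sl.fast_roster,
    "linear": sl.linear_roster,
}

DEFAULT_PIPELINE_CONFIG = {
    "n_patients": 20_000,
    "seed": 0,
    "decoy_fraction": 0.05,
    "heterogeneity": 1.0,
    "confounding": 1.0,
    "train_fraction": 0.7,
    "outcome_variant": "primary",
    "discontinuation_window": [3.0, 9.0],
    "rare_drug_minimum": 20,
    "roster": "default",
    "n_folds": 10,
    "truncation": 0.01,
    "min_support": 20,
    "min_static_support": 30,
    "augmented": True,
    "importance_repetitions": 20,
    "importance_top_k": 10,
}

_SEED_OFFSETS = {"simulate": 0, "split": 11, "propensity": 23, "outcome": 37,
                 "cate": 53, "evaluate": 71, "importance": 89}


@dataclass
class ItrFit:
    """Everything produced by the training-sample two-stage estimation."""

    g: itrmod.PropensityMatrix
    surfaces: itrmod.OutcomeSurfaces
    D: np.ndarray
    cate_fits: list
    rule: itrmod.TreatmentRule
    eligible_arms: np.ndarray


@dataclass
class RunManifest:
    config_digest: str
    seeds: dict
    row_counts: dict
    artifacts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config_digest": self.config_digest, "seeds": self.seeds,
             "row_counts": self.row_counts, "artifacts": self.artifacts},
            indent=2, sort_keys=True)


def _validate_pipeline_config(config: dict) -> dict:
    cfg = dict(DEFAULT_PIPELINE_CONFIG)
    cfg.update(config or {})
    missing = [k for k in DEFAULT_PIPELINE_CONFIG if k not in cfg]
    if missing:
        raise ConfigurationError(f"missing config keys: {missing}")
    unknown = set(cfg) - set(DEFAULT_PIPELINE_CONFIG)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if not 0.0 < cfg["train_fraction"] < 1.0:
        raise ConfigurationError("train_fraction must be strictly inside (0, 1); "
                                 "a nonempty holdout is required for honest evaluation")
    if cfg["roster"] not in ROSTERS:
        raise ConfigurationError(f"roster must be one of {sorted(ROSTERS)}")
    return cfg


def derived_seeds(master_seed: int) -> dict:
    return {k: int(master_seed) + off for k, off in _SEED_OFFSETS.items()}


def fit_itr(
    X: np.ndarray,
    arms: np.ndarray,
    y: np.ndarray,
    n_arms: int,
    roster: list | None = None,
    n_folds: int = 10,
    seed: int = 0,
    truncation: float = 0.01,
    min_support: int = 1,
    augmented: bool = True,
    cate_roster: list | None = None,
) -> ItrFit:
    """Two-stage ITR estimation on a training sample.

    The second-stage (difference-score) models default to the nuisance
    roster *minus* the intercept-only learner: on heavy-tailed AIPW targets
    the CV-optimal weight on a constant predictor differs between arms,
    which shrinks each arm's score by a different factor and distorts the
    argmax rule. Pass `cate_roster` explicitly to override.
    """
    roster = sl.default_roster() if roster is None else roster
    if cate_roster is None:
        cate_roster = [s for s in roster if s.name != "mean"] or roster
    seeds = derived_seeds(seed)
    eligible = itrmod.eligible_arm_set(arms, n_arms, min_support)
    g = itrmod.estimate_propensities(X, arms, roster, n_arms, n_folds=n_folds,
                                     seed=seeds["propensity"], truncation=truncation)
    surfaces = itrmod.estimate_outcome_surfaces(X, arms, y, roster, n_arms,
                                                n_folds=n_folds, seed=seeds["outcome"])
    D = itrmod.compute_difference_scores(y, arms, g, surfaces, augmented=augmented)
    cate_fits = itrmod.fit_cate_models(X, D, cate_roster, n_folds=n_folds,
                                       seed=seeds["cate"], eligible_arms=eligible)
    rule = itrmod.build_itr(cate_fits, n_arms)
    return ItrFit(g=g, surfaces=surfaces, D=D, cate_fits=cate_fits, rule=rule,
                  eligible_arms=eligible)


def holdout_nuisances(
    X: np.ndarray,
    arms: np.ndarray,
    y: np.ndarray,
    n_arms: int,
    roster: list | None = None,
    n_folds: int = 10,
    seed: int = 0,
    truncation: float = 0.01,
):
    """Refit (g, Q) on the holdout sample for TMLE evaluation."""
    roster = sl.default_roster() if roster is None else roster
    g = itrmod.estimate_propensities(X, arms, roster, n_arms, n_folds=n_folds,
                                     seed=seed + 1, truncation=truncation)
    surfaces = itrmod.estimate_outcome_surfaces(X, arms, y, roster, n_arms,
                                                n_folds=n_folds, seed=seed + 2)
    return g, surfaces


def evaluate_rules(
    X: np.ndarray,
    arms: np.ndarray,
    y: np.ndarray,
    rule: itrmod.TreatmentRule,
    n_arms: int,
    roster: list | None = None,
    n_folds: int = 10,
    seed: int = 0,
    truncation: float = 0.01,
    min_static_support: int = 30,
    nuisances: tuple | None = None,
    recommended_arms: np.ndarray | None = None,
) -> dict:
    """TMLE evaluation of the learned rule and the comparison schemes.

    Returns a dict with keys: 'observed', 'itr', 'static' (arm -> estimate),
    'uniform', 'proportional', and 'comparisons' (name -> RuleComparison of
    the ITR against that scheme). Nuisances are refit on the holdout unless
    a (g, surfaces) pair is supplied (transport mode).
    """
    if nuisances is None:
        g, surfaces = holdout_nuisances(X, arms, y, n_arms, roster=roster,
                                        n_folds=n_folds, seed=seed,
                                        truncation=truncation)
    else:
        g, surfaces = nuisances
    out: dict = {"nuisances": (g, surfaces)}
    out["observed"] = val.observed_success_rate(y)

    rec = recommended_arms if recommended_arms is not None \
        else rule.recommend(X, observed_arms=arms)
    out["recommended_arms"] = rec
    out["itr"] = val.tmle_rule_value(y, arms, rec, g, surfaces.Q)

    counts = np.bincount(arms, minlength=n_arms)
    static: dict[int, val.RuleValueEstimate] = {}
    for a in range(n_arms):
        if counts[a] < min_static_support:
            continue
        static[a] = val.tmle_rule_value(y, arms, np.full(len(y), a), g, surfaces.Q)
    out["static"] = static

    avail = sorted(static)
    w_unif = np.zeros(n_arms)
    w_unif[avail] = 1.0 / len(avail)
    out["uniform"] = val.stochastic_rule_value(static, w_unif)
    w_prop = np.zeros(n_arms)
    w_prop[avail] = counts[avail] / counts[avail].sum()
    out["proportional"] = val.stochastic_rule_value(static, w_prop)

    comparisons = {
        "observed": val.compare_rules(out["itr"], out["observed"]),
        "uniform": val.compare_rules(out["itr"], out["uniform"]),
        "proportional": val.compare_rules(out["itr"], out["proportional"]),
    }
    for a in avail:
        comparisons[f"static_{a}"] = val.compare_rules(out["itr"], static[a])
    out["comparisons"] = comparisons
    return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, index=False)
    manifest.artifacts[path.name] = _digest(path)


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> RunManifest:
    """Execute every stage from one config; write artifacts and a manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _validate_pipeline_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    seeds = derived_seeds(cfg["seed"])
    manifest = RunManifest(config_digest=digest, seeds=seeds, row_counts={})

    # --- simulate ---------------------------------------------------------
    sim = default_config(n_patients=cfg["n_patients"], seed=seeds["simulate"],
                         decoy_fraction=cfg["decoy_fraction"],
                         heterogeneity=cfg["heterogeneity"],
                         confounding=cfg["confounding"])
    patients, events, truth = generate_raw_records(sim)
    manifest.row_counts["raw_records"] = len(patients)
    _write(patients, out / "patients_raw.csv", manifest)
    _write(events, out / "events.csv", manifest)
    truth_df = pd.DataFrame(
        np.column_stack([truth.true_propensities, truth.true_success_probs]),
        columns=[f"g_{a}" for a in sim.arms] + [f"mu_{a}" for a in sim.arms])
    truth_df["oracle_arm"] = truth.oracle_arm
    _write(truth_df, out / "ground_truth.csv", manifest)

    # --- cohort -----------------------------------------------------------
    eligible, excl = coh.apply_eligibility(
        patients, list(sim.arms), rare_drug_minimum=cfg["rare_drug_minimum"])
    manifest.row_counts["eligible"] = len(eligible)
    manifest.row_counts["exclusions"] = excl
    definition = coh.OutcomeDefinition(cfg["outcome_variant"],
                                       tuple(cfg["discontinuation_window"]))
    cohort = coh.build_cohort(eligible, events, sim.covariate_names,
                              list(sim.arms), definition,
                              cfg["train_fraction"], seeds["split"])
    cohort_df = cohort.patients[["patient_id"] + sim.covariate_names + ["arm"]].copy()
    cohort_df["outcome"] = cohort.outcome
    cohort_df["split"] = cohort.split
    _write(cohort_df, out / "cohort.csv", manifest)

    train = cohort.part("train")
    hold = cohort.part("holdout")
    manifest.row_counts["train"] = train.n
    manifest.row_counts["holdout"] = hold.n

    # --- fit the ITR on the training sample -------------------------------
    roster = ROSTERS[cfg["roster"]]()
    fit = fit_itr(train.X, train.arms, train.outcome, sim.n_arms, roster=roster,
                  n_folds=cfg["n_folds"], seed=cfg["seed"],
                  truncation=cfg["truncation"], min_support=cfg["min_support"],
                  augmented=cfg["augmented"])
    _write(pd.DataFrame(fit.g.values, columns=list(sim.arms)),
           out / "propensities_train.csv", manifest)
    _write(pd.DataFrame(fit.surfaces.Q, columns=list(sim.arms)),
           out / "outcome_surfaces_train.csv", manifest)
    _write(pd.DataFrame(fit.D, columns=list(sim.arms)),
           out / "difference_scores_train.csv", manifest)

    # --- evaluate on the holdout ------------------------------------------
    ev = evaluate_rules(hold.X, hold.arms, hold.outcome, fit.rule, sim.n_arms,
                        roster=roster, n_folds=cfg["n_folds"],
                        seed=seeds["evaluate"], truncation=cfg["truncation"],
                        min_static_support=cfg["min_static_support"])
    tables = render_tables(hold, ev, list(sim.arms))
    for name, tab in tables.items():
        _write(tab, out / f"{name}.csv", manifest)

    # --- prescriptive-predictor importance (training sample) --------------
    report = importance_report(fit.cate_fits, train.X, fit.D,
                               sim.covariate_names, list(sim.arms),
                               n_repetitions=cfg["importance_repetitions"],
                               seed=seeds["importance"])
    _write(report, out / "importance.csv", manifest)
    _write(top_k_table(report, cfg["importance_top_k"]),
           out / "importance_topk.csv", manifest)

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def render_tables(hold: coh.Cohort, ev: dict, arm_names: list[str]) -> dict[str, pd.DataFrame]:
    """The five report tables of a comparative ITR analysis.

    table1: observed vs recommended medication distributions (chi-square);
    table2: prescribed shares for recommended vs non-recommended patients
    with concordance ratios; table3: medication-specific success rates;
    table4/table5: success-rate changes for patients off their recommended
    medication, with the per-medication contribution decomposition.
    """
    n_arms = len(arm_names)
    rec = ev["recommended_arms"]
    arms = hold.arms
    y = hold.outcome.astype(float)
    obs_counts = np.bincount(arms, minlength=n_arms)
    rec_counts = np.bincount(rec, minlength=n_arms)
    t1, chi2, p = val.distribution_table(arm_names, obs_counts, rec_counts)
    t1.attrs["chi2"] = chi2
    t1.attrs["p"] = p

    rows = []
    for a, name in enumerate(arm_names):
        is_rec = rec == a
        n_rec, n_not = int(is_rec.sum()), int((~is_rec).sum())
        p_rec = 100.0 * (arms[is_rec] == a).mean() if n_rec else 0.0
        p_not = 100.0 * (arms[~is_rec] == a).mean() if n_not else 0.0
        try:
            ratio = val.concordance_ratio(p_rec, p_not)
        except ValueError:
            ratio = np.nan
        rows.append({"medication": name,
                     "pct_prescribed_when_recommended": p_rec,
                     "pct_prescribed_when_not": p_not,
                     "concordance_ratio": ratio})
    t2 = pd.DataFrame(rows)

    t3 = val.medication_specific_summary(y, arms, rec, arm_names,
                                         ev["static"], ev["itr"])

    # Patients prescribed medication a while recommended something else:
    # how would success change had they received their recommendation?
    rows = []
    itr_qs = ev["itr"].q_star_rule
    for a, name in enumerate(arm_names):
        off = (arms == a) & (rec != a)
        n_off = int(off.sum())
        if n_off == 0 or a not in ev["static"]:
            continue
        obs_rate = 100.0 * y[off].mean()
        est_rate = 100.0 * float(itr_qs[off].mean()) if itr_qs is not None else np.nan
        rows.append({"medication": name, "n_without_recommended": n_off,
                     "obs_success_pct": obs_rate,
                     "est_success_if_recommended_pct": est_rate,
                     "difference_pct": est_rate - obs_rate})
    t5 = pd.DataFrame(rows)
    if len(t5):
        contrib = val.contribution_decomposition(
            t5["difference_pct"].to_numpy(), t5["n_without_recommended"].to_numpy())
        t5["contribution_pct"] = contrib

    summary = pd.DataFrame([
        {"scheme": name,
         "success_pct": 100.0 * est.value,
         "se_pct": 100.0 * est.se,
         "ci_low_pct": 100.0 * est.ci95[0],
         "ci_high_pct": 100.0 * est.ci95[1],
         "n": est.n}
        for name, est in (("itr", ev["itr"]), ("observed", ev["observed"]),
                          ("uniform", ev["uniform"]),
                          ("proportional", ev["proportional"]),
                          *((f"static_{arm_names[a]}", e) for a, e in sorted(ev["static"].items())))
    ])
    return {"table1_distributions": t1, "table2_concordance": t2,
            "table3_medication_success": t3, "table5_contributions": t5,
            "value_summary": summary}
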