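"""End-to-end pipeline: simulate -> preprocess -> class-predict ->
survival-screen -> risk-predict -> evaluate-pairs -> qpcr.

One flat YAML configuration drives every stage; each stochastic stage gets a
seed derived deterministically from the master seed, the configuration is
echoed verbatim into the output directory, and a machine-readable run report
collects versions, seeds, warnings and headline statistics.  A rerun under
the same configuration reproduces every statistical output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import cross_partition_accuracy, t_test_per_feature
from .io import write_clinical_tsv, write_ct_tsv, write_expression_tsv
from .pairs import evaluate_pairs, pairs_table, summarize_pairs
from .preprocess import drop_sparse_and_impute
from .qpcr import analyze_ct_table
from .risk import (fit_risk_model, km_estimate, loocv_risk_groups,
                   permutation_significance, risk_call, save_model)
from .simulate import (SimulationConfig, generate_cancer_normal,
                       generate_ct_table, generate_pairs,
                       generate_survival_cohort)
from .survival import select_survival_features

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("simulate", "preprocess", "class_predict", "survival_screen",
           "risk_predict", "evaluate_pairs", "qpcr")


@dataclass
class RunConfig:
    """Flat pipeline configuration (YAML-compatible key/value file)."""

    seed: int = 0
    # simulation (cohort structure mirrors the study design)
    n_cancer: int = 90
    n_normal: int = 34
    n_survival: int = 82
    n_features: int = 1667
    n_replicates_per_feature: int = 4
    n_diff_features: int = 125
    diff_log2_effect: float = 1.0
    n_hazard_features: int = 58
    hazard_log_effect: float = 0.06
    hazard_factor_corr: float = 0.5
    n_pairs: int = 8
    pair_shift: float = 2.0
    noise_sd: float = 0.5
    # analysis thresholds
    class_table_alpha: float = 0.005
    class_prediction_alpha: float = 0.05
    survival_alpha: float = 0.05
    cutoff_percentile: float = 67.0
    partitions: int = 100
    permutations: int = 1000
    lowess_span: float = 2.0 / 3.0
    max_missing_frac: float = 0.5
    # stage toggles
    stages: tuple = _STAGES

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        idx = _STAGES.index(stage)
        return int(np.random.SeedSequence([int(self.seed), 100 + idx])
                   .generate_state(1)[0] % (2 ** 31))


def _fmt(df: pd.DataFrame, path, index=True):
    df.to_csv(path, sep="\t", float_format="%.6g", na_rep="", index=index)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the enabled stages in order; returns the run report dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    report = {
        "package": "chemomir",
        "version": __version__,
        "seed": int(config.seed),
        "stage_seeds": {s: config.stage_seed(s) for s in config.stages},
        "stages_run": [],
        "warnings": [],
        "headline": {},
    }
    caught: list = []

    def run_stage(name, fn):
        if name not in config.stages:
            return
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                fn()
            caught.extend(f"{name}: {w.message}" for w in wlist)
            report["stages_run"].append(name)
        except Exception as exc:
            report["failed_stage"] = name
            report["error"] = str(exc)
            _write_report(report, caught, out)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    state: dict = {}

    def simulate():
        base = SimulationConfig(
            n_cancer=config.n_cancer, n_normal=config.n_normal,
            n_features=config.n_features,
            n_replicates_per_feature=config.n_replicates_per_feature,
            n_diff_features=config.n_diff_features,
            diff_log2_effect=config.diff_log2_effect,
            n_hazard_features=config.n_hazard_features,
            hazard_log_effect=config.hazard_log_effect,
            hazard_factor_corr=config.hazard_factor_corr,
            n_pairs=config.n_pairs, pair_shift=config.pair_shift,
            noise_sd=config.noise_sd, seed=config.stage_seed("simulate"),
        )
        state["class_cohort"] = generate_cancer_normal(base)
        state["surv_cohort"] = generate_survival_cohort(
            base.with_(n_cancer=config.n_survival))
        write_expression_tsv(state["class_cohort"].expression,
                             out / "expression_class_probes.tsv")
        write_expression_tsv(state["surv_cohort"].expression,
                             out / "expression_survival_probes.tsv")
        write_clinical_tsv(state["class_cohort"].clinical_table(),
                           out / "clinical_class.tsv")
        write_clinical_tsv(state["surv_cohort"].clinical_table(),
                           out / "clinical_survival.tsv")
        _fmt(pd.concat([state["class_cohort"].truth, state["surv_cohort"].truth]),
             out / "truth.tsv", index=False)

    def preprocess():
        for key, stem in (("class_cohort", "class"), ("surv_cohort", "survival")):
            collapsed = drop_sparse_and_impute(state[key].mirna_expression(),
                                               config.max_missing_frac)
            state[f"X_{stem}"] = collapsed
            write_expression_tsv(collapsed, out / f"expression_{stem}_mirna.tsv")

    def class_predict():
        X = state["X_class"]
        labels = state["class_cohort"].class_labels
        tab = t_test_per_feature(X, labels.to_numpy())
        table = tab[tab["usable"] & (tab["p"] < config.class_table_alpha)]
        table = table.sort_values("p")[["statistic", "p", "fdr", "ratio"]]
        _fmt(table, out / "differential_features.tsv")
        res = cross_partition_accuracy(
            X, labels.to_numpy(), n_partitions=config.partitions,
            selection_alpha=config.class_prediction_alpha,
            seed=config.stage_seed("class_predict"))
        rows = [{"classifier": m, "median_accuracy": r.median,
                 "accuracies": ",".join(f"{a:.4f}" for a in r.accuracies)}
                for m, r in res.items()]
        _fmt(pd.DataFrame(rows), out / "partition_accuracy.tsv", index=False)
        report["headline"]["n_differential_features"] = int(len(table))
        report["headline"]["classifier_median_accuracy"] = {
            m: r.median for m, r in res.items()}

    def survival_screen():
        X = state["X_survival"]
        surv = state["surv_cohort"].survival
        sel = select_survival_features(X, surv["ttp_months"].to_numpy(),
                                       surv["event"].to_numpy().astype(bool),
                                       alpha=config.survival_alpha)
        state["selection"] = sel
        tab = sel.table[sel.table["list"] != ""].sort_values("p")
        _fmt(tab[["p", "fdr", "hazard_ratio", "list"]], out / "survival_features.tsv")
        report["headline"]["n_survival_selected"] = len(sel.selected)
        report["headline"]["n_resistance"] = len(sel.resistance)
        report["headline"]["n_sensitivity"] = len(sel.sensitivity)

    def risk_predict():
        X = state["X_survival"]
        surv = state["surv_cohort"].survival
        t = surv["ttp_months"].to_numpy()
        e = surv["event"].to_numpy().astype(bool)
        model = fit_risk_model(X, t, e, selection_alpha=config.survival_alpha,
                               cutoff=config.cutoff_percentile)
        state["model"] = model
        save_model(model, out / "risk_model.json")
        calls = [risk_call(model, s, X[s]) for s in X.columns]
        _fmt(pd.DataFrame([{"sample_id": c.sample_id,
                            "predictive_index": c.predictive_index,
                            "percentile": c.percentile, "group": c.group}
                           for c in calls]),
             out / "risk_calls_training.tsv", index=False)
        cv = loocv_risk_groups(X, t, e, selection_alpha=config.survival_alpha,
                               cutoff=config.cutoff_percentile)
        _fmt(cv, out / "loocv_groups.tsv")
        for grp in ("low", "high"):
            m = (cv["group"] == grp).to_numpy()
            if m.any():
                km = km_estimate(t[m], e[m])
                _fmt(km.to_frame(), out / f"km_{grp}.tsv")
        perm = permutation_significance(
            X, t, e, n_perm=config.permutations,
            seed=config.stage_seed("risk_predict"),
            selection_alpha=config.survival_alpha,
            cutoff=config.cutoff_percentile)
        _fmt(pd.DataFrame([{"lr_observed": perm.lr_observed, "p": perm.p,
                            "n_perm": perm.n_perm}]),
             out / "permutation.tsv", index=False)
        report["headline"]["loocv_high_risk_n"] = int((cv["group"] == "high").sum())
        report["headline"]["lr_observed"] = perm.lr_observed
        report["headline"]["permutation_p"] = perm.p

    def eval_pairs():
        model = state["model"]
        direction = pd.Series(model.weights, index=model.selected_features)
        pair_cohort = generate_pairs(state["surv_cohort"], direction)
        Xp = drop_sparse_and_impute(pair_cohort.mirna_expression(),
                                    config.max_missing_frac)
        write_expression_tsv(Xp, out / "expression_pairs_mirna.tsv")
        write_clinical_tsv(pair_cohort.clinical_table(), out / "clinical_pairs.tsv")
        results = evaluate_pairs(model, Xp, pair_cohort.pairs)
        _fmt(pairs_table(results), out / "pair_predictions.tsv", index=False)
        summary = summarize_pairs(results)
        report["headline"]["pairs"] = {
            "n_pairs": summary.n_pairs,
            "pre_low": summary.n_pre_low,
            "overall_correct": summary.n_correct,
        }

    def qpcr():
        ct = generate_ct_table(seed=config.stage_seed("qpcr"))
        write_ct_tsv(ct, out / "ct_table.tsv")
        per_sample, per_target = analyze_ct_table(ct)
        _fmt(per_sample, out / "qpcr_expression.tsv", index=False)
        _fmt(per_target, out / "qpcr_group_comparison.tsv", index=False)
        report["headline"]["qpcr_min_p"] = float(per_target["p"].min())

    run_stage("simulate", simulate)
    run_stage("preprocess", preprocess)
    run_stage("class_predict", class_predict)
    run_stage("survival_screen", survival_screen)
    run_stage("risk_predict", risk_predict)
    run_stage("evaluate_pairs", eval_pairs)
    run_stage("qpcr", qpcr)

    _write_report(report, caught, out)
    return report


def _write_report(report: dict, caught: list, out: Path) -> None:
    report["warnings"] = sorted(set(caught))
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
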