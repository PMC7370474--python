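"""End-to-end orchestration: cohort → Relief-F selection → classifier
benchmark → balanced random forest → assessment → importance consensus.

A single global seed is fanned out deterministically per stage (SHA-256 of
stage name + seed), so one number reproduces the whole run; every artifact is
written to the output directory with its checksum recorded in the run report.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import brf as brf_mod
from . import cohort as cohort_mod
from . import importance as imp_mod
from . import metrics as mx
from . import relief as relief_mod
from . import splits as splits_mod

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline",
           "stage_seed"]

logger = logging.getLogger(__name__)

DEFAULTS: dict = {
    "input_csv": None,
    "outdir": "pheoihd_out",
    "seed": 0,
    "log_level": "INFO",
    "cohort": {
        "n_total": None,        # None -> reference cohort size (283)
        "prevalence": None,     # None -> reference prevalence (74/283)
        "encoding_mode": None,  # None keeps per-feature defaults
    },
    "relief": {"m": "all", "k": 10, "cutoff": -24.0},
    "benchmark": {"enabled": True, "schemes": "default9", "classifiers": "default7"},
    "brf": {"m": 21, "n": "auto", "trees_per_forest": 100, "train_frac": 0.6,
            "stratified": True},
    "consensus": {"k": 5, "min_lists": 2},
    "ci": {"level": 0.95, "replicates": 2000},
}


@dataclass(frozen=True)
class PipelineConfig:
    settings: dict

    def __getitem__(self, key):
        return self.settings[key]


def _merge_checked(defaults: dict, user: dict, path: str = "") -> dict:
    merged = copy.deepcopy(defaults)
    for key, value in user.items():
        where = f"{path}{key}"
        if key not in defaults:
            raise ValueError(f"unknown configuration key: {where!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            merged[key] = _merge_checked(defaults[key], value, where + ".")
        else:
            merged[key] = value
    return merged


def validate_config(raw: str | dict | None = None) -> PipelineConfig:
    """Parse YAML/dict configuration, fill defaults, reject unknown keys and
    out-of-range values with messages naming the offending key."""
    if raw is None:
        user = {}
    elif isinstance(raw, dict):
        user = raw
    else:
        user = yaml.safe_load(raw) or {}
        if not isinstance(user, dict):
            raise ValueError("configuration must be a mapping")
    cfg = _merge_checked(DEFAULTS, user)

    prev = cfg["cohort"]["prevalence"]
    if prev is not None and not 0.0 <= prev <= 1.0:
        raise ValueError(f"cohort.prevalence must lie in [0, 1], got {prev}")
    n_total = cfg["cohort"]["n_total"]
    if n_total is not None and n_total < 1:
        raise ValueError(f"cohort.n_total must be >= 1, got {n_total}")
    tf = cfg["brf"]["train_frac"]
    if not 0.0 < tf < 1.0:
        raise ValueError(f"brf.train_frac must lie in (0, 1), got {tf}")
    if not 0.0 < cfg["ci"]["level"] < 1.0:
        raise ValueError(f"ci.level must lie in (0, 1), got {cfg['ci']['level']}")
    relief_mod.ReliefConfig(m=cfg["relief"]["m"], k=cfg["relief"]["k"])
    imp_mod.ConsensusConfig(k=cfg["consensus"]["k"],
                            min_lists=cfg["consensus"]["min_lists"])
    mode = cfg["cohort"]["encoding_mode"]
    if mode is not None and mode not in ("numerical", "categorical"):
        raise ValueError(f"cohort.encoding_mode must be numerical/categorical, got {mode!r}")
    if cfg["input_csv"] is not None and not Path(cfg["input_csv"]).exists():
        raise ValueError(f"input_csv does not exist: {cfg['input_csv']}")
    return PipelineConfig(cfg)


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    consensus: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def record(self, name: str, status: str, seconds: float = 0.0,
               reason: str | None = None, artifacts: dict | None = None) -> None:
        self.stages[name] = {"status": status, "seconds": round(seconds, 3),
                             "reason": reason, "artifacts": artifacts or {}}

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"stages": self.stages, "consensus": self.consensus,
             "config": self.config, "seeds": self.seeds},
            indent=1, sort_keys=True, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _artifact(outdir: Path, name: str) -> tuple[Path, dict]:
    path = outdir / name
    return path, {"path": str(path)}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis. Later stages only ever see the feature set
    the selection stage produced, and test rows are held out before the
    ensemble trains. A stage failure halts the run with completed stages and
    their artifacts retained in the report."""
    cfg = config.settings
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), logging.INFO))
    report = RunReport(config=copy.deepcopy(cfg))
    seed = int(cfg["seed"])

    def finish(stage, t0, artifacts):
        for meta in artifacts.values():
            meta["sha256"] = _sha256(Path(meta["path"]))
        report.record(stage, "complete", time.perf_counter() - t0, artifacts=artifacts)

    # --- stage: cohort -----------------------------------------------------
    t0 = time.perf_counter()
    report.seeds["cohort"] = stage_seed(seed, "cohort")
    if cfg["input_csv"]:
        cohort = cohort_mod.Cohort.from_csv(cfg["input_csv"])
        if cfg["cohort"]["encoding_mode"]:
            cohort = cohort_mod.Cohort(
                cohort.features, cohort.labels,
                tuple(cohort_mod.set_encoding_mode(cohort.schema,
                                                   cfg["cohort"]["encoding_mode"])))
    else:
        cc = cohort_mod.default_config(
            n_total=cfg["cohort"]["n_total"], prevalence=cfg["cohort"]["prevalence"],
            seed=report.seeds["cohort"], encoding_mode=cfg["cohort"]["encoding_mode"])
        cohort = cohort_mod.sample_cohort(cc)
    cohort_path, cohort_art = _artifact(outdir, "cohort.csv")
    cohort.to_csv(cohort_path)
    arts = {"cohort": cohort_art,
            "schema": {"path": str(cohort_path.with_suffix(".schema.json"))}}
    finish("cohort", t0, arts)

    # --- stage: relief -----------------------------------------------------
    t0 = time.perf_counter()
    report.seeds["relief"] = stage_seed(seed, "relief")
    rcfg = relief_mod.ReliefConfig(m=cfg["relief"]["m"], k=cfg["relief"]["k"],
                                   seed=report.seeds["relief"])
    weights = relief_mod.relief_f_weights(cohort, rcfg)
    selected = relief_mod.select_above(weights, cfg["relief"]["cutoff"])
    weights_path, weights_art = _artifact(outdir, "relief_weights.csv")
    weights.to_csv(weights_path, index=False)
    finish("relief", t0, {"weights": weights_art})

    if not selected:
        for stage in ("benchmark", "brf", "importance"):
            report.record(stage, "skipped", reason="empty feature set after Relief-F cutoff")
        report.to_json(outdir / "report.json")
        return report

    # --- stage: benchmark --------------------------------------------------
    t0 = time.perf_counter()
    if cfg["benchmark"]["enabled"]:
        report.seeds["benchmark"] = stage_seed(seed, "benchmark")
        Xb = cohort_mod.design_matrix(cohort, features=selected)
        schemes = (splits_mod.default_schemes()
                   if cfg["benchmark"]["schemes"] == "default9"
                   else [splits_mod.SplitScheme(**s) for s in cfg["benchmark"]["schemes"]])
        classifiers = (splits_mod.default_classifiers()
                       if cfg["benchmark"]["classifiers"] == "default7"
                       else {name: splits_mod.default_classifiers()[name]
                             for name in cfg["benchmark"]["classifiers"]})
        bench = splits_mod.run_benchmark(Xb, cohort.labels, schemes, classifiers,
                                         seed=report.seeds["benchmark"])
        bench_path, bench_art = _artifact(outdir, "benchmark.csv")
        bench.to_csv(bench_path)
        finish("benchmark", t0, {"grid": bench_art})
    else:
        report.record("benchmark", "skipped", reason="disabled in configuration")

    # --- stage: brf --------------------------------------------------------
    t0 = time.perf_counter()
    report.seeds["brf_split"] = stage_seed(seed, "brf_split")
    report.seeds["brf_train"] = stage_seed(seed, "brf_train")
    # the ensemble treats every retained attribute as continuous
    Xm = cohort_mod.design_matrix(cohort, features=selected, mode="numerical")
    plan = splits_mod.make_holdout(len(cohort), cfg["brf"]["train_frac"],
                                   stratified=cfg["brf"]["stratified"],
                                   labels=cohort.labels,
                                   seed=report.seeds["brf_split"])
    train, test = plan.pairs[0]
    n_cfg = cfg["brf"]["n"]
    bcfg = brf_mod.BRFConfig(
        m=cfg["brf"]["m"], n=None if n_cfg in ("auto", None) else int(n_cfg),
        trees_per_forest=cfg["brf"]["trees_per_forest"],
        seed=report.seeds["brf_train"])
    model = brf_mod.train_brf(Xm.iloc[train], bcfg, y=cohort.labels[train])

    y_test = cohort.labels[test]
    predicted = brf_mod.predict_brf(model, Xm.iloc[test])
    score_pos = 1.0 - brf_mod.predict_score(model, Xm.iloc[test])  # positive = y 0
    cm = mx.confusion(y_test, predicted, positive_label=0)
    ms = mx.metric_set(cm)
    curve = mx.roc_curve(score_pos, y_test, positive_label=0)
    auc_value = mx.auc(curve)
    report.seeds["brf_ci"] = stage_seed(seed, "brf_ci")
    ci = mx.metric_ci(score_pos, y_test, metric="auc", level=cfg["ci"]["level"],
                      replicates=cfg["ci"]["replicates"], seed=report.seeds["brf_ci"])

    pred_path, pred_art = _artifact(outdir, "brf_predictions.csv")
    pd.DataFrame({"row": test, "truth": y_test, "predicted": predicted,
                  "score_positive": score_pos}).to_csv(pred_path, index=False)
    roc_path, roc_art = _artifact(outdir, "brf_roc.csv")
    pd.DataFrame({"threshold": curve.thresholds, "fpr": curve.fpr,
                  "tpr": curve.tpr}).to_csv(roc_path, index=False)
    metrics_path, metrics_art = _artifact(outdir, "brf_metrics.json")
    metrics_path.write_text(json.dumps({
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
                      "positive": cm.positive_class_meaning},
        "metrics": ms.as_dict(), "auc": round(auc_value, 4),
        "auc_ci": [round(ci[0], 4), round(ci[1], 4)],
        "test_size": int(len(test)),
        "selected_features": selected}, indent=1))
    finish("brf", t0, {"predictions": pred_art, "roc": roc_art,
                       "metrics": metrics_art})

    # --- stage: importance -------------------------------------------------
    t0 = time.perf_counter()
    report.seeds["importance"] = stage_seed(seed, "importance")
    mda_scores = imp_mod.mda(model, seed=report.seeds["importance"])
    mdg_scores = imp_mod.mdg(model)
    relief_scores = weights.set_index("feature")["weight"]
    relief_scores = relief_scores[relief_scores.index.isin(model.feature_names)]
    ccfg = imp_mod.ConsensusConfig(k=min(cfg["consensus"]["k"], len(model.feature_names)),
                                   min_lists=cfg["consensus"]["min_lists"])
    consensus = imp_mod.consensus_select(mda_scores, mdg_scores, relief_scores, ccfg)
    table = imp_mod.build_importance_table(mda_scores, mdg_scores, relief_scores)
    imp_path, imp_art = _artifact(outdir, "importance.csv")
    table.to_csv(imp_path, index=False)
    cons_path, cons_art = _artifact(outdir, "consensus.txt")
    cons_path.write_text("\n".join(consensus) + "\n")
    finish("importance", t0, {"table": imp_art, "consensus": cons_art})
    report.consensus = consensus

    report.to_json(outdir / "report.json")
    return report
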