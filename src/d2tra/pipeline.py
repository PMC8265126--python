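"""End-to-end orchestration: synth → das28 → classify → features → models → embed.

A single YAML (or dict) config drives every stage; each stage receives a
seed derived from the master seed by a fixed documented offset (master + k
for stage number k), all artifacts are written under one output directory,
and a :class:`RunManifest` records the config hash, per-stage seeds and row
counts so a rerun with the same manifest reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import d2t_rules, das28, dimred_hema, ehr_io, feature_engineering, letter_mining, models
from .synthetic_ehr import GeneratorConfig, generate_cohort

__all__ = ["RunManifest", "run_pipeline", "default_config", "StageError"]

#: fixed seed offsets per stage (documented contract: stage_seed = master + offset)
STAGE_SEEDS = {
    "synth": 0,
    "das28": 1,
    "features": 2,
    "importance": 3,
    "identify": 4,
    "predict": 5,
    "embed": 6,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_config() -> dict:
    """Demo configuration: a 500-patient cohort with moderate missingness."""
    return {
        "seed": 42,
        "generator": {
            "n_patients": 500,
            "d2t_prevalence": 0.2,
            "noise_sd": 0.3,
            "negation_rate": 0.3,
            "clinical_label_fraction": 0.3,
            "missingness_rates": {"labs": 0.1, "clinical_measurements": 0.3},
        },
        "das28": {"family": "xgboost"},
        "importance": {"n_boot": 200, "alpha": 0.05},
        "identification": {"n_folds": 10},
        "prediction": {"threshold": 0.15, "n_folds": 10},
        "embedding": {"n_neighbors": 15},
    }


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    master_seed: int
    stage_seeds: dict[str, int]
    paths: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _report_dict(report: models.EvalReport) -> dict:
    out = {
        "tp": report.tp, "fp": report.fp, "fn": report.fn, "tn": report.tn,
        "sensitivity_pct": report.sensitivity,
        "specificity_pct": report.specificity,
    }
    if report.auc is not None:
        out["auc"] = report.auc
        out["auc_interval"] = list(report.auc_interval) if report.auc_interval else None
    return out


def run_pipeline(config, out_dir: str | Path) -> RunManifest:
    """Run every stage on a freshly generated synthetic cohort.

    Writes under ``out_dir``: the bundle directory, classification CSVs,
    the feature table, the importance report, model evaluation JSONs, the
    embedding CSV with Y-scores, a combined ``report.json`` and the
    ``manifest.json``.  A stage failure aborts with :class:`StageError`;
    artifacts of completed stages are retained.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(cfg.get("seed", 0))
    seeds = {k: master + v for k, v in STAGE_SEEDS.items()}
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        master_seed=master,
        stage_seeds=seeds,
    )
    report: dict = {}
    taxonomy = d2t_rules.MoaTaxonomy.default()

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # pragma: no cover - error path
                manifest.save(out / "manifest.json")
                raise StageError(name, exc) from exc
        return deco

    state: dict = {}

    @stage("synth")
    def _synth():
        gen_cfg = GeneratorConfig(**{**cfg.get("generator", {}), "seed": seeds["synth"]})
        bundle = generate_cohort(gen_cfg)
        ehr_io.write_bundle(bundle, out / "bundle")
        state["bundle"] = bundle
        manifest.paths["bundle"] = str(out / "bundle")
        manifest.row_counts.update({k: len(v) for k, v in bundle.tables().items()})
        manifest.row_counts["letters"] = len(bundle.letters)

    @stage("validate")
    def _validate():
        reports = ehr_io.validate_schema(state["bundle"])
        report["schema"] = {
            r.table_name: {"missing_columns": r.missing_columns, "bad_rows": r.bad_rows}
            for r in reports
        }

    @stage("das28")
    def _das28():
        bundle = state["bundle"]
        try:
            approx = das28.train_das28_approximator(
                bundle, family=cfg.get("das28", {}).get("family", "xgboost"),
                seed=seeds["das28"],
            )
            state["approximator"] = approx
            report["das28_approximator"] = {
                "held_out_mae": approx.mae,
                "n_train": approx.n_train,
                "n_test": approx.n_test,
            }
        except ValueError:
            state["approximator"] = None
            report["das28_approximator"] = {"held_out_mae": None, "note": "too few complete visits"}

    @stage("classify_structured")
    def _classify_structured():
        bundle = state["bundle"]
        results = d2t_rules.classify_structured(
            bundle, taxonomy, approximator=state["approximator"]
        )
        frame = d2t_rules.results_to_frame(results)
        frame.to_csv(out / "classification_structured.csv", index=False)
        state["structured"] = frame.set_index("patient_id")["label"]
        truth = bundle.patients.set_index("patient_id")
        ev = models.evaluate(
            state["structured"].reindex(truth.index), truth["planted_truth"]
        )
        report["structured_vs_planted"] = _report_dict(ev)
        labeled = truth[truth["clinical_label"].isin(["D2T", "nonD2T"])]
        if len(labeled):
            ev2 = models.evaluate(
                state["structured"].reindex(labeled.index), labeled["clinical_label"]
            )
            report["structured_vs_clinical"] = _report_dict(ev2)

    @stage("classify_letters")
    def _classify_letters():
        bundle = state["bundle"]
        lexicon = letter_mining.Lexicon.default()
        by_patient: dict[str, list] = {pid: [] for pid in bundle.patient_ids()}
        for letter in bundle.letters:
            by_patient.setdefault(letter.patient_id, []).append(letter)
        results = [
            letter_mining.classify_unstructured(ls, lexicon, patient_id=pid)
            for pid, ls in by_patient.items()
        ]
        frame = d2t_rules.results_to_frame(results)
        frame.to_csv(out / "classification_letters.csv", index=False)
        state["unstructured"] = frame.set_index("patient_id")["label"]
        truth = bundle.patients.set_index("patient_id")
        ev = models.evaluate(
            state["unstructured"].reindex(truth.index), truth["planted_truth"]
        )
        report["letters_vs_planted"] = _report_dict(ev)
        if "letter_label" in truth.columns:
            ev2 = models.evaluate(
                state["unstructured"].reindex(truth.index), truth["letter_label"]
            )
            report["letters_vs_letter_truth"] = _report_dict(ev2)

    @stage("features")
    def _features():
        bundle = state["bundle"]
        records = das28.measured_das28_records(bundle)
        if state["approximator"] is not None:
            records = records + das28.approximate_das28(state["approximator"], bundle)
        table = feature_engineering.assemble_features(
            bundle, records, label_source=cfg.get("features", {}).get("label_source", "clinical")
        )
        table.to_csv(out / "features.csv")
        state["features"] = table
        manifest.row_counts["features"] = len(table)

    @stage("importance")
    def _importance():
        imp_cfg = cfg.get("importance", {})
        table = state["features"]
        std = feature_engineering.standardize_features(table)
        imputed = feature_engineering.impute_features(std, seed=seeds["importance"])
        selected = feature_engineering.fdr_filter(imputed, alpha=imp_cfg.get("alpha", 0.05))
        report["fdr_selected"] = len(selected)
        if not selected:
            report["importance_note"] = "no features survived the FDR filter"
            return
        sub = imputed[selected + [feature_engineering.LABEL_COLUMN]]
        n = len(sub)
        test_size = imp_cfg.get("test_size") or max(4, int(round(n * 12 / 152)))
        train_size = imp_cfg.get("train_size") or (n - test_size)
        imp = feature_engineering.bootstrap_l1_importance(
            sub,
            n_boot=imp_cfg.get("n_boot", 200),
            train_size=train_size,
            test_size=test_size,
            seed=seeds["importance"],
        )
        imp.table.to_csv(out / "importance.csv")
        report["importance_top10"] = imp.top(10).index.tolist()

    @stage("identify")
    def _identify():
        results = models.D2TIdentificationModel(state["features"]).fit(
            n_folds=cfg.get("identification", {}).get("n_folds", 10),
            seed=seeds["identify"],
        )
        report["identification"] = _report_dict(results.report)
        with open(out / "identification_report.json", "w", encoding="utf-8") as fh:
            json.dump(report["identification"], fh, indent=2)

    @stage("predict")
    def _predict():
        pred_cfg = cfg.get("prediction", {})
        results = models.D2TPredictionModel(
            state["bundle"], taxonomy,
            label_source=pred_cfg.get("label_source", "clinical"),
        ).fit(
            threshold=pred_cfg.get("threshold", 0.15),
            n_folds=pred_cfg.get("n_folds", 10),
            seed=seeds["predict"],
        )
        report["prediction"] = _report_dict(results.report)
        with open(out / "prediction_report.json", "w", encoding="utf-8") as fh:
            json.dump(report["prediction"], fh, indent=2)

    @stage("embed")
    def _embed():
        bundle = state["bundle"]
        model = dimred_hema.HematologyEmbedding(bundle)
        _, medians = model.fit(
            n_neighbors=cfg.get("embedding", {}).get("n_neighbors", 15),
            seed=seeds["embed"],
        )
        truth = bundle.patients.set_index("patient_id")
        scores = {}
        for pid in medians.index:
            clinical = truth.loc[pid, "clinical_label"] if pid in truth.index else "unlabeled"
            scores[pid] = dimred_hema.compute_y_score(
                structured=state["structured"].get(pid) == "D2T",
                unstructured=state["unstructured"].get(pid) == "D2T",
                clinical=None if clinical == "unlabeled" else clinical == "D2T",
                patient_id=pid,
            ).score
        medians = medians.copy()
        medians["y_score"] = pd.Series(scores)
        medians.to_csv(out / "embedding.csv")
        report["embedding"] = {"n_patients": len(medians)}

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    for key in ("structured_vs_planted", "identification", "prediction"):
        if key in report:
            for metric in ("sensitivity_pct", "specificity_pct", "auc"):
                if report[key].get(metric) is not None:
                    manifest.metrics[f"{key}.{metric}"] = float(report[key][metric])
    manifest.paths["report"] = str(out / "report.json")
    manifest.save(out / "manifest.json")
    return manifest
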