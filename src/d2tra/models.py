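"""Identification and prediction models with cross-validated evaluation.

The *identification* model separates D2T from non-D2T patients using all
structured data (gradient-boosted trees, which consume missing values
natively, evaluated with stratified 10-fold cross-validated ROC/AUC).  The
*prediction* model uses only data from before each patient's first b/tsDMARD
start: the longitudinal record is censored there, regularized to a
one-month grid by forward fill-in (the last known value is carried forward,
never backward), aggregated per patient, and classified at a configurable
decision threshold (0.15 by default, trading specificity for sensitivity in
a screening setting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ehr_io import CohortBundle

__all__ = [
    "EvalReport",
    "MonthlyGrid",
    "evaluate",
    "truncate_before_first_btsdmard",
    "regularize_timeline",
    "monthly_grid_features",
    "D2TIdentificationModel",
    "D2TPredictionModel",
    "CrossValResults",
    "train_identification_model",
    "train_prediction_model",
]

DAYS_PER_MONTH = 30.44


@dataclass
class EvalReport:
    """Confusion matrix and derived operating characteristics.

    Sensitivity and specificity are percentages (``100·TP/(TP+FN)`` and
    ``100·TN/(TN+FP)``); ``summary()`` rounds them to whole percent, the
    convention of clinical validation tables.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    auc: float | None = None
    auc_interval: tuple[float, float] | None = None
    n_folds: int | None = None
    threshold: float | None = None

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return 100.0 * self.tn / denom if denom else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return 100.0 * (self.tp + self.tn) / total if total else float("nan")

    def summary(self) -> str:
        lines = [
            "Classification performance",
            "=" * 30,
            f"            true D2T   true nonD2T",
            f"pred D2T    {self.tp:8d}   {self.fp:11d}",
            f"pred nonD2T {self.fn:8d}   {self.tn:11d}",
            f"sensitivity: {self.sensitivity:.0f}%",
            f"specificity: {self.specificity:.0f}%",
        ]
        if self.auc is not None:
            ci = (
                f" (95% CI {self.auc_interval[0]:.2f}–{self.auc_interval[1]:.2f})"
                if self.auc_interval
                else ""
            )
            lines.append(f"AUC-ROC:     {self.auc:.2f}{ci}")
        if self.threshold is not None:
            lines.append(f"decision threshold: {self.threshold}")
        return "\n".join(lines)


def evaluate(
    predicted,
    truth,
    positive: str = "D2T",
    auc: float | None = None,
    auc_interval=None,
    n_folds=None,
    threshold=None,
) -> EvalReport:
    """Confusion matrix of predicted vs true labels (positive class D2T)."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} vs {len(truth)}")
    tp = sum(1 for p, t in zip(predicted, truth) if p == positive and t == positive)
    fp = sum(1 for p, t in zip(predicted, truth) if p == positive and t != positive)
    fn = sum(1 for p, t in zip(predicted, truth) if p != positive and t == positive)
    tn = sum(1 for p, t in zip(predicted, truth) if p != positive and t != positive)
    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        auc=auc, auc_interval=auc_interval, n_folds=n_folds, threshold=threshold,
    )


# ---------------------------------------------------------------------------
# pre-treatment censoring and the monthly grid


def truncate_before_first_btsdmard(bundle: CohortBundle, taxonomy=None) -> CohortBundle:
    """Censor every patient's record at their first b/tsDMARD start.

    Records dated on/after the start are removed; patients who never
    received a b/tsDMARD have no censor event and are dropped entirely.
    """
    from .d2t_rules import MoaTaxonomy, moa_start_sequence

    taxonomy = taxonomy or MoaTaxonomy.default()
    censor: dict[str, pd.Timestamp] = {}
    if len(bundle.prescriptions):
        for pid, group in bundle.prescriptions.groupby("patient_id"):
            seq = moa_start_sequence(group, taxonomy)
            if seq:
                censor[pid] = pd.Timestamp(seq[0][1])
    out = bundle.copy()
    out.patients = out.patients[out.patients["patient_id"].isin(censor)].reset_index(drop=True)
    keep_ids = set(censor)

    def _cut(table: pd.DataFrame, date_col: str) -> pd.DataFrame:
        if not len(table):
            return table
        t = table[table["patient_id"].isin(keep_ids)].copy()
        dates = pd.to_datetime(t[date_col])
        limits = t["patient_id"].map(censor)
        return t[dates < limits].reset_index(drop=True)

    out.prescriptions = _cut(out.prescriptions, "start_date")
    out.labs = _cut(out.labs, "datetime")
    out.clinical_measurements = _cut(out.clinical_measurements, "date")
    out.visits = _cut(out.visits, "date")
    out.letters = [
        l
        for l in out.letters
        if l.patient_id in keep_ids and pd.Timestamp(l.date) < censor[l.patient_id]
    ]
    if out.letter_truth is not None and len(out.letter_truth):
        lt = out.letter_truth
        lt = lt[lt["patient_id"].isin(keep_ids)]
        out.letter_truth = lt[
            pd.to_datetime(lt["date"]) < lt["patient_id"].map(censor)
        ].reset_index(drop=True)
    out.censor_dates = censor  # type: ignore[attr-defined]
    return out


@dataclass
class MonthlyGrid:
    """Regular month-indexed, forward-filled feature matrix for one patient.

    Row ``k`` is the month starting ``k`` months (30.44 days) after the first
    observation; every cell holds the last value observed at or before that
    month's start, and no cell is dated on/after the censor date.
    """

    patient_id: str
    censor_date: pd.Timestamp
    grid: pd.DataFrame  # index: month number; columns: features


def regularize_timeline(
    observations: pd.DataFrame,
    censor_date,
    patient_id: str = "",
    interval_months: float = 1.0,
) -> MonthlyGrid:
    """Forward fill dated observations onto a regular monthly grid.

    ``observations`` is long-format (columns date, feature, value); rows on
    or after the censor date are discarded, the rest are binned to months
    since the first observation and carried forward.  Months before a
    feature's first observation stay missing — forward fill never moves a
    value backward in time.
    """
    censor = pd.Timestamp(censor_date)
    cols = {"date", "feature", "value"}
    if not cols.issubset(observations.columns):
        raise ValueError(f"observations must have columns {sorted(cols)}")
    obs = observations.copy()
    obs["date"] = pd.to_datetime(obs["date"])
    obs = obs[obs["date"] < censor]
    if not obs["date"].is_monotonic_increasing:
        obs = obs.sort_values("date", kind="mergesort")
    if obs.empty:
        return MonthlyGrid(patient_id, censor, pd.DataFrame())
    t0 = obs["date"].min()
    span_days = (censor - t0).total_seconds() / 86400.0
    month_days = interval_months * DAYS_PER_MONTH
    n_months = max(1, int(np.floor(span_days / month_days + 1e-9)) + 1)
    frac_days = (obs["date"] - t0).dt.total_seconds() / 86400.0
    obs["month"] = np.floor(frac_days / month_days + 1e-9).astype(int)
    wide = obs.pivot_table(index="month", columns="feature", values="value", aggfunc="mean")
    wide = wide.reindex(range(n_months)).ffill()
    wide.columns.name = None
    return MonthlyGrid(patient_id, censor, wide)


def monthly_grid_features(grid: MonthlyGrid, mean_diff_mode: str = "signed") -> dict[str, float]:
    """Per-patient aggregate features of a monthly grid's columns."""
    from .feature_engineering import aggregate_timeseries

    row: dict[str, float] = {}
    for col in grid.grid.columns:
        series = grid.grid[col].dropna().to_numpy()
        for name, value in aggregate_timeseries(series, mean_diff_mode).items():
            row[f"{col}_{name}"] = value
    row["n_grid_months"] = float(len(grid.grid))
    return row


def _bundle_observations(bundle: CohortBundle, pid: str) -> pd.DataFrame:
    """Long-format dated observations (labs + clinical measurements)."""
    pieces = []
    labs = bundle.labs
    if len(labs):
        pl = labs[labs["patient_id"] == pid]
        if len(pl):
            pieces.append(
                pd.DataFrame(
                    {
                        "date": pd.to_datetime(pl["datetime"]),
                        "feature": "lab_" + pl["test_code"].astype(str),
                        "value": pl["value"].astype(float),
                    }
                )
            )
    cm = bundle.clinical_measurements
    if len(cm):
        pc = cm[cm["patient_id"] == pid]
        for col in ("sjc28", "tjc28", "vas_gh", "systolic_bp", "weight"):
            if col in pc.columns and len(pc):
                pieces.append(
                    pd.DataFrame(
                        {
                            "date": pd.to_datetime(pc["date"]),
                            "feature": col,
                            "value": pc[col].astype(float),
                        }
                    )
                )
    if not pieces:
        return pd.DataFrame(columns=["date", "feature", "value"])
    return pd.concat(pieces, ignore_index=True)


# ---------------------------------------------------------------------------
# cross-validated XGBoost models


@dataclass
class CrossValResults:
    """Fitted classifier plus pooled out-of-fold evaluation."""

    model: object
    report: EvalReport
    fold_aucs: list[float]
    oof_probabilities: pd.Series
    feature_names: list[str]

    def summary(self) -> str:
        per_fold = ", ".join(f"{a:.2f}" for a in self.fold_aucs)
        return self.report.summary() + f"\nper-fold AUC: [{per_fold}]"


def _cross_validate(X: pd.DataFrame, y: pd.Series, n_folds: int, seed: int, threshold: float):
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold
    from xgboost import XGBClassifier

    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    positive = "D2T" if "D2T" in classes else classes[-1]
    yv = (y == positive).to_numpy(dtype=int)
    Xv = X.to_numpy(dtype=float)

    def make_model():
        return XGBClassifier(
            n_estimators=300,
            max_depth=3,
            learning_rate=0.1,
            subsample=0.9,
            n_jobs=1,
            random_state=int(seed) % (2**31),
            tree_method="hist",
            eval_metric="logloss",
        )

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**31))
    oof = np.full(len(yv), np.nan)
    fold_aucs = []
    for train_idx, test_idx in skf.split(Xv, yv):
        model = make_model()
        model.fit(Xv[train_idx], yv[train_idx])
        probs = model.predict_proba(Xv[test_idx])[:, 1]
        oof[test_idx] = probs
        if len(np.unique(yv[test_idx])) == 2:
            fold_aucs.append(float(roc_auc_score(yv[test_idx], probs)))

    auc_mean = float(np.mean(fold_aucs))
    auc_sd = float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0
    half = 1.96 * auc_sd / np.sqrt(len(fold_aucs)) if fold_aucs else 0.0
    interval = (max(0.0, auc_mean - half), min(1.0, auc_mean + half))

    pred_labels = np.where(oof >= threshold, positive, "nonD2T" if positive == "D2T" else classes[0])
    truth_labels = np.where(yv == 1, positive, "nonD2T" if positive == "D2T" else classes[0])
    report = evaluate(
        pred_labels,
        truth_labels,
        positive=positive,
        auc=auc_mean,
        auc_interval=interval,
        n_folds=n_folds,
        threshold=threshold,
    )

    final = make_model()
    final.fit(Xv, yv)
    return CrossValResults(
        model=final,
        report=report,
        fold_aucs=fold_aucs,
        oof_probabilities=pd.Series(oof, index=X.index, name="p_d2t"),
        feature_names=list(X.columns),
    )


class D2TIdentificationModel:
    """Gradient-boosted D2T identification from a patient feature table.

    Consumes the assembled feature table (missing values allowed — the tree
    ensemble routes them natively); ``fit`` runs stratified k-fold
    cross-validation and returns a :class:`CrossValResults` whose report
    pools the out-of-fold predictions.
    """

    def __init__(self, features: pd.DataFrame):
        from .feature_engineering import LABEL_COLUMN

        if LABEL_COLUMN not in features.columns:
            raise ValueError("feature table must carry a label column")
        self.X = features.drop(columns=[LABEL_COLUMN])
        self.y = features[LABEL_COLUMN]

    def fit(self, n_folds: int = 10, seed: int = 0, threshold: float = 0.5) -> CrossValResults:
        return _cross_validate(self.X, self.y, n_folds=n_folds, seed=seed, threshold=threshold)


class D2TPredictionModel:
    """Pre-treatment D2T prediction from forward-filled monthly grids.

    Built from a bundle: censors each patient at the first b/tsDMARD start,
    regularizes the pre-censor record to a monthly grid, aggregates it into
    per-patient features, and cross-validates an XGBoost classifier whose
    probabilities are thresholded at 0.15 by default.
    """

    def __init__(
        self,
        bundle: CohortBundle,
        taxonomy=None,
        label_source: str = "clinical",
        mean_diff_mode: str = "signed",
    ):
        truncated = truncate_before_first_btsdmard(bundle, taxonomy)
        censor = truncated.censor_dates  # type: ignore[attr-defined]
        patients = truncated.patients
        if label_source == "clinical":
            patients = patients[patients["clinical_label"].isin(["D2T", "nonD2T"])]
            labels = patients.set_index("patient_id")["clinical_label"]
        elif label_source == "planted":
            labels = patients.set_index("patient_id")["planted_truth"]
        else:
            raise ValueError(f"unknown label_source {label_source!r}")
        if labels.empty or labels.nunique() < 2:
            raise ValueError("need labeled patients of both classes before first b/tsDMARD")

        rows = []
        pts = truncated.patients.set_index("patient_id")
        for pid in labels.index:
            obs = _bundle_observations(truncated, pid)
            grid = regularize_timeline(obs, censor[pid], patient_id=pid)
            row = monthly_grid_features(grid, mean_diff_mode)
            row["female"] = 1.0 if pts.loc[pid, "sex"] == "F" else 0.0
            row["age_at_censor"] = float(censor[pid].year - int(pts.loc[pid, "birth_year"]))
            row["years_diagnosis_to_censor"] = (
                (censor[pid] - pd.Timestamp(pts.loc[pid, "ra_diagnosis_date"])).days / 365.25
            )
            row["patient_id"] = pid
            rows.append(row)
        table = pd.DataFrame(rows).set_index("patient_id")
        table = table.dropna(axis=1, how="all")
        self.X = table
        self.y = labels.reindex(table.index)
        self.truncated = truncated

    def fit(self, threshold: float = 0.15, n_folds: int = 10, seed: int = 0) -> CrossValResults:
        if not 0.0 < threshold <= 1.0:
            raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
        return _cross_validate(self.X, self.y, n_folds=n_folds, seed=seed, threshold=threshold)


def train_identification_model(features: pd.DataFrame, n_folds: int = 10, seed: int = 0):
    """Functional wrapper: ``(model, EvalReport)`` from a feature table."""
    results = D2TIdentificationModel(features).fit(n_folds=n_folds, seed=seed)
    return results.model, results.report


def train_prediction_model(
    bundle: CohortBundle,
    taxonomy=None,
    threshold: float = 0.15,
    n_folds: int = 10,
    seed: int = 0,
    label_source: str = "clinical",
):
    """Functional wrapper: ``(model, EvalReport)`` for the pre-treatment model."""
    results = D2TPredictionModel(bundle, taxonomy, label_source=label_source).fit(
        threshold=threshold, n_folds=n_folds, seed=seed
    )
    return results.model, results.report
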