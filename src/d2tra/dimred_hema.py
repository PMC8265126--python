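"""Supervised dimension reduction of longitudinal hematology, and the Y-score.

Every hematology sample (one blood draw, ~20 analyzer parameters) is
embedded into two dimensions with UMAP.  Training on clinically classified
patients uses the labels (supervised UMAP), which pulls the two classes into
strictly separated clusters; new cohorts are projected out-of-sample with
the fitted reducer.  Each patient is then summarised by the coordinate-wise
median of their sample embeddings over time.

The Y-score combines the available per-patient D2T calls — the structured
rule engine, the letter miner, and the clinical classification when present
— into a [0, 1] likelihood as the unweighted mean of the available binary
indicators (D2T = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ehr_io import CohortBundle
from .synthetic_ehr import HEMATOLOGY_PANEL

__all__ = [
    "YScore",
    "Embedding",
    "HematologyEmbedding",
    "compute_y_score",
    "embed_hematology",
    "patient_median_embedding",
    "hematology_sample_matrix",
]


@dataclass(frozen=True)
class YScore:
    """Combined likelihood of D2T RA for one patient."""

    patient_id: str
    score: float
    components: dict[str, bool | None]

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"Y-score must lie in [0, 1], got {self.score}")


def compute_y_score(
    structured: bool | None,
    unstructured: bool | None,
    clinical: bool | None,
    patient_id: str = "",
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> YScore:
    """Equal-weight mean of the available binary D2T indicators.

    ``None`` marks an absent component; at least one must be present.
    Custom ``weights`` reweight (structured, unstructured, clinical).
    """
    comps = {"structured": structured, "unstructured": unstructured, "clinical": clinical}
    values = []
    wsum = 0.0
    for w, (name, val) in zip(weights, comps.items()):
        if val is None:
            continue
        values.append(w * (1.0 if val else 0.0))
        wsum += w
    if not values:
        raise ValueError("Y-score undefined: all components absent")
    return YScore(patient_id=patient_id, score=float(sum(values) / wsum), components=comps)


def hematology_sample_matrix(
    bundle: CohortBundle, codes: list[str] | None = None
) -> pd.DataFrame:
    """Wide sample × parameter matrix: one row per (patient, draw datetime)."""
    codes = codes or list(HEMATOLOGY_PANEL)
    labs = bundle.labs
    hema = labs[labs["test_code"].isin(codes)]
    if hema.empty:
        return pd.DataFrame(columns=codes)
    wide = hema.pivot_table(
        index=["patient_id", "datetime"], columns="test_code", values="value", aggfunc="mean"
    )
    wide.columns.name = None
    return wide


@dataclass
class Embedding:
    """2-D UMAP coordinates per hematology sample, plus the fitted reducer."""

    sample_coords: pd.DataFrame  # index (patient_id, datetime); columns d1, d2
    supervised: bool
    seed: int
    _reducer: object = field(repr=False, default=None)
    _scaler_mean: pd.Series | None = field(repr=False, default=None)
    _scaler_sd: pd.Series | None = field(repr=False, default=None)

    def transform(self, samples: pd.DataFrame) -> pd.DataFrame:
        """Out-of-sample projection of new hematology samples."""
        X = self._prepare(samples)
        coords = self._reducer.transform(X)
        return pd.DataFrame(coords, index=samples.index, columns=["d1", "d2"])

    def _prepare(self, samples: pd.DataFrame) -> np.ndarray:
        X = samples.reindex(columns=self._scaler_mean.index)
        X = (X - self._scaler_mean) / self._scaler_sd
        return X.fillna(0.0).to_numpy(dtype=float)

    def patient_medians(self) -> pd.DataFrame:
        return patient_median_embedding(self.sample_coords)


def embed_hematology(
    samples: pd.DataFrame,
    labels: pd.Series | None = None,
    n_neighbors: int = 15,
    seed: int = 0,
    min_dist: float = 0.1,
    target_weight: float = 0.6,
) -> Embedding:
    """Embed a sample × parameter matrix into 2-D with (supervised) UMAP.

    Parameters are standardized and missing entries imputed at the training
    mean before reduction.  ``labels`` (per patient, indexed by patient_id)
    switch on supervised UMAP; samples of unlabeled patients may be present
    and enter as unsupervised points.  Deterministic under a fixed seed
    (single-threaded layout).
    """
    import umap

    if len(samples) < 10:
        raise ValueError(f"need >= 10 samples, got {len(samples)}")
    if len(samples) <= n_neighbors:
        raise ValueError(
            f"need more samples ({len(samples)}) than n_neighbors ({n_neighbors})"
        )
    mean = samples.mean()
    sd = samples.std(ddof=0).replace(0.0, 1.0)
    X = ((samples - mean) / sd).fillna(0.0).to_numpy(dtype=float)

    y = None
    supervised = labels is not None
    if supervised:
        pid_index = samples.index.get_level_values(0) if samples.index.nlevels > 1 else samples.index
        mapped = pd.Series(pid_index, index=samples.index).map(labels)
        y = mapped.map({"D2T": 1, "nonD2T": 0}).fillna(-1).to_numpy(dtype=int)

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=int(seed) % (2**31),
        target_weight=target_weight,
        n_jobs=1,
    )
    coords = reducer.fit_transform(X, y=y)
    frame = pd.DataFrame(coords, index=samples.index, columns=["d1", "d2"])
    return Embedding(
        sample_coords=frame,
        supervised=supervised,
        seed=seed,
        _reducer=reducer,
        _scaler_mean=mean,
        _scaler_sd=sd,
    )


def patient_median_embedding(
    sample_coords: pd.DataFrame, sample_to_patient: pd.Series | None = None
) -> pd.DataFrame:
    """Coordinate-wise median embedding per patient.

    With a MultiIndex (patient_id, datetime) the mapping is implicit;
    otherwise ``sample_to_patient`` must map every sample index to a
    patient (unmapped samples are an error).
    """
    coords = sample_coords
    if sample_to_patient is not None:
        mapped = sample_to_patient.reindex(coords.index)
        if mapped.isna().any():
            missing = coords.index[mapped.isna()].tolist()[:5]
            raise ValueError(f"samples not mapped to a patient: {missing}")
        group = mapped.to_numpy()
    elif coords.index.nlevels > 1:
        group = coords.index.get_level_values(0)
    else:
        raise ValueError("provide sample_to_patient or a (patient, datetime) MultiIndex")
    med = coords.groupby(group).median()
    med.columns = ["median_d1", "median_d2"]
    med.index.name = "patient_id"
    return med


class HematologyEmbedding:
    """Model-style wrapper: supervised hematology embedding for a cohort.

    Trains on the clinically labeled patients' samples and projects the
    whole cohort; ``fit`` returns the training :class:`Embedding` plus the
    per-patient median coordinates of everyone.
    """

    def __init__(
        self,
        bundle: CohortBundle,
        codes: list[str] | None = None,
        max_draws_per_patient: int | None = 8,
    ):
        samples = hematology_sample_matrix(bundle, codes)
        if max_draws_per_patient is not None and len(samples):
            # evenly spaced draws per patient keep the longitudinal span
            # while bounding the (single-threaded) layout cost
            keep = []
            for _, group in samples.groupby(level=0):
                if len(group) <= max_draws_per_patient:
                    keep.append(group)
                else:
                    idx = np.linspace(0, len(group) - 1, max_draws_per_patient).round().astype(int)
                    keep.append(group.iloc[np.unique(idx)])
            samples = pd.concat(keep)
        self.samples = samples
        self.bundle = bundle

    def fit(self, n_neighbors: int = 15, seed: int = 0, target_weight: float = 0.6):
        patients = self.bundle.patients
        labeled = patients[patients["clinical_label"].isin(["D2T", "nonD2T"])]
        labels = labeled.set_index("patient_id")["clinical_label"]
        pid_level = self.samples.index.get_level_values(0)
        train = self.samples[pid_level.isin(labels.index)]
        embedding = embed_hematology(
            train, labels=labels, n_neighbors=n_neighbors, seed=seed,
            target_weight=target_weight,
        )
        rest = self.samples[~pid_level.isin(labels.index)]
        coords = [embedding.sample_coords]
        if len(rest):
            coords.append(embedding.transform(rest))
        all_coords = pd.concat(coords)
        medians = patient_median_embedding(all_coords)
        return embedding, medians
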