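"""Datasets: the in-memory container, benchmark generators, I/O and splits.

The container is deliberately small: a dense feature matrix, a binary label
vector (0 = control, 1 = diseased) and, for clinical data with repeated
measurements, a per-record patient identifier used for grouped splitting
and per-patient aggregation of predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split


class DatasetError(ValueError):
    """Malformed dataset content or an impossible split request."""


@dataclass
class Dataset:
    """Tabular binary-classification data.

    Parameters
    ----------
    features : (n_records, n_features) float array
    labels : (n_records,) int array with values in {0, 1};
        0 is the control class, 1 the diseased class.
    patient_ids : optional (n_records,) array of identifiers; records that
        share an identifier belong to the same individual.
    feature_names : optional list of column names.
    """

    features: np.ndarray
    labels: np.ndarray
    patient_ids: np.ndarray | None = None
    feature_names: list | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise DatasetError("features must be a 2-D matrix")
        if len(self.labels) != len(self.features):
            raise DatasetError("labels length does not match features")
        if not np.all(np.isfinite(self.features)):
            raise DatasetError("features contain non-finite values")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise DatasetError("labels must be 0 (control) or 1 (diseased)")
        if self.patient_ids is not None:
            self.patient_ids = np.asarray(self.patient_ids)
            if len(self.patient_ids) != len(self.features):
                raise DatasetError("patient_ids length does not match features")
        if self.feature_names is not None:
            self.feature_names = list(self.feature_names)
            if len(self.feature_names) != self.features.shape[1]:
                raise DatasetError("feature_names length does not match features")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def n_records(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, idx) -> "Dataset":
        """Row subset (any numpy fancy index)."""
        return Dataset(
            self.features[idx], self.labels[idx],
            None if self.patient_ids is None else self.patient_ids[idx],
            self.feature_names,
        )


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on training data only."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        sd = X.std(axis=0)
        return cls(mean=X.mean(axis=0), sd=np.where(sd > 0, sd, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def apply(self, data: Dataset) -> Dataset:
        return Dataset(self.transform(data.features), data.labels,
                       data.patient_ids, data.feature_names)

    def to_dict(self) -> dict:
        return {"mean": [float(v) for v in self.mean],
                "sd": [float(v) for v in self.sd]}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(np.asarray(d["mean"], float), np.asarray(d["sd"], float))


def two_spiral(points_per_spiral: int = 97, noise_sd: float = 0.0,
               seed=None) -> Dataset:
    """The classic two-interleaved-spirals benchmark.

    For ``i = 0 .. P-1`` the angle is ``phi = i * pi / 16`` and the radius
    ``r = 6.5 * (104 - i) / 104``; the class-0 point is
    ``(r sin phi, r cos phi)`` and the class-1 point its negation, so at
    zero noise the two classes are exact mirror images through the origin.
    """
    if points_per_spiral < 1:
        raise DatasetError("points_per_spiral must be >= 1")
    i = np.arange(points_per_spiral)
    phi = i * np.pi / 16.0
    r = 6.5 * (104.0 - i) / 104.0
    p0 = np.column_stack([r * np.sin(phi), r * np.cos(phi)])
    X = np.vstack([p0, -p0])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        X = X + rng.normal(0.0, noise_sd, X.shape)
    y = np.r_[np.zeros(points_per_spiral, int), np.ones(points_per_spiral, int)]
    return Dataset(X, y, feature_names=["x", "y"])


def synth_clinical(n_patients: int = 40, records_per_patient: int = 26,
                   n_features: int = 26, class_balance: float = 0.5,
                   effect_size: float = 1.0, within_patient_corr: float = 0.5,
                   seed=None) -> Dataset:
    """Synthetic patient-structured clinical data.

    Emulates speech-recording style datasets in which every individual
    contributes several records: each patient gets a class label (diseased
    with proportion ``class_balance``), a latent per-patient feature mean
    drawn from a class-shifted Gaussian, and records equal to that mean plus
    independent noise.  Variances are chosen so each feature has unit total
    variance, the diseased-class marginal shift is ``effect_size`` standard
    deviations, and the correlation between two records of the same patient
    is ``within_patient_corr``.
    """
    if n_patients < 1 or records_per_patient < 1 or n_features < 1:
        raise DatasetError("all counts must be >= 1")
    if not 0.0 <= class_balance <= 1.0 or not 0.0 <= within_patient_corr <= 1.0:
        raise DatasetError("class_balance and within_patient_corr must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_diseased = int(round(n_patients * class_balance))
    patient_labels = np.r_[np.zeros(n_patients - n_diseased, int),
                           np.ones(n_diseased, int)]
    latent_sd = np.sqrt(within_patient_corr)
    noise_sd = np.sqrt(1.0 - within_patient_corr)
    latent = (rng.normal(0.0, 1.0, (n_patients, n_features)) * latent_sd
              + patient_labels[:, None] * effect_size)
    X = (np.repeat(latent, records_per_patient, axis=0)
         + rng.normal(0.0, 1.0, (n_patients * records_per_patient, n_features)) * noise_sd)
    y = np.repeat(patient_labels, records_per_patient)
    ids = np.repeat(np.array([f"P{p:04d}" for p in range(n_patients)]),
                    records_per_patient)
    names = [f"f{j}" for j in range(n_features)]
    return Dataset(X, y, patient_ids=ids, feature_names=names)


def holdout_split(data: Dataset, test_fraction: float = 0.10,
                  seed=None) -> tuple[Dataset, Dataset]:
    """Stratified train/test split; grouped by patient when ids exist.

    With patient ids the split is performed on patients (stratified by the
    patient's class), so no individual ever spans the split.
    """
    if len(data) == 0:
        raise DatasetError("cannot split an empty dataset")
    if not 0.0 < test_fraction < 1.0:
        raise DatasetError("test_fraction must be in (0, 1)")
    if data.patient_ids is not None:
        uniq, first = np.unique(data.patient_ids, return_index=True)
        pat_labels = data.labels[first]
        try:
            _, test_pat = train_test_split(
                uniq, test_size=test_fraction, stratify=pat_labels,
                random_state=seed)
        except ValueError as exc:
            raise DatasetError(f"too few patient groups to split: {exc}") from exc
        test_mask = np.isin(data.patient_ids, test_pat)
    else:
        idx = np.arange(len(data))
        try:
            _, test_idx = train_test_split(
                idx, test_size=test_fraction, stratify=data.labels,
                random_state=seed)
        except ValueError as exc:
            raise DatasetError(f"too few records to split: {exc}") from exc
        test_mask = np.zeros(len(data), bool)
        test_mask[test_idx] = True
    return data.subset(~test_mask), data.subset(test_mask)


def read_dataset(path, label_column: str = "label",
                 patient_column: str | None = None) -> Dataset:
    """Read a delimited-text dataset (comma separated, header row).

    Every non-label, non-id column is a numeric feature.  Errors name the
    offending column and 1-based file row (header is row 1).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if label_column not in df.columns:
        raise DatasetError(f"missing label column {label_column!r}")
    if patient_column is not None and patient_column not in df.columns:
        raise DatasetError(f"missing patient column {patient_column!r}")
    raw_labels = pd.to_numeric(df[label_column], errors="coerce")
    bad = ~raw_labels.isin([0, 1])
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise DatasetError(
            f"unknown label value {df[label_column][bad].iloc[0]!r} "
            f"in column {label_column!r}, row {row}")
    drop = [label_column] + ([patient_column] if patient_column else [])
    feat = df.drop(columns=drop)
    cols = []
    for c in feat.columns:
        vals = pd.to_numeric(feat[c], errors="coerce").to_numpy(float)
        bad = ~np.isfinite(vals)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2
            raise DatasetError(
                f"non-numeric feature value {feat[c].iloc[row - 2]!r} "
                f"in column {c!r}, row {row}")
        cols.append(vals)
    return Dataset(
        np.column_stack(cols) if cols else np.empty((len(df), 0)),
        raw_labels.to_numpy(int),
        patient_ids=None if patient_column is None else df[patient_column].to_numpy(),
        feature_names=list(feat.columns),
    )


def write_dataset(data: Dataset, path, label_column: str = "label",
                  patient_column: str = "patient_id") -> None:
    """Write a dataset as comma-separated text (full float precision)."""
    names = data.feature_names or [f"f{j}" for j in range(data.n_features)]
    df = pd.DataFrame(data.features, columns=names)
    df[label_column] = data.labels
    if data.patient_ids is not None:
        df[patient_column] = data.patient_ids
    df.to_csv(path, index=False, float_format=lambda v: format(v, ".17g"))
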