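"""Reading and writing the dataset triplet (features, responses, labels).

A dataset is three comma-separated files sharing a sample-id key column:

* ``features``  -- samples x genes expression matrix (real values),
* ``responses`` -- samples x drugs normalized AUC matrix (one column for the
  univariate case),
* ``labels``    -- one cancer-type label per sample (strings).

Files carry one header row; the first column is the sample id. Alignment is by
sample id, never by row order. Missing values are rejected outright: the
modelling code assumes complete data, and silently imputing drug sensitivities
would corrupt downstream comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "DatasetError",
    "AlignmentError",
    "load_dataset",
    "save_dataset",
    "save_predictions",
    "load_predictions",
    "dataset_from_arrays",
]


class DatasetError(ValueError):
    """Malformed dataset file (parse failure, duplicates, missing values)."""


class AlignmentError(DatasetError):
    """Sample ids do not line up across the dataset triplet."""


@dataclass
class Dataset:
    """In-memory, sample-aligned dataset.

    Labels are stored as contiguous integers ``1..K`` assigned in
    lexicographic order of the original label strings (``label_names[c-1]``
    recovers the string for category ``c``). The integer coding makes
    tie-breaking rules in the forest code deterministic.
    """

    features: np.ndarray          # (n, M) float
    responses: np.ndarray         # (n, r) float
    labels: np.ndarray            # (n,) int, values in 1..K
    sample_ids: list[str]
    feature_ids: list[str]
    label_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim == 1:
            self.responses = self.responses[:, None]
        self.labels = np.asarray(self.labels, dtype=int)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n = self.features.shape[0]
        if not (self.responses.shape[0] == self.labels.shape[0] == len(self.sample_ids) == n):
            raise DatasetError(
                f"row counts differ: features {n}, responses {self.responses.shape[0]}, "
                f"labels {self.labels.shape[0]}, sample_ids {len(self.sample_ids)}"
            )
        if n == 0:
            raise DatasetError("dataset has no samples")
        if self.features.shape[1] != len(self.feature_ids):
            raise DatasetError("feature_ids length does not match feature matrix width")
        for name, arr in (("features", self.features), ("responses", self.responses)):
            if not np.isfinite(arr).all():
                raise DatasetError(f"{name} contain non-finite values")
        k = self.n_classes
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > k:
            raise DatasetError(f"labels must lie in 1..{k}, got {present.tolist()}")
        if len(present) != k:
            raise DatasetError("every category 1..K must occur at least once")

    # -- conveniences --------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_responses(self) -> int:
        return self.responses.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.label_names) if self.label_names else int(self.labels.max())

    def subset(self, idx) -> "Dataset":
        """Row subset (keeps the global label coding, so K may shrink)."""
        idx = np.asarray(idx)
        labels = self.labels[idx]
        present = np.unique(labels)
        # recode to contiguous 1..K' so the subset is itself a valid Dataset
        remap = {int(c): i + 1 for i, c in enumerate(present)}
        return Dataset(
            features=self.features[idx],
            responses=self.responses[idx],
            labels=np.array([remap[int(c)] for c in labels]),
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            label_names=[self.label_names[c - 1] for c in present],
        )


def dataset_from_arrays(features, responses, labels, sample_ids=None,
                        feature_ids=None, label_names=None) -> Dataset:
    """Build a Dataset from arrays, generating ids and label coding as needed.

    ``labels`` may be strings (mapped lexicographically to 1..K) or already
    integer-coded 1..K (then ``label_names`` defaults to the string form of
    each code).
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    labels = np.asarray(labels)
    if labels.dtype.kind in "USO":
        names = sorted(set(labels.tolist()))
        coded = np.array([names.index(v) + 1 for v in labels.tolist()])
    else:
        coded = labels.astype(int)
        names = label_names or [str(c) for c in range(1, int(coded.max()) + 1)]
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(n)]
    if feature_ids is None:
        feature_ids = [f"g{j:04d}" for j in range(features.shape[1])]
    return Dataset(features, responses, coded, list(sample_ids), list(feature_ids), names)


def _read_numeric(path) -> pd.DataFrame:
    """Read a CSV with sample-id index, enforcing numeric, complete cells."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DatasetError(f"{path}: duplicate sample ids {dupes}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise DatasetError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        col = df.columns[df.isna().any().to_numpy().argmax()]
        row = df.index[df[col].isna().to_numpy().argmax()]
        raise DatasetError(f"{path}: missing value at row {row!r}, column {col!r} "
                           "(imputation is refused; clean the input)")
    return df


def load_dataset(features_path, responses_path, labels_path) -> Dataset:
    """Load and align the (features, responses, labels) triplet by sample id.

    The feature file defines the sample universe; the response file must cover
    exactly the same ids (any discrepancy is an alignment error). The label
    file must cover at least those ids; labels for unknown ids are ignored,
    and a category left with zero samples after alignment is dropped from the
    coding with a logged warning.
    """
    feats = _read_numeric(features_path)
    resps = _read_numeric(responses_path)

    labels_df = pd.read_csv(labels_path, index_col=0)
    if labels_df.index.duplicated().any():
        dupes = labels_df.index[labels_df.index.duplicated()].unique().tolist()
        raise DatasetError(f"{labels_path}: duplicate sample ids {dupes}")
    if labels_df.shape[1] < 1:
        raise DatasetError(f"{labels_path}: expected a label column after the sample id")
    label_series = labels_df.iloc[:, 0].astype(str)

    missing = feats.index.difference(resps.index).tolist()
    extra = resps.index.difference(feats.index).tolist()
    if missing or extra:
        raise AlignmentError(
            f"responses do not align with features: missing {missing}, unexpected {extra}"
        )
    missing_labels = feats.index.difference(label_series.index).tolist()
    if missing_labels:
        raise AlignmentError(f"labels missing for samples {missing_labels}")

    ids = feats.index.tolist()
    resps = resps.loc[ids]
    aligned_labels = label_series.loc[ids]

    all_names = sorted(set(label_series.tolist()))
    used_names = sorted(set(aligned_labels.tolist()))
    dropped = [name for name in all_names if name not in used_names]
    if dropped:
        logger.warning("dropping categories with no aligned samples: %s", dropped)

    coded = np.array([used_names.index(v) + 1 for v in aligned_labels.tolist()])
    return Dataset(
        features=feats.to_numpy(dtype=float),
        responses=resps.to_numpy(dtype=float),
        labels=coded,
        sample_ids=[str(i) for i in ids],
        feature_ids=[str(c) for c in feats.columns],
        label_names=used_names,
    )


def save_dataset(dataset: Dataset, prefix: str) -> dict:
    """Write the CSV triplet ``<prefix>_{features,responses,labels}.csv``."""
    paths = {
        "features": f"{prefix}_features.csv",
        "responses": f"{prefix}_responses.csv",
        "labels": f"{prefix}_labels.csv",
    }
    idx = pd.Index(dataset.sample_ids, name="sample_id")
    pd.DataFrame(dataset.features, index=idx, columns=dataset.feature_ids).to_csv(paths["features"], float_format="%.17g")
    resp_cols = [f"drug_{k + 1}" for k in range(dataset.n_responses)]
    pd.DataFrame(dataset.responses, index=idx, columns=resp_cols).to_csv(paths["responses"], float_format="%.17g")
    names = [dataset.label_names[c - 1] for c in dataset.labels]
    pd.DataFrame({"label": names}, index=idx).to_csv(paths["labels"])
    return paths


def save_predictions(sample_ids, predicted_categories, predicted_responses, path) -> None:
    """Write one row per sample: id, category, response_1..response_r.

    ``predicted_categories`` may be None (plain regression forest); the
    category column is then left empty. Values round-trip at full float
    precision (pandas writes repr-exact decimals).
    """
    responses = np.asarray(predicted_responses, dtype=float)
    if responses.ndim == 1:
        responses = responses[:, None]
    n, r = responses.shape
    if len(sample_ids) != n:
        raise ValueError("sample_ids and predictions have different lengths")
    if predicted_categories is None:
        cats = [""] * n
    else:
        cats = list(predicted_categories)
        if len(cats) != n:
            raise ValueError("categories and predictions have different lengths")
    frame = pd.DataFrame({"category": cats}, index=pd.Index(sample_ids, name="sample_id"))
    for k in range(r):
        frame[f"response_{k + 1}"] = responses[:, k]
    frame.to_csv(path, float_format="%.17g")


def load_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, float_precision="round_trip")
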