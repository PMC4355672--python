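"""Dataset container and delimited-text I/O for two-group time-course feature tables.

The universal input is a samples x features intensity matrix with per-sample
metadata: a group label (control ``C`` vs model ``M``), a time-point index
``i`` (0 <= i < N) and a sampling-time index ``j`` (0 <= j < p_i, always 0
when each time point has a single collection batch).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourseDataset",
    "DatasetSchema",
    "read_dataset",
    "write_dataset",
    "validate",
    "GROUP_CONTROL",
    "GROUP_MODEL",
]

GROUP_CONTROL = "C"
GROUP_MODEL = "M"

# tolerant ingestion aliases; anything else is an error
_GROUP_ALIASES = {
    "c": GROUP_CONTROL,
    "control": GROUP_CONTROL,
    "0": GROUP_CONTROL,
    "m": GROUP_MODEL,
    "model": GROUP_MODEL,
    "case": GROUP_MODEL,
    "1": GROUP_MODEL,
}


def normalize_group_label(label: object) -> str:
    """Map a raw group label to the canonical ``C``/``M``; raise on anything else."""
    key = str(label).strip().lower()
    try:
        return _GROUP_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown group label {label!r}: expected one of "
            "C/control/0 or M/model/case/1 (case-insensitive)"
        ) from None


@dataclass(frozen=True)
class DatasetSchema:
    """Column naming and layout conventions for the on-disk wide table."""

    sample_id: str = "sample_id"
    group: str = "group"
    time_point: str = "time_point"
    sampling_time: str = "sampling_time"
    delimiter: str | None = None  # None = infer from extension (.tsv/.txt -> tab)

    @property
    def metadata_columns(self) -> tuple[str, str, str, str]:
        return (self.sample_id, self.group, self.time_point, self.sampling_time)


@dataclass
class TimeCourseDataset:
    """Samples x features matrix plus (group, time point, sampling time) metadata.

    Parameters
    ----------
    values
        Non-negative intensity matrix, shape ``(n_samples, n_features)``.
    feature_ids
        Feature identifiers (e.g. ``"9.95_528.2631"`` retention-time_m/z
        strings); treated as opaque.
    group
        Per-sample canonical label, each ``"C"`` or ``"M"``.
    time_point
        Per-sample 0-based time-point index ``i``; indices must cover a
        contiguous range ``0..N-1`` with ``N >= 2``.
    sampling_time
        Per-sample 0-based within-time-point batch index ``j``.
    """

    values: np.ndarray
    feature_ids: list[str]
    group: np.ndarray
    time_point: np.ndarray
    sampling_time: np.ndarray
    sample_ids: list[str] | None = None
    time_point_labels: dict[int, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.group = np.asarray([normalize_group_label(g) for g in np.asarray(self.group)])
        self.time_point = np.asarray(self.time_point, dtype=int)
        self.sampling_time = np.asarray(self.sampling_time, dtype=int)
        n = self.values.shape[0]
        if self.sample_ids is None:
            self.sample_ids = [f"S{k}" for k in range(n)]
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]
        for name, arr in (
            ("feature_ids", self.feature_ids),
            ("group", self.group),
            ("time_point", self.time_point),
            ("sampling_time", self.sampling_time),
            ("sample_ids", self.sample_ids),
        ):
            expected = self.values.shape[1] if name == "feature_ids" else n
            if len(arr) != expected:
                raise ValueError(
                    f"{name} has length {len(arr)}, expected {expected} to match values"
                )
        if np.isnan(self.values).any():
            raise ValueError("values matrix contains missing entries after ingestion")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_time_points(self) -> int:
        """N, the number of time points."""
        return int(self.time_point.max()) + 1 if self.n_samples else 0

    @property
    def sampling_times_per_point(self) -> np.ndarray:
        """p_i: number of sampling times present at each time point."""
        p = np.zeros(self.n_time_points, dtype=int)
        for i in range(self.n_time_points):
            mask = self.time_point == i
            p[i] = int(self.sampling_time[mask].max()) + 1 if mask.any() else 0
        return p

    def group_codes(self) -> np.ndarray:
        """0 for C, 1 for M."""
        return (self.group == GROUP_MODEL).astype(np.int8)

    def subset_features(self, feature_ids: list[str]) -> "TimeCourseDataset":
        """Restrict to the given features, preserving their given order."""
        index = {f: k for k, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise KeyError(f"features not in dataset: {missing[:5]}")
        cols = [index[f] for f in feature_ids]
        return replace(self, values=self.values[:, cols].copy(), feature_ids=list(feature_ids))

    def to_frame(self, schema: DatasetSchema | None = None) -> pd.DataFrame:
        schema = schema or DatasetSchema()
        meta = pd.DataFrame(
            {
                schema.sample_id: self.sample_ids,
                schema.group: self.group,
                schema.time_point: self.time_point,
                schema.sampling_time: self.sampling_time,
            }
        )
        feats = pd.DataFrame(self.values, columns=self.feature_ids)
        return pd.concat([meta, feats], axis=1)


def _delimiter_for(path: str, schema: DatasetSchema) -> str:
    if schema.delimiter is not None:
        return schema.delimiter
    lower = str(path).lower()
    return "\t" if lower.endswith((".tsv", ".txt")) else ","


def read_dataset(path, schema: DatasetSchema | None = None) -> TimeCourseDataset:
    """Read a wide delimited table (one column per feature) into a dataset.

    Metadata columns are those named by *schema*; every other column is a
    feature. Group labels are mapped to the canonical ``C``/``M``. Row order
    is preserved. Raises on missing metadata columns, non-numeric feature
    cells (with the cell address) and unknown group labels (with the row).
    """
    schema = schema or DatasetSchema()
    df = pd.read_csv(path, sep=_delimiter_for(path, schema), float_precision="round_trip")
    for col in schema.metadata_columns:
        if col not in df.columns:
            raise ValueError(f"schema error: metadata column {col!r} missing from {path}")
    feature_cols = [c for c in df.columns if c not in schema.metadata_columns]
    values = np.empty((len(df), len(feature_cols)), dtype=float)
    for k, col in enumerate(feature_cols):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"parse error: non-numeric value {df[col].iloc[row]!r} "
                f"in feature column {col!r}, row {row}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ValueError(f"missing value in feature column {col!r}, row {row}")
        values[:, k] = converted.to_numpy(dtype=float)
    groups = []
    for row, raw in enumerate(df[schema.group]):
        try:
            groups.append(normalize_group_label(raw))
        except ValueError as exc:
            raise ValueError(f"row {row}: {exc}") from None
    raw_tp = df[schema.time_point]
    # map arbitrary time-point labels onto 0-based indices in sorted label order
    labels = sorted(pd.unique(raw_tp))
    label_to_index = {lab: i for i, lab in enumerate(labels)}
    time_point = np.array([label_to_index[t] for t in raw_tp], dtype=int)
    return TimeCourseDataset(
        values=values,
        feature_ids=feature_cols,
        group=np.asarray(groups),
        time_point=time_point,
        sampling_time=df[schema.sampling_time].to_numpy(dtype=int),
        sample_ids=[str(s) for s in df[schema.sample_id]],
        time_point_labels={i: lab for lab, i in label_to_index.items()},
    )


def write_dataset(dataset: TimeCourseDataset, path, schema: DatasetSchema | None = None) -> None:
    """Write the wide table with full float precision (repr round-trip)."""
    schema = schema or DatasetSchema()
    df = dataset.to_frame(schema)
    df.to_csv(path, sep=_delimiter_for(path, schema), index=False, float_format=None)


def validate(dataset: TimeCourseDataset) -> list[str]:
    """Return human-readable diagnostics; empty list iff all invariants hold."""
    diags: list[str] = []
    n_tp = dataset.n_time_points
    if n_tp < 2:
        diags.append(f"N={n_tp} time points; at least 2 required")
    present = np.unique(dataset.time_point)
    expected = np.arange(n_tp)
    if not np.array_equal(present, expected):
        diags.append(
            f"time points {sorted(present.tolist())} are not the contiguous range 0..{n_tp - 1}"
        )
    if (dataset.values < 0).any():
        s, f = map(int, np.argwhere(dataset.values < 0)[0])
        diags.append(
            f"negative intensity at sample {dataset.sample_ids[s]!r}, "
            f"feature {dataset.feature_ids[f]!r}"
        )
    for i in present.tolist():
        tp_mask = dataset.time_point == i
        for g in (GROUP_CONTROL, GROUP_MODEL):
            if not (tp_mask & (dataset.group == g)).any():
                diags.append(f"group {g} has no samples at time point {i}")
        j_present = np.unique(dataset.sampling_time[tp_mask])
        j_expected = np.arange(int(j_present.max()) + 1) if j_present.size else np.array([])
        if not np.array_equal(j_present, j_expected):
            diags.append(
                f"sampling times {sorted(j_present.tolist())} at time point {i} "
                "are not a contiguous range from 0"
            )
    return diags
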