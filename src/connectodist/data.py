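"""Data model and text I/O for functional connectomes.

Containers for per-subject functional connectivity (FC) matrices, cohorts of
them, parcellated region-by-time series, and region-to-functional-network
partitions, plus the standard construction steps: zero-phase Butterworth
band-pass filtering, Pearson-correlation FC estimation, run averaging and
network reordering.

All file formats are plain tab-separated text:

* matrices — a header row of region IDs followed by one numeric row per region;
* time series — regions as rows, first column the region ID;
* partitions — two columns (region_id, network_label);
* cohort manifests — three columns (subject_id, condition, relative_path).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "FCMatrix",
    "Cohort",
    "TimeSeriesSet",
    "NetworkPartition",
    "DEFAULT_NETWORKS",
    "bandpass_filter",
    "fc_from_timeseries",
    "average_runs",
    "reorder_by_partition",
    "read_matrix",
    "write_matrix",
    "read_cohort",
    "write_cohort",
    "read_partition",
    "write_partition",
    "read_timeseries",
    "write_timeseries",
]

#: Seven cortical systems plus a subcortical block — the canonical ordering.
DEFAULT_NETWORKS = ("VIS", "SM", "DA", "VA", "L", "FP", "DMN", "SUBC")

_SYM_TOL = 1e-10
_FLOAT_FMT = "%.17g"


@dataclass
class FCMatrix:
    """One subject's symmetric Pearson-correlation matrix over labeled regions."""

    values: np.ndarray
    region_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = tuple(str(r) for r in self.region_ids)
        n = len(self.region_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} region ids"
            )
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL, rtol=0):
            raise ValueError("FC matrix is not symmetric within 1e-10")
        if not np.allclose(np.diag(self.values), 1.0, atol=_SYM_TOL, rtol=0):
            raise ValueError("FC matrix diagonal must be 1")
        off = self.values[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


@dataclass
class Cohort:
    """A labeled, ordered collection of per-subject FC matrices for one condition."""

    condition: str
    subjects: tuple[str, ...]
    matrices: tuple[FCMatrix, ...]

    def __post_init__(self) -> None:
        self.subjects = tuple(str(s) for s in self.subjects)
        self.matrices = tuple(self.matrices)
        if len(self.subjects) != len(self.matrices):
            raise ValueError("one matrix per subject required")
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("subject IDs must be unique")
        if not self.matrices:
            raise ValueError("cohort must contain at least one subject")
        ref = self.matrices[0].region_ids
        for subj, m in zip(self.subjects, self.matrices):
            if m.region_ids != ref:
                raise ValueError(
                    f"subject {subj} has a different region ordering"
                )

    @property
    def region_ids(self) -> tuple[str, ...]:
        return self.matrices[0].region_ids

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def stacked(self) -> np.ndarray:
        """All matrices as one (n_subjects, n, n) array."""
        return np.stack([m.values for m in self.matrices])


@dataclass
class TimeSeriesSet:
    """Parcellated time series for one subject: regions x time points."""

    subject: str
    data: np.ndarray
    region_ids: tuple[str, ...]
    sampling_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.region_ids = tuple(str(r) for r in self.region_ids)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (regions x time)")
        if self.data.shape[0] != len(self.region_ids):
            raise ValueError("one row per region required")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 time points")
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")
        if np.isnan(self.data).any():
            raise ValueError("time series contain missing values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class NetworkPartition:
    """Assignment of every region to exactly one functional network."""

    assignment: dict[str, str]
    networks: tuple[str, ...] = DEFAULT_NETWORKS

    def __post_init__(self) -> None:
        self.assignment = {str(k): str(v) for k, v in self.assignment.items()}
        self.networks = tuple(str(n) for n in self.networks)
        used = set(self.assignment.values())
        unknown = used - set(self.networks)
        if unknown:
            raise ValueError(f"assignment uses unlisted networks: {sorted(unknown)}")
        empty = [n for n in self.networks if n not in used]
        if empty:
            raise ValueError(f"networks with no regions: {empty}")

    def labels_for(self, region_ids: Sequence[str]) -> np.ndarray:
        """Network label per region, erroring on unassigned regions."""
        missing = [r for r in region_ids if r not in self.assignment]
        if missing:
            raise ValueError(
                f"regions not covered by partition: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        return np.asarray([self.assignment[r] for r in region_ids])

    def members(self, network: str, region_ids: Sequence[str]) -> list[str]:
        return [r for r in region_ids if self.assignment.get(r) == network]


# ---------------------------------------------------------------------------
# construction operations


def bandpass_filter(
    ts: TimeSeriesSet, low_hz: float, high_hz: float
) -> TimeSeriesSet:
    """Zero-phase first-order Butterworth band-pass of every region's series.

    The filter is applied forward and reverse (``filtfilt``), doubling the
    effective order and cancelling phase distortion.  The band must lie
    strictly inside (0, Nyquist).
    """
    nyquist = 0.5 / ts.sampling_interval
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz must satisfy "
            f"0 < low < high < Nyquist ({nyquist:g} Hz)"
        )
    b, a = signal.butter(
        1, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.sampling_interval
    )
    filtered = signal.filtfilt(b, a, ts.data, axis=1)
    return TimeSeriesSet(
        subject=ts.subject,
        data=filtered,
        region_ids=ts.region_ids,
        sampling_interval=ts.sampling_interval,
    )


def fc_from_timeseries(ts: TimeSeriesSet) -> FCMatrix:
    """Pearson-correlation FC matrix from parcellated time series.

    The diagonal is forced to exactly 1 and off-diagonal values clipped into
    [-1, 1] to absorb floating-point overshoot.
    """
    sd = ts.data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.region_ids[i] for i in dead[:5]]
        raise ValueError(
            f"zero-variance region series: {names}"
            + ("..." if dead.size > 5 else "")
        )
    r = np.corrcoef(ts.data)
    r = np.clip(r, -1.0, 1.0)
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(values=r, region_ids=ts.region_ids)


def average_runs(fc_a: FCMatrix, fc_b: FCMatrix) -> FCMatrix:
    """Entry-wise mean of two runs' FC matrices (e.g., LR and RL phase encodings)."""
    if fc_a.region_ids != fc_b.region_ids:
        raise ValueError("runs have different region orderings")
    mean = 0.5 * (fc_a.values + fc_b.values)
    np.fill_diagonal(mean, 1.0)
    return FCMatrix(values=mean, region_ids=fc_a.region_ids)


def partition_order(
    region_ids: Sequence[str], part: NetworkPartition
) -> np.ndarray:
    """Stable permutation grouping regions by network, networks in partition order."""
    labels = part.labels_for(region_ids)
    rank = {n: i for i, n in enumerate(part.networks)}
    keys = np.asarray([rank[l] for l in labels])
    return np.argsort(keys, kind="stable")


def reorder_by_partition(fc: FCMatrix, part: NetworkPartition) -> FCMatrix:
    """Permute rows/columns so each network's regions are contiguous."""
    perm = partition_order(fc.region_ids, part)
    values = fc.values[np.ix_(perm, perm)]
    ids = tuple(fc.region_ids[i] for i in perm)
    return FCMatrix(values=values, region_ids=ids)


# ---------------------------------------------------------------------------
# text I/O


def write_matrix(path: str | os.PathLike, values: np.ndarray,
                 region_ids: Sequence[str]) -> None:
    df = pd.DataFrame(np.asarray(values), columns=list(region_ids))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_matrix(path: str | os.PathLike) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", header=0, dtype=float,
                     float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(
            f"{path}: expected a square matrix, got {values.shape}"
        )
    return values, tuple(str(c) for c in df.columns)


def write_fc(path: str | os.PathLike, fc: FCMatrix) -> None:
    write_matrix(path, fc.values, fc.region_ids)


def read_fc(path: str | os.PathLike) -> FCMatrix:
    values, ids = read_matrix(path)
    return FCMatrix(values=values, region_ids=ids)


def write_cohort(directory: str | os.PathLike, cohort: Cohort) -> Path:
    """Write one FC file per subject plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj, fc in zip(cohort.subjects, cohort.matrices):
        rel = f"{cohort.condition}_{subj}.tsv"
        write_fc(directory / rel, fc)
        rows.append({"subject_id": subj, "condition": cohort.condition,
                     "relative_path": rel})
    manifest = directory / f"manifest_{cohort.condition}.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort(manifest_path: str | os.PathLike,
                condition: str | None = None) -> Cohort:
    """Load a cohort from a manifest table (subject_id, condition, relative_path)."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t", dtype=str)
    required = {"subject_id", "condition", "relative_path"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"{manifest_path}: manifest must have columns {sorted(required)}"
        )
    if condition is not None:
        table = table[table["condition"] == condition]
        if table.empty:
            raise ValueError(
                f"{manifest_path}: no subjects with condition {condition!r}"
            )
    conditions = table["condition"].unique()
    if len(conditions) != 1:
        raise ValueError(
            f"{manifest_path}: manifest mixes conditions {list(conditions)}; "
            "pass condition= to select one"
        )
    base = manifest_path.parent
    subjects, matrices = [], []
    for _, row in table.iterrows():
        subjects.append(row["subject_id"])
        matrices.append(read_fc(base / row["relative_path"]))
    return Cohort(condition=str(conditions[0]), subjects=tuple(subjects),
                  matrices=tuple(matrices))


def write_partition(path: str | os.PathLike, part: NetworkPartition) -> None:
    rows = [{"region_id": r, "network_label": n}
            for r, n in part.assignment.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_partition(path: str | os.PathLike,
                   networks: Sequence[str] | None = None) -> NetworkPartition:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"region_id", "network_label"}.issubset(table.columns):
        raise ValueError(
            f"{path}: partition needs columns region_id, network_label"
        )
    assignment = dict(zip(table["region_id"], table["network_label"]))
    if networks is None:
        # preserve first-appearance order of labels
        networks = tuple(dict.fromkeys(table["network_label"]))
    return NetworkPartition(assignment=assignment, networks=tuple(networks))


def write_timeseries(path: str | os.PathLike, ts: TimeSeriesSet) -> None:
    df = pd.DataFrame(ts.data)
    df.insert(0, "region_id", list(ts.region_ids))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_timeseries(path: str | os.PathLike, subject: str,
                    sampling_interval: float) -> TimeSeriesSet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "region_id" not in df.columns:
        raise ValueError(f"{path}: first column must be region_id")
    ids = tuple(str(r) for r in df["region_id"])
    data = df.drop(columns="region_id").to_numpy(dtype=float)
    return TimeSeriesSet(subject=subject, data=data, region_ids=ids,
                         sampling_interval=sampling_interval)
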