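"""Synthetic rest/task cohorts with planted effects, and a coupled synthetic SC.

Generates two cohorts of region-by-time series (and their FC matrices) from
zero-mean multivariate normal draws whose target correlation matrix has a
modular block structure over the functional networks, with a configurable set
of "planted" edges whose coupling is shifted in the task condition.  This
gives every pipeline stage a known ground truth: the planted edges are the
ones an edgewise distance analysis should recover.  A paired mode reuses the
same subjects in both conditions with a shared subject-level deflection of
the target matrix, so that paired differences cancel the subject effect.

The companion structural matrix mimics a log10-transformed streamline-count
connectome: symmetric, nonnegative, denser and stronger within blocks,
values spanning [0, 5], connected on its positive weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (
    Cohort,
    DEFAULT_NETWORKS,
    FCMatrix,
    NetworkPartition,
    TimeSeriesSet,
    fc_from_timeseries,
)
from .structure import SCMatrix

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "default_partition",
    "generate_cohorts",
    "generate_dataset",
    "generate_sc",
    "nearest_correlation",
]


def default_partition(
    n_regions: int, networks: Sequence[str] = DEFAULT_NETWORKS
) -> NetworkPartition:
    """Contiguous, near-equal blocks of regions labeled r000, r001, ..."""
    K = len(networks)
    if n_regions < K:
        raise ValueError(f"need at least {K} regions for {K} networks")
    sizes = np.full(K, n_regions // K)
    sizes[: n_regions % K] += 1
    assignment: dict[str, str] = {}
    r = 0
    for net, size in zip(networks, sizes):
        for _ in range(size):
            assignment[f"r{r:03d}"] = net
            r += 1
    return NetworkPartition(assignment=assignment, networks=tuple(networks))


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults mirror the cohort structure the framework targets: a 374-region
    atlas (360 cortical + 14 subcortical) partitioned into 8 functional
    networks, 50 rest and 50 task subjects, and run lengths of 1,200 frames at
    0.72 s sampling.
    """

    n_regions: int = 374
    n_subjects_rest: int = 50
    n_subjects_task: int = 50
    networks: tuple[str, ...] = DEFAULT_NETWORKS
    planted_edges: tuple[tuple[int, int, float], ...] = ()
    within_block_r: float = 0.3
    between_block_r: float = 0.05
    noise_sd: float = 0.0
    paired: bool = False
    subject_effect_sd: float = 0.1
    T: int = 1200
    sampling_interval: float = 0.72
    seed: int = 0
    task_condition: str = "TASK"

    def __post_init__(self) -> None:
        seen = set()
        for (i, j, dr) in self.planted_edges:
            if i == j:
                raise ValueError("planted edges must be off-diagonal")
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
                raise ValueError(f"planted edge ({i},{j}) out of range")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate planted edge {key}")
            seen.add(key)
        if self.paired and self.n_subjects_rest != self.n_subjects_task:
            raise ValueError("paired mode requires equal cohort sizes")


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces."""

    rest: Cohort
    task: Cohort
    rest_ts: list[TimeSeriesSet]
    task_ts: list[TimeSeriesSet]
    truth: pd.DataFrame
    partition: NetworkPartition
    spec: SyntheticSpec


def nearest_correlation(
    target: np.ndarray, min_eig: float = 1e-8
) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at ``min_eig`` and the result renormalized to a
    unit diagonal; a single pass suffices for the mild indefiniteness planted
    deltas can introduce.
    """
    sym = 0.5 * (target + target.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= min_eig:
        out = sym
    else:
        vals = np.clip(vals, min_eig, None)
        out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 1.0)
    if np.linalg.eigvalsh(out).min() < -1e-10:
        raise ValueError("could not repair target to a valid correlation matrix")
    return out


def _block_target(spec: SyntheticSpec, part: NetworkPartition,
                  region_ids: Sequence[str]) -> np.ndarray:
    labels = part.labels_for(region_ids)
    same = labels[:, None] == labels[None, :]
    C = np.where(same, spec.within_block_r, spec.between_block_r)
    np.fill_diagonal(C, 1.0)
    return C


def _sample_subject(
    rng: np.random.Generator, corr: np.ndarray, spec: SyntheticSpec,
) -> np.ndarray:
    n = corr.shape[0]
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(n))
    z = rng.standard_normal((n, spec.T))
    x = L @ z
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal((n, spec.T))
    return x


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Simulate the full study: time series, FCs, ground truth, partition.

    Each subject gets an independent random substream derived from the master
    seed, so the same spec always reproduces the same data bit for bit.  In
    paired mode the same substreams (and subjects) are used for both
    conditions, plus one shared deflection of the target correlations per
    subject.
    """
    part = default_partition(spec.n_regions, spec.networks)
    region_ids = tuple(sorted(part.assignment))
    base = _block_target(spec, part, region_ids)

    task_target = base.copy()
    for (i, j, dr) in spec.planted_edges:
        task_target[i, j] += dr
        task_target[j, i] += dr
    if np.any(np.abs(task_target[~np.eye(spec.n_regions, dtype=bool)]) >= 1):
        raise ValueError("planted deltas push a target correlation out of (-1, 1)")

    rest_target = nearest_correlation(base)
    task_target = nearest_correlation(task_target)

    master = np.random.SeedSequence(spec.seed)
    n_streams = spec.n_subjects_rest + spec.n_subjects_task
    if spec.paired:
        n_streams = spec.n_subjects_rest  # shared subjects, shared streams
    streams = master.spawn(n_streams)

    def _make(condition: str, target: np.ndarray, count: int,
              offset: int, prefix: str) -> tuple[list[TimeSeriesSet], Cohort]:
        ts_sets: list[TimeSeriesSet] = []
        mats: list[FCMatrix] = []
        subjects = []
        for s in range(count):
            stream = streams[offset + s]
            # three condition-agnostic substreams per subject; in paired mode
            # the subject stream is shared between conditions, so the effect
            # substream (and hence the deflection) is shared too
            rest_child, task_child, eff_child = np.random.SeedSequence(
                entropy=stream.entropy, spawn_key=stream.spawn_key
            ).spawn(3)
            rng = np.random.default_rng(
                rest_child if condition == "REST" else task_child
            )
            corr = target
            if spec.subject_effect_sd > 0:
                eff_rng = np.random.default_rng(eff_child)
                n = spec.n_regions
                noise = eff_rng.standard_normal((n, n))
                noise = spec.subject_effect_sd * 0.5 * (noise + noise.T)
                np.fill_diagonal(noise, 0.0)
                corr = nearest_correlation(np.clip(target + noise,
                                                   -0.999, 0.999))
            subj = f"{prefix}{s:03d}"
            data = _sample_subject(rng, corr, spec)
            ts = TimeSeriesSet(subject=subj, data=data,
                               region_ids=region_ids,
                               sampling_interval=spec.sampling_interval)
            ts_sets.append(ts)
            mats.append(fc_from_timeseries(ts))
            subjects.append(subj)
        cohort = Cohort(condition=condition, subjects=tuple(subjects),
                        matrices=tuple(mats))
        return ts_sets, cohort

    if spec.paired:
        rest_ts, rest = _make("REST", rest_target, spec.n_subjects_rest, 0, "sub")
        task_ts, task = _make(spec.task_condition, task_target,
                              spec.n_subjects_task, 0, "sub")
    else:
        rest_ts, rest = _make("REST", rest_target, spec.n_subjects_rest, 0,
                              "rest")
        task_ts, task = _make(spec.task_condition, task_target,
                              spec.n_subjects_task, spec.n_subjects_rest,
                              "task")

    truth = pd.DataFrame(
        [
            {
                "region_i": region_ids[min(i, j)],
                "region_j": region_ids[max(i, j)],
                "i": min(i, j),
                "j": max(i, j),
                "delta_r": dr,
            }
            for (i, j, dr) in spec.planted_edges
        ],
        columns=["region_i", "region_j", "i", "j", "delta_r"],
    )
    return SyntheticDataset(rest=rest, task=task, rest_ts=rest_ts,
                            task_ts=task_ts, truth=truth, partition=part,
                            spec=spec)


def generate_cohorts(
    spec: SyntheticSpec,
) -> tuple[Cohort, Cohort, pd.DataFrame]:
    """Rest cohort, task cohort, and the planted-edge ground-truth table."""
    ds = generate_dataset(spec)
    return ds.rest, ds.task, ds.truth


def generate_sc(spec: SyntheticSpec) -> SCMatrix:
    """Synthetic log10-weight structural connectome coupled to the partition.

    Within-block edges are always present with high weights; between-block
    edges are sparse with low weights.  A ring over all regions guarantees
    connectedness; weights are clamped into [0, 5].
    """
    part = default_partition(spec.n_regions, spec.networks)
    region_ids = tuple(sorted(part.assignment))
    labels = part.labels_for(region_ids)
    n = spec.n_regions
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0x5C)))
    same = labels[:, None] == labels[None, :]

    weights = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    within = same[iu]
    w = np.zeros(iu[0].shape)
    w[within] = np.clip(rng.normal(3.5, 0.8, within.sum()), 0.1, 5.0)
    n_between = (~within).sum()
    present = rng.random(n_between) < 0.3
    wb = np.clip(rng.normal(1.2, 0.6, n_between), 0.0, 5.0) * present
    w[~within] = wb
    weights[iu] = w
    weights = weights + weights.T
    # ring for guaranteed connectedness
    for i in range(n):
        j = (i + 1) % n
        if weights[i, j] == 0:
            weights[i, j] = weights[j, i] = np.clip(
                rng.normal(0.8, 0.2), 0.1, 5.0
            )
    np.fill_diagonal(weights, 0.0)
    return SCMatrix(values=weights, region_ids=region_ids)
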