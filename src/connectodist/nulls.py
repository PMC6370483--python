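"""Null models for the edgewise connectivity-distance analysis.

Two complementary nulls:

* AAFT surrogates — each region's time series is replaced by an
  amplitude-adjusted Fourier-transform surrogate that preserves its amplitude
  distribution exactly and its power spectrum approximately, destroying the
  inter-regional correlation structure.  Rebuilding FCs and the edgewise JS
  map from surrogates shows how many suprathreshold edges arise by chance.
* Label permutation — whole FC matrices (correlation structure intact) are
  reshuffled between the rest and task groups, and the JS map recomputed,
  testing whether the observed suprathreshold count could arise under
  exchangeable group labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import Cohort, FCMatrix, TimeSeriesSet, fc_from_timeseries
from .divergence import UNPAIRED_BINNING, BinningScheme
from .mapping import JSMatrix, edgewise_js_matrix, threshold_pooled

__all__ = [
    "NullDistribution",
    "aaft_surrogate",
    "surrogate_timeseries_set",
    "surrogate_null",
    "label_permutation_test",
    "suprathreshold_count",
    "empirical_p",
]


@dataclass
class NullDistribution:
    """Suprathreshold edge counts under a null model, one per realization."""

    condition: str
    counts: np.ndarray
    observed: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a nonempty 1-D array")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_realizations(self) -> int:
        return self.counts.size

    def p_value(self, observed: int | None = None) -> float:
        obs = self.observed if observed is None else observed
        if obs is None:
            raise ValueError("no observed count available")
        return empirical_p(obs, self.counts)


def empirical_p(observed: float, null_counts: np.ndarray) -> float:
    """(1 + #{null >= observed}) / (1 + n) — guaranteed in (0, 1]."""
    null_counts = np.asarray(null_counts)
    return float((1 + (null_counts >= observed).sum()) / (1 + null_counts.size))


def suprathreshold_count(js: JSMatrix, cutoff: float) -> int:
    """Undirected edges with JS distance strictly above the cutoff."""
    return int((js.upper_values() > cutoff).sum())


# ---------------------------------------------------------------------------
# AAFT surrogates


def aaft_surrogate(series, rng: np.random.Generator | int) -> np.ndarray:
    """Amplitude-adjusted Fourier-transform surrogate of a single time series.

    Classic three-step scheme: (1) rank-remap a Gaussian white-noise
    realization onto the ordering of the data, (2) randomize the Fourier
    phases of that Gaussianized series, (3) rank-remap the original amplitudes
    onto the phase-randomized result.  The sorted surrogate values equal the
    sorted input values exactly; the power spectrum is preserved
    approximately.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("series must be 1-D with at least 4 points")
    if np.ptp(x) == 0:
        raise ValueError("cannot build a surrogate of a constant series")
    rng = np.random.default_rng(rng)
    T = x.size

    order = np.argsort(x, kind="stable")
    ranks = np.empty(T, dtype=int)
    ranks[order] = np.arange(T)

    # (1) Gaussianize: white noise with the data's rank ordering
    g = np.sort(rng.standard_normal(T))
    y = g[ranks]

    # (2) phase randomization preserving |FFT|; DC and Nyquist stay real
    spectrum = np.fft.rfft(y)
    phases = rng.uniform(0, 2 * np.pi, spectrum.size)
    phases[0] = 0.0
    if T % 2 == 0:
        phases[-1] = 0.0
    y_rand = np.fft.irfft(np.abs(spectrum) * np.exp(1j * phases), n=T)

    # (3) restore the original amplitude distribution
    out = np.empty(T)
    out[np.argsort(y_rand, kind="stable")] = np.sort(x)
    return out


def surrogate_timeseries_set(
    ts: TimeSeriesSet, rng: np.random.Generator | int
) -> TimeSeriesSet:
    """Independent AAFT surrogate of every region's series (univariate scheme)."""
    rng = np.random.default_rng(rng)
    data = np.stack([aaft_surrogate(row, rng) for row in ts.data])
    return TimeSeriesSet(subject=ts.subject, data=data,
                         region_ids=ts.region_ids,
                         sampling_interval=ts.sampling_interval)


def _cohort_from_ts(
    ts_sets: Sequence[TimeSeriesSet], condition: str
) -> Cohort:
    # condition-prefixed IDs keep paired inputs from tripping the
    # shared-subject warning in the unpaired JS computation
    return Cohort(
        condition=condition,
        subjects=tuple(f"{condition}:{ts.subject}" for ts in ts_sets),
        matrices=tuple(fc_from_timeseries(ts) for ts in ts_sets),
    )


def surrogate_null(
    rest_ts: Sequence[TimeSeriesSet],
    task_ts: Sequence[TimeSeriesSet],
    cutoff: float,
    n_realizations: int = 100,
    seed: int = 0,
    binning: BinningScheme = UNPAIRED_BINNING,
    rethreshold: bool = False,
    percentile: float = 95.0,
    condition: str = "TASK",
) -> NullDistribution:
    """Null distribution of suprathreshold edge counts from AAFT surrogates.

    Per realization every region series of every subject is surrogated, FCs
    are rebuilt, the edgewise JS matrix recomputed, and the entries above the
    original-data ``cutoff`` counted.  With ``rethreshold=True`` each
    realization is instead thresholded at its own ``percentile``.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    master = np.random.SeedSequence(seed)
    counts = np.empty(n_realizations, dtype=int)
    for r, child in enumerate(master.spawn(n_realizations)):
        streams = child.spawn(len(rest_ts) + len(task_ts))
        sur_rest = [
            surrogate_timeseries_set(ts, np.random.default_rng(s))
            for ts, s in zip(rest_ts, streams[: len(rest_ts)])
        ]
        sur_task = [
            surrogate_timeseries_set(ts, np.random.default_rng(s))
            for ts, s in zip(task_ts, streams[len(rest_ts):])
        ]
        js = edgewise_js_matrix(
            _cohort_from_ts(sur_rest, "REST-surrogate"),
            _cohort_from_ts(sur_task, f"{condition}-surrogate"),
            binning,
        )
        if rethreshold:
            c = float(np.percentile(js.upper_values(), percentile))
            counts[r] = suprathreshold_count(js, c)
        else:
            counts[r] = suprathreshold_count(js, cutoff)
    return NullDistribution(condition=condition, counts=counts)


# ---------------------------------------------------------------------------
# label permutation


def label_permutation_test(
    rest: Cohort,
    task: Cohort,
    cutoff: float,
    n_permutations: int = 100,
    seed: int = 0,
    binning: BinningScheme = UNPAIRED_BINNING,
) -> NullDistribution:
    """Permute rest/task labels over whole FC matrices and recount survivors.

    Every permutation keeps each matrix's correlation structure intact and
    only reassigns matrices to groups of the original sizes; the JS matrix is
    recomputed and its entries above the original-data cutoff counted.  The
    observed count (identity labeling) is stored on the result.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if rest.region_ids != task.region_ids:
        raise ValueError("cohorts have different region orderings")
    pool = list(rest.matrices) + list(task.matrices)
    n_rest = rest.n_subjects
    if len(pool) < 2:
        raise ValueError("need at least 2 subjects in the combined pool")

    import warnings as _warnings

    def _js_count(rest_mats, task_mats) -> int:
        rc = Cohort("REST-perm",
                    tuple(f"r{i}" for i in range(len(rest_mats))), rest_mats)
        tc = Cohort(f"{task.condition}-perm",
                    tuple(f"t{i}" for i in range(len(task_mats))), task_mats)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # perm groups share no subjects
            js = edgewise_js_matrix(rc, tc, binning)
        return suprathreshold_count(js, cutoff)

    observed = _js_count(tuple(rest.matrices), tuple(task.matrices))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    counts = np.empty(n_permutations, dtype=int)
    for p in range(n_permutations):
        perm = rng.permutation(len(pool))
        rest_mats = tuple(pool[i] for i in perm[:n_rest])
        task_mats = tuple(pool[i] for i in perm[n_rest:])
        counts[p] = _js_count(rest_mats, task_mats)
    return NullDistribution(condition=task.condition, counts=counts,
                            observed=observed)
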