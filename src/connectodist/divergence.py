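"""Discrete probability distributions over uniform bins and Jensen-Shannon machinery.

Edgewise connectivity values (Pearson correlations, or paired differences of
correlations) are discretized into probability vectors on a fixed uniform
binning, and cohorts of connectomes are then compared edge by edge with the
Kullback-Leibler and Jensen-Shannon divergences.  All logarithms are base 2,
which bounds the Jensen-Shannon divergence in [0, 1]; its square root is a
true metric ("Jensen-Shannon distance").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinningScheme",
    "ProbabilityVector",
    "UNPAIRED_BINNING",
    "PAIRED_BINNING",
    "discretize",
    "kl_divergence",
    "js_divergence",
    "js_distance",
    "paired_js_distance",
]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class BinningScheme:
    """Uniform binning of a closed interval ``[lower, upper]``.

    Bins are half-open ``[lo, hi)`` except the last, which is closed, so both
    endpoints of the range are always representable.  ``(upper - lower)/width``
    must be an integer number of bins.
    """

    lower: float
    upper: float
    width: float

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError(
                f"upper ({self.upper}) must exceed lower ({self.lower})"
            )
        if not self.width > 0:
            raise ValueError(f"bin width must be positive, got {self.width}")
        n = (self.upper - self.lower) / self.width
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError(
                f"range [{self.lower}, {self.upper}] is not an integer "
                f"number of bins of width {self.width}"
            )

    @property
    def n_bins(self) -> int:
        return int(round((self.upper - self.lower) / self.width))

    @property
    def edges(self) -> np.ndarray:
        # lo + span*(i/n) rather than lo + i*width: exact midpoint edge (0.0)
        # for the symmetric ranges used throughout, so the bin containing 0
        # starts exactly at 0.
        n = self.n_bins
        edges = self.lower + (self.upper - self.lower) * (np.arange(n + 1) / n)
        edges[0] = self.lower
        edges[-1] = self.upper
        return edges

    def bin_index(self, value: float) -> int:
        """Index of the bin containing ``value`` (last bin closed)."""
        idx = assign_bins(np.asarray([value]), self)
        return int(idx[0])


#: Binning for raw Pearson correlations: [-1, 1] in steps of 0.2.
UNPAIRED_BINNING = BinningScheme(-1.0, 1.0, 0.2)

#: Binning for paired (same-subject) correlation differences: [-2, 2] in 0.1.
PAIRED_BINNING = BinningScheme(-2.0, 2.0, 0.1)


@dataclass(frozen=True)
class ProbabilityVector:
    """A discrete distribution over the ordered bins of a :class:`BinningScheme`."""

    masses: np.ndarray
    binning: BinningScheme

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "masses", masses)
        if masses.ndim != 1 or masses.shape[0] != self.binning.n_bins:
            raise ValueError(
                f"expected {self.binning.n_bins} masses, got shape {masses.shape}"
            )
        if np.any(masses < 0):
            raise ValueError("probability masses must be nonnegative")
        if abs(masses.sum() - 1.0) > _PROB_TOL:
            raise ValueError(
                f"masses sum to {masses.sum()!r}, expected 1 within {_PROB_TOL}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbabilityVector):
            return NotImplemented
        return self.binning == other.binning and np.array_equal(
            self.masses, other.masses
        )


def assign_bins(values: np.ndarray, binning: BinningScheme) -> np.ndarray:
    """Vectorized bin assignment; values must lie in ``[lower, upper]``."""
    values = np.asarray(values, dtype=float)
    below = values < binning.lower
    above = values > binning.upper
    if below.any() or above.any():
        bad = values[below | above].flat[0]
        raise ValueError(
            f"value {bad!r} outside binning range "
            f"[{binning.lower}, {binning.upper}]"
        )
    idx = np.searchsorted(binning.edges, values, side="right") - 1
    # the closed right edge of the final bin
    return np.minimum(idx, binning.n_bins - 1)


def discretize(values, binning: BinningScheme) -> ProbabilityVector:
    """Empirical distribution of ``values`` over the bins of ``binning``.

    The mass of each bin is the fraction of values falling in it; bins are
    half-open ``[lo, hi)`` except the last, which also contains ``upper``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty set of values")
    idx = assign_bins(values.ravel(), binning)
    counts = np.bincount(idx, minlength=binning.n_bins)
    return ProbabilityVector(counts / values.size, binning)


def _check_shared_binning(P: ProbabilityVector, Q: ProbabilityVector) -> None:
    if P.binning != Q.binning:
        raise ValueError(
            f"distributions use different binnings: {P.binning} vs {Q.binning}"
        )


def kl_divergence(P: ProbabilityVector, Q: ProbabilityVector) -> float:
    """Kullback-Leibler divergence D_KL(P || Q) in bits.

    Zero-mass bins of P contribute nothing (0*log 0 = 0 convention); a bin
    with P(i) > 0 and Q(i) = 0 yields +inf, which never occurs against the
    mixtures used inside the Jensen-Shannon divergence.
    """
    _check_shared_binning(P, Q)
    p, q = P.masses, Q.masses
    support = p > 0
    if np.any(support & (q == 0)):
        return float("inf")
    ps, qs = p[support], q[support]
    return float(np.sum(ps * np.log2(ps / qs)))


def js_divergence(P: ProbabilityVector, Q: ProbabilityVector) -> float:
    """Jensen-Shannon divergence in bits: 1/2 KL(P||M) + 1/2 KL(Q||M), M = (P+Q)/2.

    Symmetric, always finite, and in [0, 1] with base-2 logarithms.
    """
    _check_shared_binning(P, Q)
    return float(_jsd_arrays(P.masses[None, :], Q.masses[None, :])[0])


def js_distance(P: ProbabilityVector, Q: ProbabilityVector) -> float:
    """Square root of the Jensen-Shannon divergence — a metric in [0, 1]."""
    return float(np.sqrt(js_divergence(P, Q)))


def _jsd_arrays(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Rowwise Jensen-Shannon divergence of stacked distributions (base 2)."""
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_p = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / m), 0.0)
        term_q = np.where(q > 0, q * np.log2(np.where(q > 0, q, 1.0) / m), 0.0)
    jsd = 0.5 * term_p.sum(axis=-1) + 0.5 * term_q.sum(axis=-1)
    return np.clip(jsd, 0.0, 1.0)


def paired_null(binning: BinningScheme = PAIRED_BINNING) -> ProbabilityVector:
    """Point-mass distribution at the bin containing 0 — the no-change null."""
    masses = np.zeros(binning.n_bins)
    masses[binning.bin_index(0.0)] = 1.0
    return ProbabilityVector(masses, binning)


def paired_js_distance(
    rest_values,
    task_values,
    binning: BinningScheme = PAIRED_BINNING,
) -> float:
    """Paired Jensen-Shannon distance for repeated measurements on the same subjects.

    The element-wise differences ``task - rest`` (subjects index-aligned) are
    discretized on ``binning`` and compared against a null distribution with
    probability 1 at the bin containing 0, which encodes the expectation of no
    change between repeated measurements.
    """
    rest = np.asarray(rest_values, dtype=float)
    task = np.asarray(task_values, dtype=float)
    if rest.shape != task.shape:
        raise ValueError(
            f"paired vectors must have equal length, got {rest.shape} and {task.shape}"
        )
    P = discretize(task - rest, binning)
    return js_distance(P, paired_null(binning))
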