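"""Edgewise Jensen-Shannon distance maps and network-level processing statistics.

For every edge (pair of regions), the across-subject distribution of its
correlation values in a task cohort is compared against the same edge's
distribution at rest, yielding a symmetric matrix of Jensen-Shannon distances
(the "connectivity distance" of each functional link from the resting
baseline).  Thresholding the pooled distance distribution at a high percentile
selects the most reconfigured edges; counting the survivors within and between
functional networks gives the centralized-processing (CP) and
distributed-processing (DP) statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .data import Cohort, NetworkPartition
from .divergence import (
    PAIRED_BINNING,
    UNPAIRED_BINNING,
    BinningScheme,
    _jsd_arrays,
    assign_bins,
    paired_null,
)

__all__ = [
    "JSMatrix",
    "ThresholdMask",
    "CPDPTable",
    "edgewise_js_matrix",
    "edgewise_paired_js_matrix",
    "threshold_pooled",
    "centralized_processing",
    "distributed_processing",
    "cpdp_table",
    "cross_task_summary",
    "nodal_js_strength",
    "js_baseline_correlation",
    "cpdp_cosine_similarity",
]


@dataclass
class JSMatrix:
    """Symmetric matrix of edgewise Jensen-Shannon distances in [0, 1]."""

    values: np.ndarray
    condition: str
    mode: Literal["unpaired", "paired"]
    binning: BinningScheme
    region_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("JS matrix must be square")
        if not self.region_ids:
            self.region_ids = tuple(str(i) for i in range(n))
        if len(self.region_ids) != n:
            raise ValueError("region_ids length mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("JS matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("JS matrix diagonal must be 0")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("JS distances must lie in [0, 1]")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def upper_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]


@dataclass
class ThresholdMask:
    """Binary map of the edges whose JS distance strictly exceeds a cutoff."""

    mask: np.ndarray
    cutoff: float
    percentile: float = 95.0
    condition: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.mask.shape[0]
        if self.mask.shape != (n, n):
            raise ValueError("mask must be square")
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("mask must be symmetric")
        if np.any(np.diag(self.mask)):
            raise ValueError("mask diagonal must be 0")

    @property
    def n_survivors(self) -> int:
        """Number of surviving undirected edges (each counted once)."""
        return int(self.mask.sum()) // 2


@dataclass
class CPDPTable:
    """CP per network and DP per unordered network pair, as fractions in [0, 1]."""

    cp: dict[str, float]
    dp: dict[tuple[str, str], float]
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"condition": self.condition, "network_or_pair": k,
             "statistic": "CP", "value": v}
            for k, v in self.cp.items()
        ]
        rows += [
            {"condition": self.condition, "network_or_pair": f"{k}-{l}",
             "statistic": "DP", "value": v}
            for (k, l), v in self.dp.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# edgewise JS matrices


def _edge_distributions(stack: np.ndarray, binning: BinningScheme) -> np.ndarray:
    """Per-edge empirical distributions from an (S, n, n) stack of FC values.

    Returns an (E, B) array over the E = n(n-1)/2 upper-triangular edges.
    """
    S, n, _ = stack.shape
    iu = np.triu_indices(n, k=1)
    edge_vals = stack[:, iu[0], iu[1]]            # (S, E)
    idx = assign_bins(edge_vals.ravel(), binning).reshape(S, -1)
    E = idx.shape[1]
    B = binning.n_bins
    flat = idx + np.arange(E)[None, :] * B
    counts = np.bincount(flat.ravel(), minlength=E * B).reshape(E, B)
    return counts / S


def _to_symmetric(edge_values: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = edge_values
    return out + out.T


def edgewise_js_matrix(
    rest: Cohort,
    task: Cohort,
    binning: BinningScheme = UNPAIRED_BINNING,
) -> JSMatrix:
    """Unpaired edgewise JS-distance matrix between a task cohort and rest.

    For every edge the across-subject correlation values of each cohort are
    discretized on ``binning`` and the JS distance between the two empirical
    distributions is computed.  Cohorts are expected to hold different
    subjects; a warning is emitted if they overlap.
    """
    if rest.region_ids != task.region_ids:
        raise ValueError("cohorts have different region orderings")
    if set(rest.subjects) & set(task.subjects):
        warnings.warn(
            "rest and task cohorts share subjects; the unpaired JS distance "
            "assumes disjoint cohorts (use edgewise_paired_js_matrix for "
            "repeated measurements)",
            stacklevel=2,
        )
    P = _edge_distributions(rest.stacked(), binning)
    Q = _edge_distributions(task.stacked(), binning)
    js = np.sqrt(_jsd_arrays(P, Q))
    return JSMatrix(
        values=_to_symmetric(js, len(rest.region_ids)),
        condition=task.condition,
        mode="unpaired",
        binning=binning,
        region_ids=rest.region_ids,
    )


def edgewise_paired_js_matrix(
    rest: Cohort,
    task: Cohort,
    binning: BinningScheme = PAIRED_BINNING,
) -> JSMatrix:
    """Paired edgewise JS-distance matrix from same-subject rest/task cohorts.

    Per edge, the element-wise differences task - rest across the shared,
    identically ordered subjects are discretized and compared against a
    point-mass null at the zero bin.
    """
    if rest.region_ids != task.region_ids:
        raise ValueError("cohorts have different region orderings")
    if rest.subjects != task.subjects:
        raise ValueError(
            "paired mode requires identical subject lists in identical order"
        )
    diff = task.stacked() - rest.stacked()
    P = _edge_distributions(diff, binning)
    q = paired_null(binning).masses[None, :]
    js = np.sqrt(_jsd_arrays(P, np.broadcast_to(q, P.shape)))
    return JSMatrix(
        values=_to_symmetric(js, len(rest.region_ids)),
        condition=task.condition,
        mode="paired",
        binning=binning,
        region_ids=rest.region_ids,
    )


# ---------------------------------------------------------------------------
# thresholding and CP/DP


def threshold_pooled(
    js_matrices: Sequence[JSMatrix],
    percentile: float = 95.0,
) -> tuple[float, list[ThresholdMask]]:
    """Pool upper-triangular JS values across all tasks and threshold each map.

    The cutoff is the linear-interpolation percentile of the pooled values;
    each mask keeps the edges whose JS distance is strictly greater than the
    cutoff (so an all-ties input yields no survivors).
    """
    if not js_matrices:
        raise ValueError("need at least one JS matrix")
    if not 0 <= percentile <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    n = js_matrices[0].n_regions
    for m in js_matrices:
        if m.n_regions != n:
            raise ValueError("JS matrices have different dimensions")
    pooled = np.concatenate([m.upper_values() for m in js_matrices])
    cutoff = float(np.percentile(pooled, percentile))
    masks = [
        ThresholdMask(mask=m.values > cutoff, cutoff=cutoff,
                      percentile=percentile, condition=m.condition)
        for m in js_matrices
    ]
    return cutoff, masks


def _network_blocks(
    part: NetworkPartition, region_ids: Sequence[str]
) -> dict[str, np.ndarray]:
    labels = part.labels_for(region_ids)
    return {k: np.flatnonzero(labels == k) for k in part.networks}


def centralized_processing(
    mask: ThresholdMask, part: NetworkPartition,
    region_ids: Sequence[str] | None = None,
) -> dict[str, float]:
    """CP per network: surviving within-network edges / total within-network edges."""
    n = mask.mask.shape[0]
    ids = tuple(region_ids) if region_ids else tuple(str(i) for i in range(n))
    blocks = _network_blocks(part, ids)
    cp: dict[str, float] = {}
    for k, idx in blocks.items():
        total = len(idx) * (len(idx) - 1) // 2
        if total == 0:
            warnings.warn(f"network {k} has fewer than 2 regions; CP undefined",
                          stacklevel=2)
            cp[k] = float("nan")
            continue
        sub = mask.mask[np.ix_(idx, idx)]
        cp[k] = int(np.triu(sub, k=1).sum()) / total
    return cp


def distributed_processing(
    mask: ThresholdMask, part: NetworkPartition,
    region_ids: Sequence[str] | None = None,
) -> dict[tuple[str, str], float]:
    """DP per network pair: surviving between-network edges / |k|*|l|."""
    n = mask.mask.shape[0]
    ids = tuple(region_ids) if region_ids else tuple(str(i) for i in range(n))
    blocks = _network_blocks(part, ids)
    nets = part.networks
    dp: dict[tuple[str, str], float] = {}
    for a in range(len(nets)):
        for b in range(a + 1, len(nets)):
            k, l = nets[a], nets[b]
            ik, il = blocks[k], blocks[l]
            sub = mask.mask[np.ix_(ik, il)]
            dp[(k, l)] = int(sub.sum()) / (len(ik) * len(il))
    return dp


def cpdp_table(
    mask: ThresholdMask, part: NetworkPartition,
    region_ids: Sequence[str] | None = None,
    condition: str | None = None,
) -> CPDPTable:
    return CPDPTable(
        cp=centralized_processing(mask, part, region_ids),
        dp=distributed_processing(mask, part, region_ids),
        condition=condition if condition is not None else mask.condition,
    )


def network_dp_aggregate(
    table: CPDPTable,
    mask: ThresholdMask | None = None,
    part: NetworkPartition | None = None,
    region_ids: Sequence[str] | None = None,
    how: Literal["pooled", "mean"] = "pooled",
) -> dict[str, float]:
    """Single DP value per network, aggregating its pairwise DP entries.

    ``mean`` averages the K-1 pairwise fractions; ``pooled`` recounts
    survivors over all between-k edges at once (the default), which weights
    pairs by their edge counts and requires the mask and partition.
    """
    nets = {k for pair in table.dp for k in pair}
    if how == "mean":
        return {
            k: float(np.mean([v for pair, v in table.dp.items() if k in pair]))
            for k in sorted(nets)
        }
    if mask is None or part is None:
        raise ValueError("pooled aggregation needs the mask and partition")
    n = mask.mask.shape[0]
    ids = tuple(region_ids) if region_ids else tuple(str(i) for i in range(n))
    blocks = _network_blocks(part, ids)
    out: dict[str, float] = {}
    for k in part.networks:
        ik = blocks[k]
        others = np.concatenate([blocks[l] for l in part.networks if l != k])
        sub = mask.mask[np.ix_(ik, others)]
        out[k] = int(sub.sum()) / (len(ik) * len(others))
    return out


# ---------------------------------------------------------------------------
# summaries and diagnostics


def cross_task_summary(
    js_matrices: Sequence[JSMatrix],
    statistic: Literal["max", "median"],
    percentile: float = 95.0,
) -> tuple[JSMatrix, ThresholdMask]:
    """Entry-wise max or median JS map across tasks, with its own threshold.

    The mask cutoff is the requested percentile of the summary map's own
    upper-triangular values (strictly-greater rule).
    """
    if not js_matrices:
        raise ValueError("need at least one JS matrix")
    stack = np.stack([m.values for m in js_matrices])
    if statistic == "max":
        summary = stack.max(axis=0)
    elif statistic == "median":
        summary = np.median(stack, axis=0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    ref = js_matrices[0]
    js = JSMatrix(values=summary, condition=f"{statistic}-across-tasks",
                  mode=ref.mode, binning=ref.binning, region_ids=ref.region_ids)
    cutoff = float(np.percentile(js.upper_values(), percentile))
    mask = ThresholdMask(mask=summary > cutoff, cutoff=cutoff,
                         percentile=percentile, condition=js.condition)
    return js, mask


def nodal_js_strength(js: JSMatrix, mask: ThresholdMask) -> np.ndarray:
    """Per-region sum of suprathreshold JS distances, divided by n regions."""
    if js.values.shape != mask.mask.shape:
        raise ValueError("JS matrix and mask shapes differ")
    n = js.n_regions
    return (js.values * mask.mask).sum(axis=1) / n


def js_baseline_correlation(js: JSMatrix, rest: Cohort) -> float:
    """Pearson r between edgewise JS values and the median rest-FC per edge.

    Quantifies whether the connectivity distance simply tracks the magnitude
    of the baseline correlations (near 0 when it does not).
    """
    if js.region_ids != rest.region_ids:
        raise ValueError("JS matrix and cohort have different regions")
    iu = np.triu_indices(js.n_regions, k=1)
    x = js.values[iu]
    y = np.median(rest.stacked(), axis=0)[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def cpdp_cosine_similarity(a: CPDPTable, b: CPDPTable) -> dict[str, float]:
    """Per-network cosine similarity between two CP/DP coordinate vectors.

    Each network's coordinates are its CP value followed by all its pairwise
    DP values (in a canonical order); the cosine measures whether two
    processing configurations (e.g., under two band-pass choices) point the
    same way in that state space, regardless of overall magnitude.
    """
    if set(a.cp) != set(b.cp) or set(a.dp) != set(b.dp):
        raise ValueError("tables cover different networks")
    out: dict[str, float] = {}
    for k in a.cp:
        pairs = sorted(p for p in a.dp if k in p)
        va = np.array([a.cp[k]] + [a.dp[p] for p in pairs])
        vb = np.array([b.cp[k]] + [b.dp[p] for p in pairs])
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            raise ValueError(f"zero CP/DP vector for network {k}")
        out[k] = float(va @ vb / (na * nb))
    return out
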