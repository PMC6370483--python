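"""Structural connectomes, search information, and structure-function association.

Associates the most JS-distant functional edges with properties of the
underlying structural connectome: the (log10-transformed) connection weights
themselves, and the search information of the shortest structural path — the
number of bits a random walker needs to follow that path, a measure of how
"hidden" or nested the route between two regions is.  Edges are grouped into
five percentile intervals of weight (or search information) and the fraction
of suprathreshold within-/between-network edges per interval is compared
across intervals with a one-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .data import NetworkPartition
from .mapping import ThresholdMask, _network_blocks

__all__ = [
    "SCMatrix",
    "SIMatrix",
    "BinAssignment",
    "group_average_sc",
    "search_information",
    "percentile_bin_assignment",
    "cpdp_by_bin",
    "one_way_anova",
]

PERCENTILE_INTERVALS = ((0, 20), (20, 40), (40, 60), (60, 80), (80, 100))


@dataclass
class SCMatrix:
    """Symmetric nonnegative structural connectome (log10-transformed weights)."""

    values: np.ndarray
    region_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = tuple(str(r) for r in self.region_ids)
        n = len(self.region_ids)
        if self.values.shape != (n, n):
            raise ValueError("SC matrix shape does not match region ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("SC matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("SC diagonal must be 0")
        if self.values.min() < 0:
            raise ValueError("SC weights must be nonnegative")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


@dataclass
class SIMatrix:
    """Search-information map in bits; directed unless symmetrized."""

    values: np.ndarray
    region_ids: tuple[str, ...]
    symmetrized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.region_ids)
        if self.values.shape != (n, n):
            raise ValueError("SI matrix shape does not match region ids")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < -1e-9:
            raise ValueError("search information must be nonnegative")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("SI diagonal must be 0")

    def symmetrize(self) -> "SIMatrix":
        """Mean of SI(i->j) and SI(j->i)."""
        return SIMatrix(values=0.5 * (self.values + self.values.T),
                        region_ids=self.region_ids, symmetrized=True)


@dataclass
class BinAssignment:
    """Edge-to-percentile-interval assignment on a matrix's positive entries.

    ``bins`` holds, per (i, j), the 0-based interval index (0 = lowest 20%),
    or -1 for excluded entries (diagonal and zero-weight edges).
    """

    bins: np.ndarray
    intervals: tuple[tuple[int, int], ...] = PERCENTILE_INTERVALS

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=int)

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------


def group_average_sc(scs: Sequence[SCMatrix]) -> SCMatrix:
    """Entry-wise arithmetic mean of individual (log10-weight) SC matrices."""
    if not scs:
        raise ValueError("need at least one SC matrix")
    ids = scs[0].region_ids
    for sc in scs:
        if sc.region_ids != ids:
            raise ValueError("SC matrices have different region orderings")
    mean = np.mean([sc.values for sc in scs], axis=0)
    return SCMatrix(values=mean, region_ids=ids)


def _shortest_path(predecessors: np.ndarray, source: int, target: int) -> list[int]:
    path = [target]
    while path[-1] != source:
        prev = predecessors[path[-1]]
        if prev < 0:
            return []
        path.append(prev)
    path.reverse()
    return path


def search_information(
    sc: SCMatrix,
    lengths: Literal["inverse", "neglog"] = "inverse",
    memory: bool = False,
    symmetrize: bool = False,
) -> SIMatrix:
    """Bits of information needed to follow each shortest structural path.

    Shortest paths are computed on edge lengths derived from the weights
    (``inverse``: 1/w, the default; ``neglog``: -log10(w/max)).  The walker's
    probability of taking the path i -> j is the product over consecutive
    steps (u, v) of w_uv / s_u with s_u the strength of u; search information
    is -log2 of that product.  With ``memory=True`` the incoming edge's weight
    is excluded from s_u at every step after the first (a walker that never
    steps back).  Unreachable pairs get +inf with a warning.
    """
    W = sc.values
    n = sc.n_regions
    if n < 2:
        raise ValueError("need at least 2 regions")
    pos = W > 0
    with np.errstate(divide="ignore"):
        if lengths == "inverse":
            L = np.where(pos, 1.0 / np.where(pos, W, 1.0), 0.0)
        elif lengths == "neglog":
            wmax = W.max()
            if wmax <= 0:
                raise ValueError("SC has no positive weights")
            # small offset keeps the maximum-weight edge traversable
            L = np.where(pos, -np.log10(np.where(pos, W, 1.0) / (wmax * 1.0001)),
                         0.0)
        else:
            raise ValueError(f"unknown length transform {lengths!r}")
    graph = csr_matrix(L)
    n_comp, _ = connected_components(csr_matrix(pos.astype(float)),
                                     directed=False)
    if n_comp > 1:
        warnings.warn(
            "structural graph is disconnected; unreachable pairs reported "
            "as +inf", stacklevel=2,
        )
    _, predecessors = dijkstra(graph, directed=False,
                               return_predecessors=True)
    strength = W.sum(axis=1)
    log2w = np.where(pos, np.log2(np.where(pos, W, 1.0)), -np.inf)
    si = np.full((n, n), np.inf)
    np.fill_diagonal(si, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            path = _shortest_path(predecessors[i], i, j)
            if not path:
                continue
            bits = 0.0
            for step, (u, v) in enumerate(zip(path[:-1], path[1:])):
                s_u = strength[u]
                if memory and step > 0:
                    s_u = s_u - W[path[step - 1], u]
                bits -= log2w[u, v] - np.log2(s_u)
            si[i, j] = max(bits, 0.0)
    out = SIMatrix(values=si, region_ids=sc.region_ids)
    return out.symmetrize() if symmetrize else out


def percentile_bin_assignment(
    matrix: SCMatrix | SIMatrix,
    intervals: tuple[tuple[int, int], ...] = PERCENTILE_INTERVALS,
) -> BinAssignment:
    """Assign each positive (finite) edge to a percentile interval of its value.

    Percentile ranks are computed on the positive upper-triangular entries
    with maximum ranks for ties (so tied values share an interval); interval
    b holds ranks in (20(b-1), 20b].  Zero-weight and non-finite edges are
    excluded (-1).
    """
    values = matrix.values
    n = values.shape[0]
    iu = np.triu_indices(n, k=1)
    edge_vals = values[iu]
    ok = np.isfinite(edge_vals) & (edge_vals > 0)
    if ok.sum() < len(intervals):
        raise ValueError(
            f"need at least {len(intervals)} positive entries, got {ok.sum()}"
        )
    prank = np.full(edge_vals.shape, np.nan)
    ranks = stats.rankdata(edge_vals[ok], method="max")
    prank[ok] = 100.0 * ranks / ok.sum()
    k = len(intervals)
    step = 100.0 / k
    bin_of_edge = np.where(
        ok, np.minimum(np.ceil(np.where(ok, prank, 1.0) / step) - 1, k - 1), -1
    ).astype(int)
    bins = np.full((n, n), -1, dtype=int)
    bins[iu] = bin_of_edge
    bins[(iu[1], iu[0])] = bin_of_edge
    return BinAssignment(bins=bins, intervals=intervals)


def cpdp_by_bin(
    masks: Sequence[ThresholdMask],
    part: NetworkPartition,
    bins: BinAssignment,
    region_ids: Sequence[str] | None = None,
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Percentage of suprathreshold within-/between-network edges per interval.

    One row per (condition, interval, CP|DP): survivors in that edge class and
    interval, divided by the class's edge count in the interval, as a
    percentage.  Empty intervals yield missing values.
    """
    if not masks:
        raise ValueError("need at least one mask")
    n = masks[0].mask.shape[0]
    ids = tuple(region_ids) if region_ids else tuple(str(i) for i in range(n))
    labels = part.labels_for(ids)
    iu = np.triu_indices(n, k=1)
    within = labels[iu[0]] == labels[iu[1]]
    edge_bin = bins.bins[iu]
    if conditions is None:
        conditions = [m.condition or f"task{i}" for i, m in enumerate(masks)]
    rows = []
    for cond, mask in zip(conditions, masks):
        surv = mask.mask[iu]
        for b in range(bins.n_intervals):
            in_bin = edge_bin == b
            for cls, sel in (("CP", within), ("DP", ~within)):
                total = int((in_bin & sel).sum())
                count = int((in_bin & sel & surv).sum())
                rows.append({
                    "condition": cond,
                    "interval": f"{bins.intervals[b][0]}-{bins.intervals[b][1]}",
                    "interval_index": b,
                    "statistic": cls,
                    "n_edges": total,
                    "n_surviving": count,
                    "percentage": 100.0 * count / total if total else np.nan,
                })
    return pd.DataFrame(rows)


def one_way_anova(
    observations: Sequence[tuple[float, object]],
) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA over (value, group) observations.

    Returns (F, df_between, df_within, p).  Requires at least two groups and
    more observations than groups; all-identical values make F undefined.
    """
    values = np.asarray([v for v, _ in observations], dtype=float)
    groups = [g for _, g in observations]
    uniq = list(dict.fromkeys(groups))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if len(values) <= len(uniq):
        raise ValueError("need more observations than groups")
    if np.ptp(values) == 0:
        raise ValueError("all observations identical; F undefined")
    samples = [values[[g == u for g in groups]] for u in uniq]
    F, p = stats.f_oneway(*samples)
    df_between = len(uniq) - 1
    df_within = len(values) - len(uniq)
    return float(F), df_between, df_within, float(p)


def write_sc(path, sc: SCMatrix) -> None:
    from .data import write_matrix
    write_matrix(path, sc.values, sc.region_ids)


def read_sc(path) -> SCMatrix:
    from .data import read_matrix
    values, ids = read_matrix(path)
    return SCMatrix(values=values, region_ids=ids)
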