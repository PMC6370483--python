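"""Reusable synthetic-study drivers: recovery, null-model, and structure-function runs.

Each function wires the generator and the analysis stages into one named
experiment with a scalar outcome, so tests, examples and reproduction scripts
all run exactly the same procedures.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .divergence import UNPAIRED_BINNING
from .mapping import edgewise_js_matrix, threshold_pooled
from .nulls import (
    empirical_p,
    label_permutation_test,
    surrogate_null,
    suprathreshold_count,
)
from .structure import cpdp_by_bin, one_way_anova, percentile_bin_assignment
from .synthetic import SyntheticSpec, default_partition, generate_dataset

__all__ = [
    "plant_within_block_edges",
    "planted_recovery",
    "permutation_significance",
    "surrogate_significance",
    "structure_function_contrast",
]


def plant_within_block_edges(
    n_regions: int,
    n_planted: int,
    delta_r: float,
    seed: int,
    networks=None,
) -> tuple[tuple[int, int, float], ...]:
    """Pick distinct within-network edges to plant, seeded and reproducible."""
    kwargs = {} if networks is None else {"networks": networks}
    part = default_partition(n_regions, **kwargs)
    ids = tuple(sorted(part.assignment))
    labels = part.labels_for(ids)
    iu = np.triu_indices(n_regions, k=1)
    within = np.flatnonzero(labels[iu[0]] == labels[iu[1]])
    if n_planted > within.size:
        raise ValueError("more planted edges requested than within-block edges")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xED)))
    chosen = rng.choice(within, size=n_planted, replace=False)
    return tuple((int(iu[0][e]), int(iu[1][e]), delta_r) for e in chosen)


def _mask_recall(mask: np.ndarray, truth: pd.DataFrame) -> float:
    hits = sum(bool(mask[int(r.i), int(r.j)]) for r in truth.itertuples())
    return hits / len(truth)


def planted_recovery(
    n_regions: int = 100,
    n_subjects: int = 50,
    n_planted: int = 20,
    delta_r: float = 0.5,
    n_replicates: int = 10,
    T: int = 1200,
    percentile: float = 95.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Planted-edge recall of the pooled-percentile mask over seeded replicates.

    Per replicate: simulate disjoint rest/task cohorts with ``n_planted``
    within-network edges shifted by ``delta_r``, compute the unpaired edgewise
    JS matrix, threshold at the pooled percentile, and measure the fraction of
    planted edges inside the mask (recall) plus the planted fraction of the
    mask (precision).
    """
    rows = []
    for rep in range(n_replicates):
        rep_seed = int(np.random.SeedSequence((seed, rep)).generate_state(1)[0]
                       % (2**31))
        planted = plant_within_block_edges(n_regions, n_planted, delta_r,
                                           rep_seed)
        spec = SyntheticSpec(
            n_regions=n_regions, n_subjects_rest=n_subjects,
            n_subjects_task=n_subjects, planted_edges=planted, T=T,
            seed=rep_seed,
        )
        ds = generate_dataset(spec)
        js = edgewise_js_matrix(ds.rest, ds.task)
        _, masks = threshold_pooled([js], percentile)
        mask = masks[0].mask
        recall = _mask_recall(mask, ds.truth)
        n_surv = int(np.triu(mask, k=1).sum())
        hits = recall * n_planted
        rows.append({"replicate": rep, "seed": rep_seed, "recall": recall,
                     "precision": hits / n_surv if n_surv else np.nan,
                     "n_survivors": n_surv})
    return pd.DataFrame(rows)


def permutation_significance(
    n_regions: int = 100,
    n_subjects: int = 50,
    n_planted: int = 20,
    delta_r: float = 0.5,
    n_permutations: int = 100,
    T: int = 1200,
    percentile: float = 95.0,
    seed: int = 0,
) -> dict:
    """Label-permutation test on one planted-effect synthetic study.

    Returns the observed suprathreshold count, the permutation counts, and
    the empirical p-value; with ``delta_r=0`` this measures the false-positive
    behaviour instead.
    """
    planted = (plant_within_block_edges(n_regions, n_planted, delta_r, seed)
               if delta_r != 0 else ())
    spec = SyntheticSpec(n_regions=n_regions, n_subjects_rest=n_subjects,
                         n_subjects_task=n_subjects, planted_edges=planted,
                         T=T, seed=seed)
    ds = generate_dataset(spec)
    js = edgewise_js_matrix(ds.rest, ds.task)
    cutoff, _ = threshold_pooled([js], percentile)
    nd = label_permutation_test(ds.rest, ds.task, cutoff,
                                n_permutations=n_permutations, seed=seed + 1)
    return {"observed": nd.observed, "counts": nd.counts,
            "p": nd.p_value(), "cutoff": cutoff}


def surrogate_significance(
    n_regions: int = 100,
    n_subjects: int = 20,
    n_planted: int = 20,
    delta_r: float = 0.6,
    n_realizations: int = 100,
    T: int = 400,
    percentile: float = 95.0,
    seed: int = 0,
) -> dict:
    """AAFT-surrogate null for one planted-effect synthetic study.

    The observed suprathreshold count on the original data is compared with
    the counts obtained after replacing every region series by an independent
    AAFT surrogate and rebuilding the FCs and the JS map.
    """
    planted = plant_within_block_edges(n_regions, n_planted, delta_r, seed)
    spec = SyntheticSpec(n_regions=n_regions, n_subjects_rest=n_subjects,
                         n_subjects_task=n_subjects, planted_edges=planted,
                         T=T, seed=seed)
    ds = generate_dataset(spec)
    js = edgewise_js_matrix(ds.rest, ds.task)
    cutoff, _ = threshold_pooled([js], percentile)
    observed = suprathreshold_count(js, cutoff)
    nd = surrogate_null(ds.rest_ts, ds.task_ts, cutoff,
                        n_realizations=n_realizations, seed=seed + 1,
                        condition=ds.task.condition)
    return {"observed": observed, "counts": nd.counts,
            "p": empirical_p(observed, nd.counts), "cutoff": cutoff}


def structure_function_contrast(
    n_regions: int = 60,
    n_subjects: int = 50,
    delta_r: float = 0.5,
    planted_frac_per_bin: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4),
    n_tasks: int = 3,
    T: int = 1200,
    percentile: float = 95.0,
    seed: int = 0,
) -> dict:
    """Structure-function fixture: SC weight covaries with planted within-FN shifts.

    Structural weights are drawn uniformly over (0, 5] for every edge; within
    each SC-weight quintile, a fraction ``planted_frac_per_bin[b]`` of the
    quintile's within-network edges is shifted by ``delta_r`` in the task
    condition, so the density of strongly reconfigured within-network edges
    increases with structural weight.
    Returns the per-bin CP/DP table and one-way ANOVA results; the expected
    qualitative pattern is CP rising across bins with no such trend for DP.
    """
    from .structure import BinAssignment, SCMatrix

    part = default_partition(n_regions)
    ids = tuple(sorted(part.assignment))
    labels = part.labels_for(ids)
    n = n_regions
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5F)))
    iu = np.triu_indices(n, k=1)
    w = rng.uniform(0.05, 5.0, iu[0].size)
    sc_values = np.zeros((n, n))
    sc_values[iu] = w
    sc_values = sc_values + sc_values.T
    sc = SCMatrix(values=sc_values, region_ids=ids)
    bins = percentile_bin_assignment(sc)
    edge_bin = bins.bins[iu]
    within = labels[iu[0]] == labels[iu[1]]

    planted: list[tuple[int, int, float]] = []
    for b, frac in enumerate(planted_frac_per_bin):
        pool = np.flatnonzero(within & (edge_bin == b))
        k = int(round(frac * pool.size))
        take = rng.choice(pool, size=min(k, pool.size), replace=False)
        planted += [(int(iu[0][e]), int(iu[1][e]), delta_r) for e in take]

    # several task cohorts (fresh subjects, same planted scheme) against one
    # shared rest baseline, so each percentile bin gets n_tasks observations
    js_list = []
    rest = None
    truth = None
    for t in range(n_tasks):
        task_seed = int(np.random.SeedSequence((seed, 0x7A, t))
                        .generate_state(1)[0] % (2**31))
        spec = SyntheticSpec(n_regions=n, n_subjects_rest=n_subjects,
                             n_subjects_task=n_subjects,
                             planted_edges=tuple(planted), T=T,
                             seed=task_seed, task_condition=f"TASK{t}")
        ds = generate_dataset(spec)
        if rest is None:
            rest, truth = ds.rest, ds.truth
        js_list.append(edgewise_js_matrix(rest, ds.task))
    cutoff, masks = threshold_pooled(js_list, percentile)
    table = cpdp_by_bin(masks, part, bins, region_ids=ids)
    anova = {}
    for stat in ("CP", "DP"):
        sub = table[(table.statistic == stat) & table.percentage.notna()]
        anova[stat] = one_way_anova(
            list(zip(sub.percentage, sub.interval_index))
        ) if sub.interval_index.nunique() >= 2 else None
    return {"table": table, "anova": anova, "cutoff": cutoff, "sc": sc,
            "bins": bins, "truth": truth, "masks": masks}
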