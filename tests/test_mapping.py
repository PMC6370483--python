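"""Edgewise JS maps, pooled thresholding, CP/DP, and summary diagnostics."""

import numpy as np
import pytest

from connectodist.data import Cohort, FCMatrix, NetworkPartition
from connectodist.divergence import UNPAIRED_BINNING, BinningScheme
from connectodist.mapping import (
    JSMatrix,
    ThresholdMask,
    centralized_processing,
    cpdp_cosine_similarity,
    cpdp_table,
    cross_task_summary,
    distributed_processing,
    edgewise_js_matrix,
    edgewise_paired_js_matrix,
    js_baseline_correlation,
    nodal_js_strength,
    threshold_pooled,
)


def cohort_from_stack(stack, condition="REST", prefix="s"):
    mats = []
    for v in stack:
        v = np.asarray(v, dtype=float)
        np.fill_diagonal(v, 1.0)
        mats.append(FCMatrix(values=v, region_ids=[f"r{i}" for i in
                                                   range(v.shape[0])]))
    return Cohort(condition, tuple(f"{prefix}{i}" for i in range(len(mats))),
                  tuple(mats))


def random_cohort(rng, n_subj=8, n=6, condition="REST", prefix="s"):
    stack = []
    for _ in range(n_subj):
        a = rng.uniform(-0.4, 0.4, (n, n))
        stack.append(np.clip(0.5 * (a + a.T), -1, 1))
    return cohort_from_stack(stack, condition, prefix)


def js_from_values(values, condition="T"):
    v = np.asarray(values, dtype=float)
    return JSMatrix(values=v, condition=condition, mode="unpaired",
                    binning=UNPAIRED_BINNING)


class TestEdgewiseJS:
    def test_identical_cohorts_all_zero(self, rng):
        rest = random_cohort(rng)
        task = Cohort("TASK", tuple(f"t{i}" for i in range(rest.n_subjects)),
                      rest.matrices)
        js = edgewise_js_matrix(rest, task)
        assert np.array_equal(js.values, np.zeros_like(js.values))

    def test_diagonal_zero(self, rng):
        js = edgewise_js_matrix(random_cohort(rng),
                                random_cohort(rng, condition="T", prefix="t"))
        assert np.all(np.diag(js.values) == 0)

    def test_subject_order_invariance(self, rng):
        rest = random_cohort(rng)
        task = random_cohort(rng, condition="T", prefix="t")
        js1 = edgewise_js_matrix(rest, task)
        perm = rng.permutation(rest.n_subjects)
        rest2 = Cohort("REST", tuple(rest.subjects[i] for i in perm),
                       tuple(rest.matrices[i] for i in perm))
        js2 = edgewise_js_matrix(rest2, task)
        assert np.array_equal(js1.values, js2.values)

    def test_shared_subjects_warn(self, rng):
        rest = random_cohort(rng)
        task = Cohort("TASK", rest.subjects,
                      random_cohort(rng, condition="x").matrices)
        with pytest.warns(UserWarning, match="share subjects"):
            edgewise_js_matrix(rest, task)

    def test_planted_edges_stand_out(self, small_dataset):
        ds = small_dataset
        js = edgewise_js_matrix(ds.rest, ds.task)
        iu = np.triu_indices(js.n_regions, k=1)
        planted = set(zip(ds.truth.i, ds.truth.j))
        flags = np.array([(i, j) in planted for i, j in zip(*iu)])
        planted_mean = js.values[iu][flags].mean()
        background = js.values[iu][~flags]
        assert planted_mean > np.percentile(background, 99)


class TestPairedJS:
    def test_identical_per_subject_all_zero(self, rng):
        rest = random_cohort(rng)
        task = Cohort("TASK", rest.subjects, rest.matrices)
        js = edgewise_paired_js_matrix(rest, task)
        assert np.array_equal(js.values, np.zeros_like(js.values))

    def test_unit_shift_gives_one(self, rng):
        rest_stack, task_stack = [], []
        for _ in range(6):
            a = rng.uniform(-0.3, 0.3, (4, 4))
            v = 0.5 * (a + a.T)
            v[0, 1] = v[1, 0] = -0.5
            w = v.copy()
            w[0, 1] = w[1, 0] = 0.5  # exactly +1.0 shift on one edge
            rest_stack.append(v)
            task_stack.append(w)
        rest = cohort_from_stack(rest_stack, "REST")
        task = Cohort("TASK", rest.subjects,
                      cohort_from_stack(task_stack, "TASK").matrices)
        js = edgewise_paired_js_matrix(rest, task)
        assert js.values[0, 1] == 1.0
        others = np.triu(js.values, k=1)
        others[0, 1] = 0
        assert np.all(others == 0)

    def test_zero_bin_jitter_all_zero(self, rng):
        rest = random_cohort(rng, n=4)
        task_mats = []
        for m in rest.matrices:
            d = np.triu(rng.uniform(0, 0.0999, (4, 4)), k=1)
            task_mats.append(m.values + d + d.T)  # every diff in [0, 0.1)
        task = Cohort("TASK", rest.subjects,
                      cohort_from_stack(task_mats, "TASK").matrices)
        js = edgewise_paired_js_matrix(rest, task)
        assert np.array_equal(js.values, np.zeros_like(js.values))

    def test_subject_mismatch_rejected(self, rng):
        rest = random_cohort(rng)
        task = random_cohort(rng, condition="T", prefix="t")
        with pytest.raises(ValueError, match="identical subject lists"):
            edgewise_paired_js_matrix(rest, task)


class TestThresholdPooled:
    def test_distinct_entries_top_survivor(self):
        v = np.zeros((5, 5))
        iu = np.triu_indices(5, k=1)
        v[iu] = np.arange(1, 11) / 100
        js = js_from_values(v + v.T)
        cutoff, masks = threshold_pooled([js], 95)
        assert masks[0].n_survivors == 1
        assert masks[0].mask[np.unravel_index(np.argmax(v), v.shape)]

    def test_all_ties_no_survivors(self):
        v = np.full((4, 4), 0.3)
        np.fill_diagonal(v, 0)
        cutoff, masks = threshold_pooled([js_from_values(v)], 95)
        assert masks[0].n_survivors == 0

    def test_pooled_count_near_five_percent(self, rng):
        mats = []
        for t in range(7):
            a = rng.uniform(0, 1, (20, 20))
            v = np.triu(a, k=1)
            mats.append(js_from_values(v + v.T, condition=f"T{t}"))
        cutoff, masks = threshold_pooled(mats, 95)
        total = sum(m.n_survivors for m in masks)
        pooled_n = 7 * (20 * 19 // 2)
        # tie-free uniform draws: strictly-above count is about 5%
        assert total == pytest.approx(0.05 * pooled_n, abs=3)

    def test_extreme_percentiles(self, rng):
        a = rng.uniform(0.1, 0.9, (6, 6))
        v = np.triu(a, k=1)
        js = js_from_values(v + v.T)
        _, m0 = threshold_pooled([js], 0)
        iu = np.triu_indices(6, k=1)
        assert m0[0].n_survivors == (js.values[iu] > js.values[iu].min()).sum()
        _, m100 = threshold_pooled([js], 100)
        assert m100[0].n_survivors == 0


def two_block_partition():
    # 3 regions in A, 4 in B
    assignment = {f"r{i}": ("A" if i < 3 else "B") for i in range(7)}
    return NetworkPartition(assignment, networks=("A", "B"))


def mask_from_edges(n, edges, cutoff=0.5):
    m = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        m[i, j] = m[j, i] = True
    return ThresholdMask(mask=m, cutoff=cutoff)


class TestCPDP:
    def test_full_and_empty(self):
        part = two_block_partition()
        n = 7
        ids = tuple(f"r{i}" for i in range(n))
        all_edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
        cp = centralized_processing(mask_from_edges(n, all_edges), part, ids)
        assert cp == {"A": 1.0, "B": 1.0}
        dp = distributed_processing(mask_from_edges(n, all_edges), part, ids)
        assert dp == {("A", "B"): 1.0}
        cp0 = centralized_processing(mask_from_edges(n, []), part, ids)
        assert cp0 == {"A": 0.0, "B": 0.0}

    def test_counted_fractions(self):
        part = two_block_partition()
        ids = tuple(f"r{i}" for i in range(7))
        # 3 of B's 6 within edges survive
        mask = mask_from_edges(7, [(3, 4), (3, 5), (5, 6)])
        cp = centralized_processing(mask, part, ids)
        assert cp["B"] == 0.5
        # 6 of the 12 A-B edges survive
        cross = [(0, 3), (0, 4), (1, 3), (1, 5), (2, 6), (2, 3)]
        dp = distributed_processing(mask_from_edges(7, cross), part, ids)
        assert dp[("A", "B")] == 0.5

    def test_small_network_warns_nan(self):
        part = NetworkPartition({"r0": "A", "r1": "B", "r2": "B"},
                                networks=("A", "B"))
        with pytest.warns(UserWarning, match="fewer than 2"):
            cp = centralized_processing(mask_from_edges(3, []), part,
                                        ("r0", "r1", "r2"))
        assert np.isnan(cp["A"])

    def test_edge_class_conservation(self, rng):
        n = 12
        ids = tuple(f"r{i}" for i in range(n))
        assignment = {f"r{i}": "ABC"[i % 3] for i in range(n)}
        part = NetworkPartition(assignment, networks=("A", "B", "C"))
        m = rng.random((n, n)) < 0.3
        m = np.triu(m, k=1)
        m = m + m.T
        mask = ThresholdMask(mask=m, cutoff=0.5)
        labels = part.labels_for(ids)
        within = 0
        for k in ("A", "B", "C"):
            idx = np.flatnonzero(labels == k)
            within += int(np.triu(mask.mask[np.ix_(idx, idx)], k=1).sum())
        between = 0
        for a in range(3):
            for b in range(a + 1, 3):
                ia = np.flatnonzero(labels == "ABC"[a])
                ib = np.flatnonzero(labels == "ABC"[b])
                between += int(mask.mask[np.ix_(ia, ib)].sum())
        assert within + between == mask.n_survivors


class TestSummaries:
    def test_single_task_identity(self, rng):
        a = rng.uniform(0, 1, (5, 5))
        js = js_from_values(np.triu(a, k=1) + np.triu(a, k=1).T)
        for stat in ("max", "median"):
            summary, _ = cross_task_summary([js], stat)
            assert np.array_equal(summary.values, js.values)

    def test_order_statistics(self):
        maps = []
        for v in (0.1, 0.2, 0.6):
            m = np.zeros((3, 3))
            m[0, 1] = m[1, 0] = v
            maps.append(js_from_values(m))
        mx, _ = cross_task_summary(maps, "max")
        md, _ = cross_task_summary(maps, "median")
        assert mx.values[0, 1] == 0.6
        assert md.values[0, 1] == 0.2
        md2, _ = cross_task_summary(maps[:2], "median")
        assert md2.values[0, 1] == pytest.approx(0.15)

    def test_nodal_strength_single_edge(self):
        v = np.zeros((4, 4))
        v[1, 2] = v[2, 1] = 0.8
        js = js_from_values(v)
        mask = mask_from_edges(4, [(1, 2)])
        s = nodal_js_strength(js, mask)
        assert np.allclose(s, [0, 0.2, 0.2, 0])

    def test_nodal_strength_empty_mask(self, rng):
        a = rng.uniform(0, 1, (4, 4))
        js = js_from_values(np.triu(a, k=1) + np.triu(a, k=1).T)
        assert np.all(nodal_js_strength(js, mask_from_edges(4, [])) == 0)


class TestBaselineCorrelation:
    def test_constructed_dependence(self, rng):
        rest = random_cohort(rng, n_subj=9, n=8)
        med = np.median(rest.stacked(), axis=0)
        v = np.clip((med + 1) / 2, 0, 1)  # increasing function of median FC
        v = np.triu(v, k=1)
        js = JSMatrix(values=v + v.T, condition="T", mode="unpaired",
                      binning=UNPAIRED_BINNING,
                      region_ids=rest.region_ids)
        assert js_baseline_correlation(js, rest) > 0.99

    def test_independent_near_zero(self, rng):
        n = 142  # ~10,000 edges
        stack = []
        for _ in range(5):
            a = rng.uniform(-0.4, 0.4, (n, n))
            stack.append(np.clip(0.5 * (a + a.T), -1, 1))
        rest = cohort_from_stack(stack)
        v = np.triu(rng.uniform(0, 1, (n, n)), k=1)
        js = JSMatrix(values=v + v.T, condition="T", mode="unpaired",
                      binning=UNPAIRED_BINNING, region_ids=rest.region_ids)
        assert abs(js_baseline_correlation(js, rest)) < 0.05

    def test_constant_js_rejected(self, rng):
        rest = random_cohort(rng)
        v = np.full((6, 6), 0.3)
        np.fill_diagonal(v, 0)
        js = JSMatrix(values=v, condition="T", mode="unpaired",
                      binning=UNPAIRED_BINNING, region_ids=rest.region_ids)
        with pytest.raises(ValueError, match="constant"):
            js_baseline_correlation(js, rest)


class TestCosineSimilarity:
    def table(self, scale=1.0):
        from connectodist.mapping import CPDPTable
        return CPDPTable(cp={"A": 0.2 * scale, "B": 0.4 * scale},
                         dp={("A", "B"): 0.1 * scale}, condition="T")

    def test_identity_and_scale_invariance(self):
        a = self.table()
        assert cpdp_cosine_similarity(a, a) == {"A": pytest.approx(1.0),
                                                "B": pytest.approx(1.0)}
        b = self.table(scale=2.0)
        sims = cpdp_cosine_similarity(a, b)
        assert all(v == pytest.approx(1.0) for v in sims.values())

    def test_orthogonal_vectors(self):
        from connectodist.mapping import CPDPTable
        a = CPDPTable(cp={"A": 1.0, "B": 1.0}, dp={("A", "B"): 0.0})
        b = CPDPTable(cp={"A": 0.0, "B": 0.0}, dp={("A", "B"): 1.0})
        sims = cpdp_cosine_similarity(a, b)
        assert all(v == pytest.approx(0.0) for v in sims.values())

    def test_zero_vector_rejected(self):
        from connectodist.mapping import CPDPTable
        a = CPDPTable(cp={"A": 0.0}, dp={})
        with pytest.raises(ValueError, match="zero"):
            cpdp_cosine_similarity(a, a)
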