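# connectodist

Jensen–Shannon connectivity distance for cohorts of functional connectomes.

`connectodist` quantifies, edge by edge, how far a cohort of task-state
functional connectomes (FCs) sits from a resting-state baseline, and relates
the most reconfigured functional links to the underlying structural
connectome. It is written for researchers in brain connectomics and network
neuroscience who work with parcellated region × region correlation matrices
(any atlas; the conventions default to a 374-region cortical + subcortical
scheme grouped into 8 functional networks) and want a principled,
distribution-level distance between functional states.

## The measure

For an edge *(i, j)*, collect its Pearson correlation values across the
subjects of each cohort and discretize them on a uniform binning of [−1, 1]
(bin width 0.2), giving discrete distributions *P* (rest) and *Q* (task).
The Jensen–Shannon divergence

    JSD(P‖Q) = ½ D_KL(P‖M) + ½ D_KL(Q‖M),   M = ½(P + Q)

with base-2 logarithms is bounded in [0, 1], and its square root
JS_dist = √JSD is a true metric. Iterating over all edges yields a symmetric
JS-distance matrix per task. A paired variant for repeated measurements on
the same subjects discretizes the element-wise differences task − rest on
[−2, 2] (width 0.1) and compares them against a point-mass null at the bin
containing zero.

Thresholding the pooled JS distribution at its 95th percentile selects the
most reconfigured edges. Counting survivors per functional network gives

* **CP_k** (centralized processing): surviving within-network-*k* edges over
  all within-*k* edges,
* **DP_kl** (distributed processing): surviving edges between networks *k*
  and *l* over |k|·|l|.

Two null models validate observed counts: AAFT surrogates (amplitude
distribution and power spectrum preserved per region, inter-regional
coupling destroyed) and whole-matrix permutation of rest/task labels.
Structure–function association is assessed by binning edges into five
percentile intervals of structural weight or of search information (the
bits a random walker needs to follow the shortest structural path) and
comparing CP/DP percentages across intervals with a one-way ANOVA.

## Worked example

Simulate a rest cohort and a task cohort (20 subjects each, 40 regions)
with three planted edges whose coupling rises by 0.6 in the task, then map
and threshold the edgewise distance:

```bash
python examples/02_edgewise_distance_cpdp.py
```

```
pooled 95th-percentile cutoff: 0.3319
surviving edges: 38 of 780
planted edge (0,1) JS = 1.000  in mask: True
planted edge (2,3) JS = 1.000  in mask: True
planted edge (20,21) JS = 1.000  in mask: True

CP per network (fraction of within-network edges surviving):
  VIS   0.600
  SM    0.100
  ...
```

All three planted edges reach the maximal distance (their task and rest
correlation distributions occupy disjoint bins) and survive the pooled
threshold; the VIS network, which hosts two of them, shows the largest
centralized-processing fraction. The other examples demonstrate the
divergence primitives (`01`), the AAFT-surrogate and label-permutation
nulls (`03` — both report the minimal empirical p of 1/51 on a
planted-effect study), and the structure–function contrast (`04` — CP
climbs from 8% to 45% across structural-weight quintiles, one-way ANOVA
F = 46.96, df = 4, while DP stays flat at p = 0.11).

The same workflow is scriptable from the shell:

```bash
connectodist simulate --seed 3 --out fixture/
connectodist distance  --config fixture/config.yaml --out out/
connectodist null      --config fixture/config.yaml --out out/
connectodist structure --config fixture/config.yaml --out out/
```

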