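# Methods

## Edgewise connectivity distance

Given two cohorts of functional connectomes — symmetric matrices of Pearson
correlations between region time courses, one per subject — the framework
treats each edge's across-subject values as an empirical distribution and
measures the dissimilarity of those distributions between conditions.

Values are discretized on a uniform binning; bins are half-open `[lo, hi)`
with the final bin closed, so both endpoints of the range are representable.
The unpaired analysis bins raw correlations on [−1, 1] with width 0.2 (10
bins); the paired analysis bins same-subject differences on [−2, 2] with
width 0.1 (40 bins). Bin edges are computed as `lo + span·(i/n)` rather than
`lo + i·width` so that for these symmetric ranges the central edge is exactly
0.0 in floating point; the paired null's zero bin is therefore exactly
[0, 0.1). How a value lying exactly on an interior bin edge is assigned is a
convention (here: to the bin on its right); with continuous data the choice
is immaterial.

The Kullback–Leibler divergence uses base-2 logarithms and the standard
0·log 0 = 0 limit. The Jensen–Shannon divergence
½KL(P‖M) + ½KL(Q‖M) with M the equal mixture is symmetric, always finite,
and bounded in [0, 1] with base-2 logs; its square root is a metric
(symmetry, identity of indiscernibles, triangle inequality — all verified to
1e−12 in the tests). The paired variant compares the distribution of
element-wise task − rest differences against a point mass at the zero bin.
Note that the paired measure has a floor for symmetric noise: differences
centered at zero straddle the [0, 0.1) bin boundary, so even pure
test–retest jitter yields distances near √JSD({½,½}, {1,0}) ≈ 0.56. The
measure is therefore interpreted relatively (via percentile thresholds),
not absolutely.

## FC construction

Parcellated region × time series are band-pass filtered with a first-order
Butterworth filter applied forward and reverse (zero phase); the
conventional bands are [0.001, 0.08] Hz for rest and a more liberal
[0.001, 0.25] Hz for task runs. The sampling interval is a required input.
FCs are Pearson correlations between region series (diagonal forced to 1,
off-diagonal values clipped into [−1, 1] against floating-point overshoot);
matrices are kept signed and unthresholded. Phase-encoding runs are averaged
entry-wise. Re-z-scoring parcel series before correlation would be a no-op
(Pearson r is affine-invariant) and is not performed.

## Thresholding and CP/DP

The cutoff is the linear-interpolation percentile (default 95) of the
pooled upper-triangular JS values across all task matrices; each task's
binary mask keeps edges strictly greater than the cutoff. Strictness makes
the all-ties case well defined (no survivors). Centralized processing per
network is the fraction of its within-network edges surviving; distributed
processing per network pair is surviving between-network edges over
|k|·|l|. Fractions are stored; reports render percentages. Per-network DP
aggregation defaults to a pooled recount over all of the network's
between-network edges (weighting pairs by size), with the mean of the
pairwise values available as an alternative. The median across an even
number of tasks is the midpoint mean.

## Null models

AAFT surrogates follow the classic three-step scheme: rank-remap a Gaussian
white-noise realization onto the data's ordering, randomize the Fourier
phases of the Gaussianized series (DC and Nyquist kept real), and rank-remap
the original amplitudes onto the result. Sorted surrogate values equal
sorted originals exactly; the power spectrum is preserved approximately.
Surrogates are generated independently per region (univariate scheme),
which deliberately destroys inter-regional coupling; multivariate
phase-randomization variants are out of scope. Each realization rebuilds
all FCs and the edgewise JS map and counts entries above the original-data
cutoff (re-thresholding per realization is available by flag).

The label-permutation test reassigns whole FC matrices to rest/task groups
of the original sizes, leaving every matrix's correlation structure intact,
and recounts survivors above the original cutoff. Empirical p-values are
(1 + #{null ≥ observed})/(1 + n), guaranteed in (0, 1]. Randomness flows
from one master seed through per-realization, per-subject substreams, so
results reproduce exactly regardless of execution order.

The permutation count statistic has limited power when the effect is
sparse: because the cutoff is the 95th percentile of the same data, the
observed count is pinned near 5% of edges, and a planted effect touching
far fewer than 5% of edges raises it by only that many counts — comparable
to the permutation fluctuation of the count. A planted fraction at or above
the thresholded fraction makes the cutoff signal-dominated and the test
sharp (this regime is what the examples demonstrate).

## Structure–function association

Structural connectomes carry log10-transformed streamline weights (values
spanning roughly [0, 5]); the group average is the entry-wise arithmetic
mean. Search information for an ordered pair is −log2 of the probability
that a random walker follows the shortest path: shortest paths are computed
on edge lengths 1/weight (a −log10(w/max) transform is available), and the
step probability at node u is w_uv divided by u's strength. The default
walker is memoryless (full strength at every step); a variant that excludes
the incoming edge's weight after the first step is available, since both
conventions appear in the literature. Unreachable pairs produce +inf with a
warning. The group SI matrix is symmetrized as the mean of the two
directions.

Edges are assigned to five percentile intervals {0–20, …, 80–100} of the
positive entries of the group matrix (zero-weight edges are excluded rather
than forming a sixth bin); percentile ranks use maximum ranks for ties, so
interval b holds ranks in (20(b−1), 20b]. Per task and interval, the CP-type
percentage is surviving within-network edges over within-network edges in
the interval, and likewise DP for between-network edges. Differences across
intervals are tested with a classical one-way ANOVA (F, df_between = 4 with
five intervals, p from the F distribution).

## Synthetic studies

The generator draws each subject's region × time series from a zero-mean
multivariate normal whose target correlation matrix is block-structured
over the 8 functional networks (within-block r = 0.3, between-block
r = 0.05 by default), with a configurable set of planted edges shifted by
Δr in the task condition. Defaults mirror the targeted study design: 374
regions (360 cortical + 14 subcortical), 50 + 50 subjects, 1,200 frames at
0.72 s.

Between-subject variability is part of the data class being emulated: each
subject's target matrix receives a symmetric random deflection (entry sd
≈ 0.07 at the default `subject_effect_sd = 0.1`) before sampling. Without
it every subject is a clone up to sampling noise, each edge's across-subject
distribution collapses to a point mass and the JS analysis degenerates into
bin-edge artifacts with massive ties. In paired mode the same subjects (and
the same deflection) appear in both conditions, so subject effects cancel
in the paired differences — verified as an invariance of background paired
JS to the deflection size.

Planted targets can break positive-definiteness; targets are repaired by
eigenvalue clipping at 1e−8 followed by diagonal renormalization. This
repair perturbs unplanted entries slightly, so a planted study also carries
a small global rest–task difference — analogous to the global differences
real task data exhibit. The synthetic structural matrix places high weights
on all within-block edges, sparse lower weights between blocks, a
connectivity-guaranteeing ring, and clamps to [0, 5].

What the generator does not emulate: hemodynamics, autocorrelated BOLD
noise, motion, physiological artifacts, site effects. Passing tests
demonstrate the statistical machinery on well-specified cohort structure,
not robustness to those nuisances.

## Problem sizes and numerical choices

Tests and the acceptance suite run the synthetic studies at 100 regions
(50 + 50 subjects, 1,200 frames) for recovery and permutation inference, at
100 regions / 20 + 20 subjects / 400 frames for the 100-realization AAFT
null, and at 60 regions / 3 task cohorts for the structure–function
contrast; these sizes preserve the edge-to-planted-edge ratios that drive
the statistics. Probability vectors are validated to sum to 1 within 1e−12;
divergence oracle comparisons use 1e−12; FC symmetry uses 1e−10. Matrix
text I/O uses 17 significant digits and round-trip float parsing, making
write/read cycles bit-exact.
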