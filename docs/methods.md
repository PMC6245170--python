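# Methods

## Problem

Community detection on a single network is well studied; a resting-state
study yields one weighted network *per subject*, and most scientific
questions need a *single* group-level community structure to talk about
regions and connections on common ground. There is no external "ground
truth" for brain communities, so `netconsensus` evaluates candidate
group structures by an internal criterion: agreement with the subjects'
own individual community structures, quantified by Normalized Mutual
Information (NMI) and tested with a paired non-parametric permutation
test.

## Network construction

Per-subject pipelines start from ROI × time signal matrices or directly
from connectivity matrices.

* **Filtering** (`resample_and_filter`): the first 4 volumes are
  discarded, signals are linearly interpolated to 1 Hz, band-passed
  0.01–0.1 Hz with a 4th-order Butterworth applied forward–backward
  (zero phase; the effective magnitude response is the square of the
  4th-order prototype), then decimated to 0.5 Hz. Only the cutoffs are
  scientifically meaningful; the realization (filter family, order,
  interpolation) is this package's documented choice.
* **Connectivity**: Pearson correlation over all ROI pairs, diagonal
  forced to zero; a zero-variance ROI is an error naming the ROI.
  Fisher-Z (`atanh`) stabilizes variance; |r| = 1 (duplicated signals)
  is clipped to 1 − 1e−7 rather than mapped to ±∞.
* **Proportional thresholding** (`threshold_by_density`): the top
  `round(d · n(n−1)/2)` node pairs by **signed** weight are kept as a
  weighted graph. Rounding is half-up (a convention the underlying
  protocol leaves unstated; half-up is chosen and tested against exact
  rational arithmetic). Ties at the boundary break by node-pair
  lexicographic order, which makes edge sets nested across densities.
  Ranking by signed rather than absolute weight means anticorrelations
  are excluded first; if the retained range reaches non-positive
  weights they are dropped with a warning, because the modularity used
  downstream is defined for positive weights. Because `atanh` is
  strictly increasing, thresholding before or after Fisher-Z selects
  the same edges.

## Modularity and Louvain

Partition quality is weighted Newman–Girvan modularity at resolution 1:

    Q = Σ_c [ W_c / W − (S_c / 2W)² ]

with `W` the total edge weight, `W_c` the intra-community weight and
`S_c` the summed strength of community `c`. Optimization is a two-phase
Louvain: greedy local node moves to the neighboring community with the
largest positive ΔQ, then aggregation of communities into supernodes
(self-loops stored as twice the collapsed intra-weight so strengths are
preserved), repeated until no move improves Q by more than 1e−12.
The only stochastic element is the seeded shuffling of the node visit
order, so every run is exactly reproducible. The production protocol
runs Louvain `n_runs` times (default 100) with independent child seeds
and keeps the highest-Q partition, earliest run winning ties.

## Group-level detection schemes

* **VTS** (virtual typical subject): element-wise mean of the subjects'
  unthresholded matrices, thresholded at density `d`, then best-of-n
  Louvain. Cheap; ignores inter-subject variability.
* **IS** (individual structure): best-of-n Louvain per subject, NMI for
  every subject pair, and the subject with the highest mean NMI to the
  others (self-pair excluded) contributes their partition. Excluding
  the self-pair cannot change the argmax — it shifts every mean
  equally — but keeps the means interpretable. Ties go to the lowest
  subject index.
* **GA** (group analysis): a group Louvain run directly on the stack of
  individually thresholded subject graphs. Every candidate move is
  scored by the per-subject modularity change ΔQ_s evaluated on each
  subject's own graph (each with its own total weight); subjects whose
  ΔQ_s falls outside the 25th–75th percentile band (linear-interpolation
  percentiles, recomputed per candidate move) are excluded, and the
  move maximizing the trimmed mean is applied. Aggregation collapses
  communities in all subjects' graphs in parallel. A degenerate band
  that would exclude every subject falls back to the untrimmed mean
  with a warning. Trimming per candidate move, rather than once per
  optimization pass, is the literal reading adopted here; the band is a
  parameter so per-pass variants can be emulated by callers.

All three variants run on one engine in which the single-subject case
is a one-graph stack without trimming — so an ensemble of identical
matrices provably reduces to plain Louvain. Because a single group Q is
undefined for GA, its best-of-n selection uses the subject-mean of the
recalculated Q under each candidate partition.

## Agreement and testing

NMI is computed from the community-overlap confusion matrix with
natural logs and arithmetic-mean normalization `2I/(H₁+H₂)`; the
geometric-mean variant is a flag. Degenerate cases follow continuity:
two single-community partitions of the same nodes are identical, NMI 1;
if exactly one partition is trivial, I = 0 and NMI = 0.

For each density, each scheme's group partition is compared with every
subject's individual partition, giving one NMI per subject per scheme.
Two schemes are compared by the **subject-count statistic**
`#{a_s > b_s} − #{b_s > a_s}` (ties count for neither side) under a
**sign-flip null**: each subject's pair is swapped independently with
probability ½ — the standard exchangeability-preserving null for paired
designs; full relabeling nulls would be an alternative but the paired
structure makes sign-flips the natural choice. P-values are two-sided
with the add-one estimator `(b+1)/(N+1)` (always > 0, valid by
construction), default 10,000 iterations. The same machinery applies to
per-subject modularity recalculated under a fixed group partition on
each subject's own graph. The mean-difference statistic is provided for
contrast: a single extreme subject can mask 19 small consistent
differences in the mean but not in the count, so the count test is the
more robust default.

Multiplicity across the density grid (default 1–50 % in 1 % steps) is
controlled per approach-pair with Benjamini–Yekutieli step-up FDR at
α = 0.05, valid under the arbitrary dependence that nested density
thresholds induce.

At n = 20 subjects the count statistic is discrete: the largest
attainable two-sided level below 0.05 is 0.0414 (binomial sign-test
arithmetic), so the test is slightly conservative at conventional α.

## Consistency analysis

`iteration_consistency` re-runs VTS or GA `n_runs` times as *single*
runs (no best-of selection), against individual partitions detected
once and held fixed, and reports the mean and SD across runs of the
subject-mean NMI plus the all-pairs NMI among the detected partitions.
`pairwise_mean == 1` implies SD 0 (all runs identical). This isolates
the group method's own heuristic variability; independent seeds are
used rather than reusing the best-of-n runs.

## Synthetic data: what it emulates, and what it does not

`generate_ensemble` draws per-subject weighted networks around a
planted block structure: within-community pairs have mean weight `w_in`
(default 0.6), between-community pairs `w_out` (default 0.1), on a
90-node, 9×10-community, 20-subject geometry. Subject variability has
two separated knobs: `weight_sd` adds Gaussian noise to each upper-
triangle entry (symmetrization then halves the per-entry variance) and
`rewire_prob` swaps a pair's block identity, i.e. topological noise.
Matrices are clipped to [−1, 1] and zero-diagonal.
`generate_block_timeseries` instead draws multivariate-normal ROI
signals with exchangeable within/between-block correlations, so block
structure is induced through the correlation pipeline itself; the
implied covariance is checked for positive semi-definiteness.

Not emulated: haemodynamics, temporal autocorrelation, spatial
autocorrelation between neighboring ROIs, global signal, or realistic
degree distributions. Passing tests therefore show the *machinery* is
correct and the schemes behave as designed under controlled structure —
not that any scheme is superior on real fMRI data.

One behavior of the benchmark matters for interpreting trends: with
equal-size blocks and weight noise only, agreement between group and
individual partitions *rises* with density at the sparse end, because
very sparse thresholds fragment the planted blocks differently in every
subject. The empirically familiar decreasing trend — denser networks
are harder to summarize with one structure — reproduces once the
planted communities have unequal sizes (e.g. 15…6 on 60 nodes) and
moderate weight noise (sd 0.10), where added noise edges progressively
absorb the small communities. The trend tests and the acceptance script
use that regime over densities 0.15–0.50.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale protocols chosen as
reasonable defaults for simulation studies: 60–90 nodes, 10–20
subjects, best-of-5 to best-of-20 Louvain, 500–2000 permutation
iterations, 500–2000 null replicates for calibration. Production
defaults remain 100 runs and 10,000 iterations. Other numerics: move
acceptance tolerance 1e−12; matrix symmetry tolerance 1e−12 (1e−8 for
file input, repaired by averaging); p-values validated to (0, 1];
percentiles by linear interpolation.

## Known limitations

* GA keeps dense per-subject adjacency stacks in memory: fine for
  atlas-scale networks (90–200 nodes), not for voxel-level graphs.
* Negative-weight information is discarded at thresholding; no signed
  modularity.
* No overlapping or hierarchical communities; single resolution.
* The IS representative is the best *existing* individual partition;
  consensus-clustering alternatives (voting, co-association) are out of
  scope.
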