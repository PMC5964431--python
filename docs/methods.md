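# Methods

`metcovnet` implements a group-level metabolic covariance network analysis:
per-subject regional uptake signals (e.g. FDG-PET SUVR values over a
90-region anatomical parcellation) are turned into one network per cohort,
the networks are summarized by small-world graph statistics and
betweenness-centrality hubs, group differences are assessed by subject
relabeling permutation tests, and a seed region's voxel-wise coupling is
compared between groups with a two-sample Fisher-z statistic.

## Signal model and preprocessing

Each subject contributes a 3-D volume assumed already registered to a common
template space. Preprocessing is smooth → grayscale-rescale → extract →
normalize:

* **Smoothing.** Separable Gaussian convolution; per-axis sigma (voxels) =
  FWHM / (voxel size · √(8 ln 2)). Boundary handling is edge replication
  (configurable in principle; the choice only affects voxels within a kernel
  radius of the grid edge). Default FWHM 10 mm for real volumes; off for
  synthetic volumes, which are piecewise constant by construction.
* **Grayscale rescale.** Optional per-subject linear min–max map onto
  [0, 255]. Because later normalization removes per-subject affine scale,
  this step is a no-op for everything downstream of normalization; it is kept
  for fidelity to the volumetric workflow it reproduces and for users who
  export intermediate volumes. A constant volume maps to the lower bound.
* **Region extraction.** Arithmetic mean of the (processed) volume over each
  atlas label, in label order.
* **Whole-brain normalization.** Each subject's region vector is z-scored
  against the mean and population SD of the subject's in-mask voxels
  (labels > 0). Background voxels are excluded deliberately: the grid is
  mostly zeros and would otherwise dominate both moments. For cohorts
  supplied as tables (no volumes), the same normalization is computed across
  the region values, optionally weighted by region voxel counts — with
  weights equal to the atlas region sizes the table path reproduces the
  voxel path exactly on noise-free data.

The per-subject z-normalization makes the pipeline invariant to any positive
rescaling of a subject's volume (the intent of SUVR reference scaling); a
helper flag can additionally divide a volume by a named reference region's
mean before extraction.

## Group networks

For one cohort the normalized subjects × regions table X gives a sample
covariance S. Because the number of regions (90) exceeds the cohort size
(22), S is singular and the partial-correlation matrix is estimated through
diagonal shrinkage:

    S* = (1 − λ) S + λ diag(S),   Ω = (S*)⁻¹,
    R_ij = −Ω_ij / √(Ω_ii Ω_jj),  R_ii = 1.

Default λ = 0.5; λ is a stabilizer, and since the downstream binarization is
rank-based its exact value mostly cancels. A Moore–Penrose pseudo-inverse
route (`use_pinv=True`) is exposed for λ = 0; it is noisier and not the
default. At λ = 0 with p ≥ n the estimator refuses to run (singular matrix)
rather than silently inverting noise.

**Binarization.** The N(N−1)/2 upper-triangle entries are ranked by |R|
descending (ties broken by ascending index pair, so results are
deterministic); the top floor(s · N(N−1)/2) pairs become edges at sparsity
s. Negative correlations enter through their absolute value. At N = 90 and
s = 0.21 this is exactly 841 edges. `floor` (not rounding) is used, with a
1e-9 epsilon against float representation of grid values; on the standard
grid (0.06 to 0.40, step 0.01) the fractional parts of s·4005 are multiples
of 0.05, so the epsilon can never change a mathematically fractional count.

**Connectedness.** `min_connected_sparsity` scans the grid for the smallest
sparsity whose largest connected component exceeds a size threshold
(default > 50 nodes) and reports the full component-size curve.

## Graph metrics

All metrics are computed on the binary undirected adjacency with fixed
conventions:

* distances are unweighted shortest paths; disconnected pairs contribute 0
  to reciprocal sums;
* the characteristic path length is harmonic, L = 1/E_glob, so L · E_glob = 1
  identically whenever the graph has any edge (an edgeless graph reports
  L = +inf);
* clustering C_i = 2E(i)/(k_i(k_i−1)); nodes with degree < 2 contribute 0 to
  C and to local efficiency (keeps the means defined without dropping
  nodes);
* local efficiency of node k is the mean reciprocal distance *inside* the
  subgraph induced by k's neighbours (not full-graph distances);
* betweenness sums over unordered source–target pairs with endpoints
  excluded; bi = B_i / mean(B). bi is scale-free, so the ordered/unordered
  convention cancels. mean(bi) = 1 on any graph where some shortest path has
  an interior node; otherwise bi is all-zero and flagged degenerate. Nodes
  with bi > 1.5 are hubs (strict inequality).

**Null model.** Degree-preserving double-edge swaps: two edges (a,b), (c,d)
with distinct endpoints are replaced by (a,d), (c,b) when neither exists.
10 accepted swaps per edge by default (configurable), with a 100× try budget;
a graph too constrained to swap is returned with a warning rather than
looping forever. gamma = C/C_rand and lambda = L/L_rand use the means of C
and L over 200 rewired nulls by default; nulls with zero clustering or no
edges are excluded from the means. sigma = gamma/lambda summarizes
small-worldness.

The swap loop and the BFS distance sums are numba-compiled: the permutation
procedures below evaluate metrics on hundreds of thousands of 90-node
networks, and the compiled kernels keep a full run in minutes on one core.
Betweenness is delegated to igraph's exact Brandes implementation; the test
suite checks all metrics against independent pure-Python brute-force oracles
(exhaustive triangle counting, hand-rolled BFS, recursive shortest-path
enumeration).

## Permutation inference

Group differences are tested by pooling the subjects of both cohorts,
reshuffling group labels while preserving the group sizes, and recomputing
the full network → metric chain per relabeling. P-values use the add-one
convention p = (1 + #qualifying nulls)/(1 + n_perm), which can never be zero
and is decision-equivalent to a 95th-percentile cutoff on the null
distribution at α = 0.05.

Two details are deliberate:

* **Canonical pooling.** The pooled rows are sorted lexicographically before
  relabelings are drawn. The null distribution then depends only on the
  *set* of subjects, so swapping the cohort argument order flips every
  observed difference's sign while leaving two-sided p-values identical for
  equal group sizes — a property the test suite asserts exactly.
* **Shared randomness.** Within one sparsity all metrics share the same
  relabelings (one shuffle, all metrics), and the two pseudo-groups of a
  relabeling share the rewiring seed for their small-world nulls (common
  random numbers), so identical cohorts give identically zero differences.

The metric-vs-sparsity curves test seven metrics (C, L, E_glob, E_loc,
gamma, lambda, sigma) at each grid sparsity, one-tailed toward the observed
direction (the tail is reported per row). The small-world ratios *inside*
the permutation loop are estimated with a lighter null count
(`n_null_perm`, default 10) than the observed values (`n_null`, default
200): the inner nulls only feed the difference's null distribution, where
their extra variance is shared by both pseudo-groups, and the full 200 would
multiply run time by the permutation count. Hub comparison uses the
per-region statistic bi_A − bi_B at a fixed sparsity with two-sided
p-values (alterations in both directions are of interest), rows sorted by
p, and hub status in either group flagged. No multiple-testing correction is
applied across regions or sparsities in the headline tables; raw p < 0.05
is the operative threshold, and an FDR switch can be applied downstream by
the user. Permutation counts default to 2000 for the curves and 1000 for
the hub comparison, both configurable.

A permutation whose statistic is undefined (for example, all rewired nulls
degenerate at a very sparse threshold) contributes NaN and is excluded from
the p-value's numerator and denominator; more than 10% such permutations
aborts the test with diagnostics.

## Seed-based voxel comparison

For a chosen seed region, each subject's seed value is the mean intensity
over the seed's voxels; every in-mask voxel's Pearson correlation with the
seed values across subjects gives a per-group r-map. Fisher's
transformation z = arctanh(r) (values |r| ≥ 1 are clipped to 1 − 1e-7 with
a warning; they arise only at self-correlated voxels) and the two-sample
statistic

    z_diff = (z₁ − z₂) / √(1/(n₁−3) + 1/(n₂−3))

give a standard-normal deviate per voxel, two-sided p-values, and a
Benjamini–Hochberg mask at q = 0.05 over the voxels that carry a test
(zero-variance voxels are excluded from m). The denominator carries the
square root of the summed variances — the standard form of the two-sample
Fisher-z comparison. Significant voxels are split into strengthened
(z_diff > 0: first group's coupling stronger) and weakened (z_diff < 0)
masks.

## Synthetic data generator

The generator emulates the study design the package targets: two cohorts of
22 subjects with 90 regional SUVR-like values each (mean level 100), drawn
from group-specific multivariate normal distributions.

* **Covariance.** Identity × (1 + diagonal_load) plus edge_strength on the
  adjacency of a ring lattice (backbone_degree = 8 neighbours) rewired with
  probability 0.05 — a small-world backbone. Defaults: edge_strength 0.3,
  diagonal_load 0.5 (keeps the matrix well conditioned at n = 22, p = 90).
  If an alteration breaks positive definiteness, the diagonal is loaded by
  |min eigenvalue| + 0.01 — a monotone, documented repair rather than a
  spectral projection.
* **Planted alterations.** *Weaken* zeroes every covariance tie of a region
  (the region decouples). *Strengthen* adds a magnitude to the region's
  ties with a dispersed subset of partners (every max(2, N//18)-th region
  around the ring, ≈17 partners at N = 90). Dispersed rather than uniform
  is essential: a uniform increment to all 89 partners is, to first order, a
  loading on the subject's global-mean signal, which whole-brain
  normalization removes exactly — such an alteration is invisible to the
  pipeline at any sample size. Dispersed long-range ties survive
  normalization and give the region shortcut (high-betweenness) topology.
  `strengthen_pair` plants a single seed–target covariance increase for the
  voxel-level analysis.
* **Volumes.** A toy atlas partitions a centered ellipsoidal mask (semi-axes
  0.45 × grid extent, default 24³ grid) into contiguous regions by seeded
  multi-source BFS region growing — irregular regions, so extraction
  bookkeeping is genuinely exercised. Rendering paints each region with the
  subject's regional value plus i.i.d. Gaussian voxel noise.

What the generator does **not** emulate: PET physics (attenuation, scatter,
partial-volume effects), spatially correlated noise, anatomically realistic
covariance (modular/hemispheric structure), registration error, or
demographic confounds. Tests that pass on this generator therefore
demonstrate the correctness and calibration of the *analysis chain*, not
clinical sensitivity.

## Power regimes for recovery simulations

At the study size (n = 22 per group, 90 regions) the shrinkage
partial-correlation network is noise-dominated: roughly a third of the true
backbone edges survive binarization at 21% sparsity, and the across-seed
standard deviation of a region's bi is ≈ 0.3–0.4. Positive definiteness
bounds any single region's simultaneous correlation mass (k partners imply
per-partner correlations ≲ 1/√k), so no plantable single-region alteration
can shift bi by the ≈ 0.85 needed to reach the top ranks at n = 22 — a
genuine information limit of the design, not an implementation artifact.
The planted-hub recovery simulations therefore run at n = 160 per group
with shrinkage 0.1, where the chain recovers the planted region at rank ≈ 1;
the study defaults (n = 22, shrinkage 0.5) are unchanged everywhere else.
The seed-map recovery plants a seed–target correlation of ≈ 0.89 (covariance
increment 2.0 against the PD repair), which the Fisher-z comparison detects
through FDR at n = 22. Null calibration checks (type-I error of the
permutation chain, voxel-wise p-value uniformity) run at the study size,
where they belong.

## Reproducibility

Every stochastic component takes an explicit seed. The pipeline derives one
seed per stage from the master seed via `SeedSequence([master, stage_index])`,
so stages can be re-run independently and a full run is bit-reproducible;
the run manifest records the config hash and all stage seeds. The
double-edge-swap kernel seeds numba's Mersenne Twister, which is
deterministic per seed. TSV outputs are written with fixed float formatting
so repeated runs are byte-identical.

## Problem sizes in the shipped test suite

The test suite runs the oracle comparisons at N ≤ 12 (exhaustive path
enumeration is exponential), the small-world regime checks at N = 90 with
200 nulls × 20 seeds, type-I calibration with 200 simulated datasets × 200
permutations, the recovery simulations with 20 seeds × 200 permutations,
and one full pipeline run at 2 × 22 subjects, 90 regions, 24³ volumes, 200
nulls and 200 permutations over the full 0.06–0.40 sparsity grid. These
sizes keep a complete run on one core in the tens of minutes while leaving
every statistical check at sample sizes where its nominal behaviour is
testable.

## Known limitations

* The shrinkage default (0.5) is a stabilizer, not an optimized
  regularization (e.g. Ledoit–Wolf); the spec of the estimation problem at
  p = 90, n = 22 makes any fixed choice somewhat arbitrary, which is why the
  rank-based binarization was designed to be insensitive to it.
* Weighted and directed network variants, community detection, and
  cluster-extent inference on the voxel maps are out of scope.
* The curves' one-tailed-toward-observed p-values are post hoc directional;
  interpret borderline values accordingly.
* bi comparisons at n = 22 have very low power for realistic alterations
  (see the power section); the package reports honest p-values rather than
  pretending otherwise.
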