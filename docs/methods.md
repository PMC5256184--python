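# Methods

This note documents the models, conventions and numerical choices behind
`hubcentral`, in the order the pipeline runs.

## Synthetic cohorts

Each subject's region-by-time matrix is drawn from a zero-mean multivariate
Gaussian with a block correlation structure: `within_module_corr` (default
0.5) inside each planted module, `between_module_corr` (default 0.1) across
modules. These defaults give binary graphs whose low densities are dominated
by intra-module edges — the regime in which participation coefficient is
informative. For the default 92-region parcellation the six planted modules
have sizes [16, 16, 15, 15, 12, 18], with the boundary placed so that the
putamen falls in a striatal module while the pallidum, thalamus and
cerebellum share the next module; the planted hub (default `Thalamus_L`)
therefore gains cross-module coupling toward the putamen, which is exactly
what the seed-connectivity stage is designed to detect.

The hub effect adds `hub_boost` (default 0.25) plus a per-subject jitter
(sd 0.08) to every cross-module correlation of the hub, in affected groups
only (default TP). After the edit, the matrix is repaired to a valid
correlation matrix by clipping eigenvalues at 1e-6 and rescaling to unit
diagonal; a matrix that is still not positive definite afterwards is an
error, not a silent fix.

The simulated resting-tremor score (UPDRS-like item 20) is a linear readout
of the subject's realized hub increment δ:

    item20 = max(0, 4 + 20·δ + ε),  ε ~ N(0, 2.8²)

With jitter sd 0.08 the population correlation between δ and the score is
20·0.08 / √((20·0.08)² + 2.8²) = 0.50, giving the correlation stage a known
target; the baseline of 4 keeps the nonnegativity clip from truncating the
distribution. Tremor-history and action-tremor items (16, 21) carry half
that loading; rigidity (item 22) and bradykinesia (items 23–26) are
hub-independent patient symptoms, so specificity screens have a true null.
Ages are uniform on 45–70 years and sex is Bernoulli(0.5), independent of
the effect (a `confound_age` switch shifts affected-group ages by +5 years
for covariate-adjustment tests). Motion parameters, WM and CSF signals are
slow Gaussian random walks, mixed into every region signal at 0.1 of the
signal sd — small enough to be removable, large enough that skipping the
cleaning stage is visible.

The generator emulates only the second-order statistics the graph analysis
consumes. It does not model hemodynamic response, spatial autocorrelation,
physiological noise spectra, or scanner drift, so passing recovery tests
demonstrate correctness of the pipeline's inference, not robustness to every
property of real fMRI data.

## Cleaning

Fixed order: discard the first 10 volumes, OLS-regress the 26-column
nuisance design (24-parameter motion expansion + WM + CSF, intercept always
included), band-pass the residuals. Regression before filtering prevents
filtered nuisance structure from re-entering the residuals. The motion
derivative is a backward difference with a zero first row. Collinear design
columns are dropped greedily from the left with a warning. The filter is a
second-order Butterworth applied forward-backward (`sosfiltfilt`), i.e.
zero-phase with an effective fourth-order magnitude response; passband
0.01–0.08 Hz by default, and an upper edge at or above Nyquist
(1/(2·TR) = 0.25 Hz at TR = 2 s) is rejected.

Head-motion QC uses the 6 rigid-body parameters alone: summed
volume-to-volume translational and rotational excursions, and a Power-style
scalar framewise displacement (sum of absolute parameter differences,
rotations converted to arc length on a 50 mm sphere). This scalar FD is a
documented convention, not a voxel-level quantity.

## Graphs

Connectivity is the Pearson correlation of cleaned signals, diagonal zeroed;
exactly-constant regions get zero correlations with a warning. Thresholding
keeps the round(d·N(N−1)/2) largest *signed* correlations (strongest
positive coupling) per density; an `absolute` switch ranks |r| instead.
Nearest-integer rounding of the edge count is deliberate and documented
because floor vs round changes counts by one. Ties are broken by
lexicographic (i, j) order for determinism; with continuous data ties have
measure zero. Because every density takes a prefix of one ranking, edge sets
are nested and thresholding depends only on the rank order of the weights.
Disconnected graphs at low density are legal; no connectedness repair is
attempted. Whether negative correlations can enter the edge set at high
densities depends on the data under the signed rule; the behaviour is
defined (they can, if fewer positive pairs exist than requested edges) but
not prevented.

## Centrality

Degree and betweenness are global measures; within-module degree and
participation coefficient are modular measures evaluated against the
max-modularity partition of the same graph. Conventions:

* betweenness counts ordered pairs (h, j), i.e. twice the unordered sum —
  only group contrasts matter downstream, so the constant factor is fixed
  and documented; a `normalized` flag divides by (N−1)(N−2);
* partitions are recomputed per density (the graphs differ), by Louvain with
  a restart-specific RNG seed and max-Q selection over 100 restarts by
  default; restart seeds are drawn sequentially from the caller's seed, so
  increasing the restart count extends rather than reshuffles the stream,
  and the best Q is monotone in the number of restarts;
* Z uses the population standard deviation of the module's intra-module
  degree distribution, with Z = 0 when that sd is 0 (including singleton
  modules); P = 0 for isolated nodes; an edgeless graph yields a single
  module with Q defined as 0 and a warning.

Group-average networks are built by element-wise averaging of connectivity
matrices, thresholding at density 0.30, partitioning, and listing each query
node's neighbours as same-module vs other-module — the summary used to ask
which modules a hub reaches in each group.

## Group statistics

The design is repeated-measures: densities within-subject, group
between-subject, age (mean-centred) and sex (0/1) as covariates. The
reported group effect is the between-subject main effect, computed exactly
as the OLS ANCOVA on subject-level density-averaged values — the
between-subject stratum of a mixed ANOVA is algebraically the ANOVA on
subject means, so no approximation is involved; the suite verifies the
classical F = t² equivalence in the balanced two-group case. Within-subject
(density) effects are reported from a mixed ANOVA on covariate-residualized
values with Greenhouse–Geisser correction. Post hoc pairwise contrasts are
pooled-variance t-tests on covariate-adjusted density-averaged values,
matching the scale on which the clinical correlations are defined. Partial
correlations residualize both variables on the covariates (plus intercept)
and test the residual correlation against t with n−2−k degrees of freedom.

No multiple-testing correction is applied across nodes, metrics or scores:
the metrics are strongly interdependent and the node set is an a priori
hypothesis. Every report records this policy.

## Seed connectivity

The per-subject GLM regresses each target region on the bilateral seed's
mean signal (unweighted mean of left and right) with the full nuisance
design; the seed beta is the connectivity estimate, and a seed that is
numerically collinear with the nuisances (condition number > 1e8 after
column scaling) is rejected. Group contrasts within an a priori mask are
covariate-adjusted two-group t statistics; family-wise error over the mask
is controlled by the permutation distribution of the maximum |t| under
group-label permutation with covariates held fixed (default 5,000
permutations, seed-controlled), with the add-one convention
p = (1 + #{max ≥ |t|})/(n_perm + 1). This max-statistic correction is exact
at the region level and replaces voxel-based small-volume corrections, which
have no analog without image data; inference is peak-level (largest |t| in
the mask), and the peak "extraction" is the node's beta itself.

## Validation experiments and problem sizes

`hubcentral.validation` plants known truths and measures recovery. Sizes are
chosen so the full battery runs in minutes on one CPU; all are parameters:

* **planted-partition recovery**: 100 graphs of 40 nodes (4 modules of 10,
  p_in = 0.8, p_out = 0.05), 5 restarts; recovery = adjusted Rand > 0.9.
* **null calibration of the group test**: 500 simulated null cohorts
  (3 × 10 subjects, 7 densities, subject random intercepts); the group-effect
  p-value should be uniform (KS test) with ~5% type-I rate.
* **permutation FWE**: 500 null beta cohorts (2 × 20 subjects, 6-node mask,
  199 permutations); family-wise rejection at α = .05 should be ≤ nominal.
* **hub recovery**: 100 replicate cohorts (TP/HC, 20 per group, 40 nodes,
  185 volumes, hub boost 0.25), cleaned and profiled at 5 densities
  (0.10–0.40 step 0.075) with 2 restarts — the planted structure is strong
  enough that more restarts change nothing; power of the TP > HC t-test on
  the hub's density-averaged degree and participation, the hub's rank among
  group-mean participation values, and false positives at two control nodes
  in unaffected modules.
* **clinical-coupling recovery**: 100 affected-only cohorts of n = 22; the
  hub's measured cross-module coupling (mean correlation to out-of-module
  regions) is partially correlated with the tremor score. The measured
  coupling is a noisy estimate of the planted increment, so the recovered
  partial r is attenuated below the planted 0.5 (typically ≈ 0.37–0.45);
  the planted construct itself (increment vs score) is detected with power
  matching the Fisher-z analytic power at that n within a few points.

## Known limitations

Binary graphs only (no weighted-network analysis); no partial-correlation or
regularized connectivity estimation; no scrubbing of high-motion volumes; no
consensus clustering across subjects; region-level analysis throughout — no
voxel maps, cluster-extent inference or image registration. The ANCOVA's
two-group post hoc contrasts are computed on density-averaged values; a
density-wise post hoc convention would differ in detail. Statistical results
on synthetic cohorts validate the machinery, not any clinical claim.
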