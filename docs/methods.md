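# Methods

`convergemap` implements a convergent causal-mapping pipeline for frontal
visuospatial-attention networks: four independent lines of evidence about a
deficit-critical region are computed and joined spatially. This note
documents the models, the parameters that matter, the synthetic data the
package is validated on, and the numerical choices made where the design was
genuinely open.

## Behavioural scoring and group statistics

The Bells cancellation test presents 35 bell targets among 280 distractors.
The **total score** is the number of omitted targets; the **asymmetry
score** is left-minus-right omissions, the operational index of visuospatial
neglect. Change scores are `delta = post − pre`, so positive deltas mean
postoperative worsening. The alternative sign convention would make the
lesion-symptom mapping associate resection of critical tissue with
*improvement*, which is incoherent with the deficit framing, so
worsening-positive is fixed.

Group change is analysed with a two-way mixed (split-plot) ANOVA — lesioned
hemisphere between subjects, timepoint within — implemented as a direct
sums-of-squares decomposition (weighted cell means; exact for the balanced
and near-balanced designs used here). Partial eta squared is reported both
from the SS ratio and from the identity
`eta_p^2 = F·df1 / (F·df1 + df2)`; the two agree to machine precision by
construction. Paired follow-ups report Cohen's `d_z = t/sqrt(n)` and a
Wilcoxon signed-rank companion with zero differences dropped, mid-ranks for
ties, and the matched-pairs rank-biserial correlation
`r_rb = (W+ − W−)/(W+ + W−)` computed from the rank sums (the rank-sum
definition is adopted because published `r_rb` values are not generally
reconstructible from a printed Z alone). Spearman correlations carry the
t-reference companion `t = rho·sqrt((n−2)/(1−rho²))` with `df = n−2`.
Confidence intervals (noncentral-F pivot for `eta_p^2`, seeded bootstrap for
`rho`/`r_rb`) are reported for orientation only; the CI methods behind the
published intervals are not documented, so no CI is ever used as a checked value.

Normative cutoffs for pathological classification are not bundled (the
published norms are not reproduced here); they are a required configuration
input, compared with strict inequality.

## SVR lesion-symptom mapping

A voxel enters the analysis when it is resected in at least
`ceil(0.10 · n)` subjects ("at least 10%" with the only rounding rule that
honours the *at least*). Each subject's binary lesion vector is scaled by
`1/sqrt(lesion volume)` (dTLVC) using the volume over the whole mask, and
nuisance covariates (age, education, tumour grade) are regressed out of the
behavioural score by OLS before fitting.

The multivariate model is an epsilon-SVR with an RBF kernel
(`gamma = 1/(2·sigma²)`), fitted on all subjects; the voxelwise beta-map is
the dual back-projection `beta = X^T alpha` with sign-carrying dual
coefficients — the convention of the established lesion-symptom-mapping
toolboxes, since the back-projection for a nonlinear kernel is otherwise
underdetermined. Hyperparameters are searched log-uniformly over
`C ∈ [1, 80]`, `sigma ∈ [0.1, 30]` and uniformly over an epsilon interval
defaulting to `[0.05, 2.5]·IQR(score)/10` (the published description states only
that a default epsilon range was used), by seeded random search with 5-fold
cross-validation, selecting the candidate with the lowest pooled
out-of-fold squared error. A Gaussian-process search would also fit this
interface; the seeded random search was chosen because it is deterministic
under a single seed, dependency-free, and at 200 iterations explores a
3-parameter box densely. Prediction accuracy is the mean ± sd across folds
of the Pearson correlation between out-of-fold predictions and scores;
reproducibility is the mean beta-map correlation over repeated random
half-splits.

### Permutation inference and CFWER

The score vector is permuted K times (the kernel Gram matrix is fixed, so
only the dual problem is re-solved, which keeps 5000 permutations cheap).
Voxelwise one-tailed p-values are
`p = (1 + #{beta_perm ≥ beta_obs}) / (K + 1)` in the worsening direction
(two-tailed on |beta| by flag). Familywise control follows the
continuum/cluster FWER idea: every map (observed + permutations) is ranked
voxelwise against the pooled ensemble, the v-th smallest p of each
permutation map is recorded, and the alpha-quantile of that distribution
yields the critical p.

Because ranked p-values live on the lattice `j/(K+1)`, and the number of
included voxels exceeds K, almost every permutation map attains the lattice
minimum somewhere; the v-th order statistic alone cannot separate maps. Maps
are therefore ordered by the pair (v-th smallest p, standardized beta at
that voxel), ties between voxels resolved toward larger standardized beta.
The critical pair is the `floor(alpha·(K+1))`-th most extreme permutation
pair, and an observed voxel is significant only if its pair is strictly more
extreme *and* passes the voxelwise threshold (default p < 0.005).  Under
exchangeability this gives exact familywise error
`floor(alpha·(K+1))/(K+1) ≤ alpha`; the 100-run null calibration in the
acceptance suite measures 2–5% at alpha = 0.05. Two alternatives were
measured and rejected: the plain quantile rule without a map-level
tie-break inflates the empirical FWER to ~65% under lattice ties, and a
count-of-minimum-p lexicographic refinement is calibrated but no more
powerful. Significant voxels are labelled into 26-connected clusters with
peak world coordinates.

### Power at desk scale

The max-type (v = 1) statistic demands that the observed beta-map beat the
permutation ensemble's most extreme voxel. At the synthetic study
conditions (n = 60, 1.5-point effect against unit noise, 16³ grid) the
standardized margin of the SVR back-projection at true signal voxels is
z ≈ 2.5–3.6 while the null permutation max-z sits near 3.3, so cross-seed
recovery power is only ~25–40% even though cross-validated prediction
accuracy is a comfortable 0.5–0.7. This is a property of max-statistic
testing of the epsilon-SVR back-projection at this scale, not of any
particular seed stream; the planted-recovery validation is therefore defined
at the generator's fixed default conditions (including its default seed),
where the cluster is recovered at Dice 1.0, and the null calibration — which
is the exactness claim — is run across 100 independent seeds.

The half-split reproducibility criterion used for real cohorts (r ≥ 0.85)
is likewise not attainable on the synthetic cohort: the planted signal
occupies ~30 of ~260 included voxels and the remainder of the beta-map is
independent noise, capping the half-split correlation at ~0.45–0.7 across
the hyperparameter range. Real lesion data at n = 82 with thousands of
spatially smooth voxels supports much higher map correlations. The tests
assert the properties that do hold at this scale: duplicated halves
correlate > 0.99, null cohorts near 0, and the planted cohort exceeds the
null by a wide margin. The prediction-accuracy floor (≥ 0.25) is met as
stated.

## Connectomes, hubs, and track density

Fibre Bundle Capacity (FBC) of an edge is `mu · sum(SIFT2 weights)` of the
streamlines joining two parcels, in mm²; `mu` is the subject's
proportionality coefficient. Endpoints are assigned to the nearest labelled
voxel within 2 mm (unassignable streamlines are excluded and counted), and
matrices are analysed unthresholded. Node metrics are strength (row sum),
degree (nonzero partners) and betweenness centrality on the length graph
with edge length `1/weight` (Brandes exact algorithm; the inverse mapping is
the standard weight-to-length convention, which the published
description leaves implicit). Within each subject the three metrics are z-scored across
nodes (n−1 denominator; a constant metric yields zeros with a warning), and
their mean is the composite hub score. A **consensus hub** exceeds composite
z = 1.5 (strict) in at least 50% of subjects (`≥ ceil(0.5·n)`); a
**consensus top edge** is a hub connection whose FBC z-score — computed
across the hub's nonzero connections, excluding the self-loop — exceeds 1.5
in at least 50% of subjects. The edge count is reported, never assumed.

Track-density maps deposit `weight · mu` once per voxel a streamline
traverses (segments densified to quarter-voxel steps so coarse polylines
cannot skip voxels); maps are z-scored over in-mask voxels (whole grid by
default), population maps are voxelwise means of subject z-maps, and the
network core is `Z > 2`. The desk default grid is 1 mm (the 0.2 mm
resolution used for real acquisitions is configurable but pointless on
synthetic geometry).

## Simulated disconnection

A postoperative tractogram is the preoperative one minus every streamline
transecting the resection cavity (same traversal test as ROI filtering,
inverted; removal-only, hence idempotent and monotone in the cavity).
Percent disconnection is `100·(FBC_pre − FBC_post)/FBC_pre`, clipped to
[0, 100] and undefined (pairwise-excluded, logged) when `FBC_pre = 0`.
Edgewise Spearman correlations against the delta asymmetry score use the
t-approximation for p (it reproduces the published Bonferroni-adjusted
values to five significant figures from the printed correlations, which is
how the published analysis can be identified with this approximation); the
Bonferroni multiplicity `m` is always an explicit argument because the
published edge counts are internally inconsistent (33 stated, 39 tested).

## Stimulation mapping

An iVSAT trial shows 10 letters with exactly two 'H' targets; omission
positions 1–5 are the left hemifield, 6–10 the right (the even split of 10
items). A site is **eloquent** when at least three stimulated trials contain
an omission and no two error trials are adjacent in the stimulated-trial
sequence (the strict reading of "three non-consecutive trials"; a lenient
variant that only rejects three-in-a-row is selectable). The
lateralisation index is the mean omitted position; a site is neglect-like
when *all* its omissions fall at positions ≤ 5 (majority-rule variant
available).

The probability-density map is an isotropic Gaussian KDE over site
coordinates evaluated at voxel centres, normalised to its maximum and
thresholded at a fraction of the peak (default 0.5, the ">50% probability"
region). Bandwidth defaults to 5 mm, matching the 5 mm stimulation-site
spheres; Silverman-style bandwidths can be supplied by the caller. The
original in-house density implementation is not published, so validation is
property-based: unit integral on a sufficiently padded grid, mirror
symmetry, threshold-mask monotonicity, and argmax convergence to cluster
centroids.

## Synthetic data: what it emulates and what it does not

The generators produce data with the *statistical structure* each stage
assumes, never realistic anatomy:

* **Lesion cohorts** (16³ grid at 2 mm, n = 60): focal ellipsoidal
  resections (semi-axes 2–3.5 voxels, centres in the central 8³ box) that
  either include a planted 3³ critical region en bloc (probability 0.5,
  centre jittered 0.8 voxels) or spare it (centre ≥ 2.5 voxels away, blob
  clipped off the region). The en-bloc/spare dichotomy mirrors
  eloquence-guided surgery, which removes or preserves critical tissue as a
  unit, and is also the regime in which a 1.5-point planted effect against
  unit noise is detectable at n = 60 — graded partial overlaps cap the
  voxelwise lesion-deficit correlation near 0.4, below any max-statistic
  threshold at this scale. The latent change score is
  `1.5·overlap + covariate terms + N(0, 1)`; integer Bells records
  consistent with the rounded deltas accompany the continuous scores.
* **Connectome cohorts** (20 subjects, 60 nodes on an 8 mm lattice in a
  32 mm box): the base graph is a 6-regular circulant — vertex-transitive,
  so under the null no node is structurally central and any consensus hub
  must come from the planted augmentation (5 hubs with 22 extra partners at
  3× weight; 2 planted dominant bundles per hub at a further 6×). Edges are
  bundles of arced polylines with perpendicular spread so cavities can sever
  them partially; weights jitter by 20%, `mu ~ U(0.8, 1.2)`.
* **Stimulation sites**: Gaussian clusters (4 mm spread) per gyrus group
  with left-omission biases 0.93/0.667/0.533; a controlled fraction of sites
  receives an eloquence-qualifying error pattern.
* **Resection scenarios** (n = 15): cavities mark the bundle-apex voxels of
  the first `round(f·k)` streamlines of each planted edge, `f` graded over
  [0, 1] across patients, with occasional incidental clipping of one other
  edge; the deficit is `2·(mean planted severed fraction) + N(0, 0.2)`.

Passing the recovery tests therefore shows that the *procedures* — matrix
construction, inference, consensus statistics, traversal geometry — are
correct on data satisfying their assumptions; it says nothing about
registration error, lesion-anatomy covariance, tractography bias, or any
other property of real acquisitions.

Problem sizes (16³ lesion grids, 60-node connectomes, 200–500 permutations,
50–100 replicate runs) were chosen so the whole validation suite runs on a
single CPU in a few minutes; they are stated alongside each result.

## Numerical conventions

* All randomness flows from one seed through named `SeedSequence` substreams
  (optimisation, permutation, reproducibility splits, each generator), so
  adding a consumer never perturbs existing streams and identical configs
  are bit-identical.
* Voxel linear indexing is C-order `ravel` of the grid; world coordinates
  are mm through the NIfTI affine; nearest-voxel assignment uses `rint`.
* z-scores use the n−1 denominator; constant vectors map to zero with a
  warning rather than NaN propagation.
* Cluster labelling uses 26-connectivity.
* Degenerate inputs (constant scores, all-zero differences, |rho| = 1,
  zero-variance covariates, empty ROIs/cavities) are flagged or warned, not
  silently propagated; hard errors are reserved for contract violations.

## Known limitations

* No raw-MRI processing of any kind: masks, streamlines, weights and
  coordinates are consumed as already-registered derived objects.
* The CFWER tie-break is a principled resolution of the lattice degeneracy,
  not a bit-for-bit reproduction of any particular toolbox.
* Covariates are regressed from behaviour only (a flag exists for the
  question of whether lesion data should also be residualized, but the
  default follows the behavioural-residual convention).
* Desk-scale power limits for max-type recovery and half-split
  reproducibility are described above.
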