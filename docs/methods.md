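# Methods

`thalparc` implements an individualized thalamic-parcellation analysis for
diffusion MRI: segmentation of each subject's thalamus into k nuclei from
fiber orientation distributions (FODs), group comparison of the resulting
partitions, nucleus shape statistics from deformation fields, fixel- and
tensor-based microstructure with covariate-adjusted nonparametric statistics,
and classification of clinical groups from the regional metrics.  Because no
patient data ship with the package, a seeded phantom generator reproduces the
cohort structure the analysis assumes; every pipeline stage is exercised and
tested end-to-end on those phantoms.

## FOD representation and fixels

FODs are antipodally symmetric spherical functions stored as real, even-order
spherical-harmonic (SH) coefficients in MRtrix-style ordering (l ascending
over even orders, m from −l to +l).  At the default lmax = 6 each voxel
carries (lmax+1)(lmax+2)/2 = 28 coefficients, and the spherical integral of
the FOD is c00·2√π.  Amplitudes are evaluated on a subdivided-icosahedron
tessellation (4 subdivisions, 2562 directions — 1281 per half-sphere) whose
per-vertex solid-angle weights sum to 4π; weighted least-squares projection
onto the basis inverts sampling to ~1e−15 for band-limited functions, which
is the tessellation-adequacy check in the test suite.

Fixels (distinct fiber populations within a voxel) are extracted by sampling
the FOD on the mesh, clipping negative amplitudes (deconvolution ringing) to
zero, taking mesh-local maxima above `peak_threshold` (default 0.1, the only
amplitude threshold the source workflow prints) times the per-voxel maximum
as peaks, and assigning every positive sample to the nearest peak under the
antipodal angular metric.  A fixel's apparent fiber density (FD) is the
quadrature integral of its lobe; because samples from both antipodal lobes
are pooled, an isotropic FOD yields a single "peakless" +z fixel carrying the
full integral c00·2√π rather than silently dropping density.  At most
`max_fixels` (default 3) fixels are kept per voxel, sorted by descending FD.
Fiber-bundle cross-section is FC = |det J| / ‖J·d‖ for warp Jacobian J and
fixel direction d (the area change of the plane perpendicular to the fiber),
and FDC = FD·FC.  Across subjects, fixels are matched to the template voxel's
fixels by smallest angular distance with a 45° cutoff; unmatched template
fixels contribute nothing to regional means, and regional fixel means weight
every matched fixel equally.

## Segmentation

Voxels of the thalamus mask are clustered with k-means under the combined
metric D = α·X + (1−α)·β·Y, where X is the Euclidean distance between SH
coefficient vectors, Y the Euclidean distance between voxel coordinates (in
template-grid voxel units), α = 0.5 and β = 85 by default, and k = 7 nuclei
per hemisphere.  Centroids are initialized from a spatial-only Ward
agglomeration cut at k, making the whole procedure deterministic.  Because
the metric uses unsquared norms while centroids are updated by arithmetic
means (the standard heuristic, not the exact minimizer of summed unsquared
distances), the iteration carries an explicit monotonicity guard: if an
update would increase the summed assigned distance, the previous state is
restored and iteration stops, so the objective trace is non-increasing by
construction.  Empty clusters are re-seeded with the voxel farthest from its
assigned centroid (preserving k); assignment ties break to the lowest
centroid index.  Label correspondence across subjects uses Hungarian
assignment maximizing voxel overlap with a reference (the cohort-template
segmentation in the pipeline).

## Partition comparison

NMI(A,B) = −2 ΣΣ N_ij log(N_ij N / (N_i N_j)) / (Σ N_i log(N_i/N) +
Σ N_j log(N_j/N)) with 0·log 0 ≡ 0, computed from the voxel contingency
table; natural logs (the ratio is base-invariant, asserted in tests).  The
degenerate both-single-cluster case is defined as 1 with a warning.

Group-level consensus partitions are built, by default, by Hungarian label
alignment of all inputs to the first followed by per-voxel majority vote
(ties to the smallest label).  A co-association realization (average-linkage
agglomeration of 1 − co-association, cut at k) is also provided
(`method='coassoc'`); both are invariant to per-subject label permutations,
reproduce identical inputs exactly, and denoise beyond any single input.
The vote method is the default because its output responds gradually to the
group's composition; the hierarchical cut snaps to whole-group attractors,
which in simulation destroys the power of the reallocation test below (the
null values tie with the observed statistic for every unbalanced
reallocation).

Partition dissimilarity between groups is tested by computing the NMI
between the two groups' consensus partitions, then randomly reallocating
subjects to two groups of the original sizes (default 1000 permutations) and
recomputing; significance uses the empirical 2.5th–97.5th percentile
interval (two-tailed, α = 0.05), and an add-one two-tailed p-value around the
null median is also reported so p > 0 always.

## Shape statistics

The Jacobian of a displacement field u is J = I + ∂u/∂x by finite differences
(central in the interior, one-sided at borders, spacing = voxel size in mm);
log det J > 0 means expansion of the subject relative to the template.  A
folding warp (det ≤ 0 inside the analysis mask) is an error.  Per-nucleus
mean log-Jacobians of the patients are tested against zero with a linear
model on mean-centered covariates (age, intracranial volume, DOC duration):
the intercept's two-sided t-test is the covariate-adjusted one-sample test,
reducing exactly to the classical one-sample t with no covariates.  BH-FDR
at q = 0.05 corrects across nuclei.  Volumetric-ratio change is computed two
ways: from voxel counts of matched parcellations, and — when subject and
reference share one grid, as the phantoms do — as the per-nucleus mean of
exp(logJ).

Finite-difference accuracy caveat: the phantom warps blend to identity over a
thin spherical shell, where the field varies at the stencil scale; voxelwise
1% agreement with the closed form holds wherever the stencil does not cross
the shell, and the per-nucleus mean (the quantity the analysis uses, whose
support is the uniformly scaled core) agrees to well under 1%.

## Microstructure statistics

Tensor metrics from eigenvalues λ1 ≥ λ2 ≥ λ3 ≥ 0: MD = mean, AD = λ1,
RD = (λ2+λ3)/2, FA = √(3/2)·‖λ − MD‖/‖λ‖ (0 for a zero tensor); units are
carried as mm²/s throughout.  All metrics are averaged within each nucleus or
along each pathway.  Group differences use a residualize-then-permute test: a
metric is residualized on the covariates over the pooled sample, the
statistic is the difference of residual group means, and the null comes from
permuting group labels (default 2000 permutations; add-one two-sided p).
BH-FDR is applied within each metric across regions (one family per metric,
matching how such results are reported per metric map); a single global
family is available.  Partial correlation is the Pearson correlation of the
two variables' covariate residuals, with p from the t distribution on
n − n_cov − 2 degrees of freedom.

Covariate choice: DOC duration is 0 for every control by convention, which
makes it nearly collinear with the group indicator; between-group tests
therefore adjust for age and intracranial volume only, while patient-only
analyses (the shape one-sample test and the CRS-R correlations) adjust for
all three.  Residualizing a between-group contrast on a covariate that
encodes the groups would remove the contrast itself.

## Classification

Features are the 7 metrics (FD, FC, FDC, FA, MD, AD, RD) per region under
the chosen parcellation mode — individualized, consensus-template, external
atlas labels, or whole-thalamus means — with volume excluded (population
parcellations would give every subject identical volumes).  The classifier is
L1-regularized logistic regression (liblinear), evaluated by stratified
3-fold cross-validation repeated 20 times.  Standardization parameters and
the penalty strength (selected over C ∈ {0.1, 1, 10} by an inner stratified
split) are fitted on training folds only; a poisoning test asserts held-out
rows never influence the fitted state.  Folds are stratified because with
5-per-class groups unstratified folds can lose a class.  Accuracy is averaged
per fold, then across folds and repeats; the reported spread is the standard
deviation of per-repeat means.  PCA embedding (top 3 components of the
z-scored features, component signs canonicalized) is provided for
visualization.

## Synthetic cohort

The generator emulates the study conditions: 10 healthy controls, 5 MCS and
5 VS patients (matching the cohort sizes of the source study), one
20×24×16-voxel hemisphere at 1.25 mm isotropic, with a box-interior thalamus
mask of 2520 voxels.

* **Nuclei.** Ground-truth nuclei are the k = 7 compact territories of a
  deterministic Ward agglomeration of the mask coordinates — contiguous,
  roughly equal-sized parcels like their anatomical counterparts.  Each
  nucleus has a dominant orientation (one polar direction plus a 45°-polar
  ring; pairwise separation ≥ 20°, guard-checked).
* **FODs.** Per-voxel coefficients are the least-squares projection of a
  Watson-like density exp(κ(μ·u)²), κ = 20, normalized to a spherical
  integral of `amplitude` (default 250 a.u., set once so that
  between-nucleus coefficient distances and β-scaled voxel distances are
  commensurate in the combined metric, which is exactly the role β plays),
  plus iid Gaussian coefficient noise of std `snr`·c00.  The default
  snr = 0.22 puts the between-nucleus class-mean distance at > 3× the mean
  within-nucleus distance.  At that ratio the segmentation recovers the
  ground truth essentially perfectly, so individual partitions barely differ
  across subjects and the pipeline's NMI stage is expectedly quiet; the NMI
  power and calibration tests therefore construct boundary-perturbed
  partition ensembles directly.
* **Pathways.** Five tubes per nucleus (35 total) start at a nucleus voxel
  and leave the mask along +z on globally distinct columns — a stand-in for
  thalamo-cortical tracts (tractography itself is out of scope); tube voxels
  outside the mask carry a z-oriented lobe.
* **Deformations.** Patient warps compose two analytic radial maps
  x → c + λ(r)(x−c): local scale s inside r0 (covering the nucleus), 1
  outside r1, C² quintic blend between, giving the closed form
  log det = log((λ′r+λ)λ²) used as the oracle for the finite-difference
  implementation.  The expanded nucleus (default 6) gets det = volume_effect^sev,
  the shrunk nucleus (default 1) its reciprocal, where sev is a per-subject
  severity (MCS ~ U(0.3,0.6), VS ~ U(0.7,1.0)).  Controls get a small smooth
  sinusoidal jitter field.  Fields are template→subject flows, so planted
  expansion gives positive log-Jacobians.
* **Microstructure effects.** Patient FODs in the designated nuclei and
  their pathways are scaled by 1 − fd_reduction·sev (default fd_reduction
  0.3); pathway tensor eigenvalues are raised by md_increase·sev (default
  0.15).  Tensors are prolate (1.7, 0.45, 0.35)·10⁻³ mm²/s with 2%
  multiplicative jitter, re-sorted.
* **Clinical scores.** CRS-R totals are round(16 − 12·sev + N(0,1)) clipped
  to [0, 23], giving the observed 4–14 patient range, VS < MCS ordering, and
  the study's effect directions: corr(CRS-R, volume change) < 0 and
  corr(CRS-R, FD) > 0.  Ages follow the reported group means/SDs; ICV ~
  N(1.45·10⁶, 1.2·10⁵) mm³; DOC duration ~ U(1.5, 8) months for patients and
  0 for controls.

What the phantoms do **not** emulate: raw DWI signal and scanner noise
spectra, registration error in the warps, spatially correlated FOD noise,
partial-volume and CSF contamination, lesions, or genuinely subject-specific
nucleus shapes (the ground-truth parcellation is shared across subjects, so
individualized and consensus features coincide when segmentation is exact —
the classification comparison can show equality but not the superiority seen
on real patients).  Passing tests demonstrate the correctness and calibration
of the machinery under these idealized conditions, not clinical effect sizes.

## Reproducibility and problem sizes

Every random quantity derives from numpy `SeedSequence` children of one
global seed (generator per subject; one per pipeline stage), so identical
configuration and seed give byte-identical outputs, asserted down to the
serialized summary JSON.  The heavier simulation tests scale the phantom to a
14×16×12 grid (480 mask voxels) and use 200 calibration replicates, 20
recovery seeds, 500 metric permutations and 99–200 NMI permutations — sizes
chosen so the full suite runs in a few minutes on one CPU while the binomial
error bands on calibration rates stay tight enough to be informative.  The
analysis drivers under `analysis/` run the full-size cohort with the default
2000/1000 permutation counts.

## Known limitations

* The unsquared-distance k-means is a heuristic: the mean update is not the
  exact minimizer, so convergence is to a guarded local optimum (verified
  against multi-restart search on small instances).
* The permutation NMI test's power depends on the consensus operator
  responding gradually to group composition; with the co-association
  realization the test is valid but nearly powerless (see above).
* The residualize-then-permute scheme is a Freedman–Lane-style
  simplification; its type-I calibration is verified by simulation.
* FD lobe segmentation by nearest-peak assignment is one published
  convention; others (e.g. watershed on the mesh) would shift FD between
  close fixels.
* The permutation statistic is the difference of residual group means; a
  studentized statistic would weigh heteroscedastic columns differently.
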