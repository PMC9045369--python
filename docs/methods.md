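# Methods

## Scope and model

`petatn` re-creates, on synthetic phantoms, a tau-PET quantification and
biomarker-classification workflow for neurodegenerative dementia: PBB3-PET
(tau), PIB-PET (amyloid-beta) and FDG-PET (glucose metabolism) volumes are
quantified as standardized uptake value ratios (SUVRs) against cerebellar
crus grey matter, amyloid and neurodegeneration statuses are derived from
PET with CSF fallback, subjects are grouped on the A/T*/N scheme
(AD continuum = A+; SNAP = A−N+; biomarker-negative = A−N−), and groups are
compared by nonparametric tests with Cliff's delta effect sizes plus
voxel-wise cluster-extent inference.

The package deliberately replaces upstream steps that need MR imaging and
nonlinear warping (unified segmentation-normalization, SPM "old
normalization") with a much lighter assumption: all volumes live on one
shared template grid, optionally perturbed by a small **rigid**
misalignment which `rigid_register` can undo. Nonlinear anatomy-level
normalization is out of scope by design; the pipeline's science begins at
the normalized-space image.

## Synthetic phantoms

`generate_atlas_phantom` partitions an ellipsoidal brain into 14 cortical
block regions (7 lobes × 2 hemispheres: medial temporal, temporal, frontal,
occipital, parietal, anterior and posterior cingulate) and a left/right
cerebellar reference, on a default 64³ grid of 2 mm voxels. Anatomical
realism is not attempted; what the phantom provides is exact label
bookkeeping, a reference region disjoint from every meta-VOI, and
controllable per-region uptake. The grey-matter probability map is ~0.9
inside labelled tissue (seed-jittered), zero outside.

`generate_cohort` defaults encode the emulated cohort: 7 AD-continuum-like
subjects (first 2 without neurodegeneration, 5 with), 10 SNAP-like, 6
biomarker-negative-like. Per-group regional PBB3 uptake uses the published
per-lobe medians and IQRs (between-subject sd = IQR/1.349); global PIB
load is 2.21 ± 0.25 (A+), 1.30 ± 0.17 (SNAP) and 1.36 ± 0.06 (BN) applied
uniformly over cortex; FDG is 1.0 ± 0.05 cortically with temporal /
parietal / posterior-cingulate suppression to 0.70 ± 0.05 in N+ subjects.
CSF Aβ42 and t-tau are drawn from per-group truncated normals
(499±169/440±230, 1065±588/462±213, 841±218/267±51 ng/L) additionally
conditioned on the subject's true biomarker side of the 600/450 ng/L
cutoffs, so recorded ground truth is always consistent with a recomputation
from the stored values. Modality availability follows the printed per-group
counts (PIB 7/6/4, FDG 4/9/3, CSF 3/4/4), laid out so PET and CSF jointly
cover every subject for both letters.

Image formation is: per-region mean + voxel-wise Gaussian noise
(`noise_sd`, default 0.02 in reference units — the source study does not
report a scan noise level, so this is an exposed free parameter), Gaussian
blur emulating scanner resolution (default 4 mm FWHM, roughly the
post-reconstruction PSF of a modern PET/CT), then optional rigid
misalignment. What the phantoms do **not** emulate: partial-volume effects,
scatter/randoms, anatomical variability, nonlinear deformation, white
matter or off-target binding. Tests passing on these phantoms therefore
validate the *computational* pipeline — label accounting, scaling,
statistics, calibration — not robustness to real-scan physics.

## Spatial operations

* Smoothing: isotropic Gaussian with σ = FWHM/√(8 ln 2) in mm, converted
  per-axis to voxels via the (axis-aligned) affine; reflect boundaries to
  avoid edge dimming. Sheared affines are rejected rather than silently
  mishandled.
* Templates: each input is divided by its grey-matter-masked reference
  median and the scaled volumes averaged voxel-wise; a sidecar JSON records
  the source subjects and scaling medians.
* Slice-wise NCC: per axial slice, the 1/n population-σ cross-correlation
  over in-mask pixels — exactly the Pearson correlation of those pixels
  (verified against an independent per-slice oracle to 1e−9). Slices with
  fewer than `min_voxels` (default 50) in-mask pixels or zero variance are
  excluded and counted. How per-slice values combine into the single
  selection criterion is not specified by the adaptive-template literature
  we follow; we use the unweighted mean over usable slices. Whether a brain
  mask was used upstream is likewise unstated; masked computation is the
  default and unmasked is available.
* Adaptive selection: argmax of aggregate NCC over the positive/negative
  template pair; exact ties resolve to *negative* so an uninformative image
  can never inflate amyloid-positive calls.
* Rigid registration: 6-parameter (mm, degrees about the fixed-grid centre)
  Powell maximization of normalized correlation after 8 mm pre-smoothing of
  both inputs, linear resampling, zero fill. On study-scale 64³ phantoms it
  recovers 4 mm / 5° perturbations to ≲0.1 mm / 0.1°. On much smaller grids
  the rotation signal can fall below the interpolation-blur asymmetry of
  the resampler, so registration accuracy is specified (and tested) at the
  64³ default scale.

## SUVR quantification

VOI value = median over voxels with label in the VOI and grey-matter
probability ≥ `gm_threshold` (default 0.5 — the source method says
"grey-matter-masked" without a number). SUVR = VOI median / reference
median; even-count medians use the midpoint convention. The global SUVR is
the volume-weighted mean over meta-VOIs; the amyloid composite (frontal,
posterior cingulate/precuneus, anterior cingulate, superior parietal,
lateral temporal) and the tau global (all seven meta-VOIs) are distinct
configurations. The meta-VOI → region-id table is plain data so a real
labelled atlas can be substituted without code changes.

## Classification

* CSF: A+ iff Aβ42 < 600 ng/L, N+ iff t-tau > 450 ng/L, both strict;
  values within ±10% of a cutoff are flagged as borderline for audit.
* Amyloid PET: ROC over global PIB SUVR with candidate thresholds at
  midpoints between consecutive unique scores (± ∞), rule
  `score ≥ threshold → positive`; the cutoff maximizes Youden's J, ties
  resolving to the lowest threshold (favours sensitivity,
  deterministic). AUC is the trapezoidal ROC area, which equals the
  Mann–Whitney statistic with half-credit ties. LOOCV refits the cutoff on
  each n−1 subset; a single-class fold falls back to the full-data cutoff
  with a logged warning. In the pipeline, the adaptive-template selection
  plays the role of the scan-level visual read used as the ROC gold
  standard. The classification direction exactly at the cutoff is not
  fixed by the emulated method; `≥ → positive` is chosen and configurable.
* FDG single subject: per-voxel OLS on ≥20 controls with intercept,
  centred age and binary sex; the patient's studentized prediction
  residual is tested two-sided with df = n−3 and Bonferroni correction
  over in-mask voxels (a deliberately conservative, dependency-free stand-in
  for random-field FWE). Hypometabolic (patient < predicted) surviving
  voxels are 26-connected-component labelled; a component of ≥ `k_min`
  (default 100) voxels intersecting the user-supplied susceptible-region
  mask yields N+. The susceptible regions default, in the pipeline, to the
  lobes the generator suppresses, mirroring the "typical VOIs" notion.
* Grouping: A+ → AD continuum; A−N+ → SNAP; A−N− → biomarker-negative; a
  missing letter → unclassifiable. When PET and CSF both inform a letter,
  PET wins and the disagreement is logged and flagged.

## Group statistics

Atlas-based: per meta-VOI, Kruskal–Wallis omnibus (the concrete reading of
"nonparametric one-way ANOVA") then pairwise two-sided Mann–Whitney tests,
Bonferroni-multiplied by the number of pairwise contrasts *within* the VOI
(whether the correction should also span VOIs is ambiguous; per-VOI is the
default). Cliff's delta = P(x>y) − P(x<y) with bands |δ|<0.33 small,
0.33–0.47 medium, >0.47 large.

Voxel-wise: Welch t with per-voxel Satterthwaite df (consistent with the
unequal-variance choice; zero-variance voxels get t = 0 and a flag),
two-tailed voxel threshold p < 0.01 in the A>B direction, 26-connectivity
clusters (configurable to 6/18). Cluster-level FWE uses the
max-cluster-size permutation null over random group relabelings — complete
enumeration when fewer distinct relabelings exist than requested
permutations — with the add-one p-value convention
p = (1+#{perm max ≥ k})/(1+n_perm), which stays valid at finite permutation
counts; clusters must additionally exceed k > 100 voxels. Per-subject
cluster summaries use the median over cluster voxels, matching the
median-based VOI statistic.

## Problem sizes and numerical choices

Defaults: 64³ grid / 2 mm voxels, 23 subjects, 24 FDG controls, 1000
permutations. The test suite exercises reduced sizes it states explicitly
(16³–48³ grids, 100–400 permutations, 100–1000 simulation replicates),
chosen as the smallest scales at which each statistical property is
identifiable. All randomness descends from explicit integer seeds
(`numpy.random.default_rng` / `SeedSequence`); reruns are byte-identical.
Degenerate inputs (single-class ROC input, empty VOIs, non-positive
reference medians, singular affines, non-finite voxels) raise typed errors
rather than propagating NaNs.

## Known limitations

* No nonlinear registration: anatomically misshapen inputs are out of
  scope; only rigid perturbations are recoverable.
* Bonferroni voxel-level FWE in the FDG test is conservative relative to
  random-field or permutation voxel-level control; borderline deficits can
  be missed (observed occasionally on marginal synthetic subjects).
* No partial-volume correction or kinetic modelling; SUVR is treated as
  the terminal quantitative unit.
* No T-biomarker threshold exists in the emulated scheme (groups are T*),
  so tau positivity is never classified.
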