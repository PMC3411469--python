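# Methods

`lvremodel` maps where the left-ventricular (LV) wall dilates after a
reperfused myocardial infarction by co-registering 3D cardiac MR volumes
acquired at baseline and follow-up, and relates that local remodeling to the
transmural extent of infarction and to microvascular obstruction (MVO).
Because patient images from such studies are not publicly deposited, the
package ships a synthetic phantom generator with exact ground truth; every
stage is validated against it.

## Imaging model and phantom

All volumes are axis-aligned scalar grids with anisotropic voxel spacing in
mm (`Volume3D`); geometry lives in world millimetres and NIfTI-1 is the
interchange format (rotated/sheared affines are rejected on read).

The phantom LV is a truncated-ellipsoid myocardial shell (default endocardial
semi-axes 22/22/40 mm, epicardial 30/30/48 mm, basal cut 24 mm above center,
wall ≈ 8 mm) between blood pool and background, with a simple lateral RV
pool.  Intensities are class means plus additive Gaussian noise:

* structural ("cine") volume — background 20, LV blood 140, LV wall 80, RV
  blood 130, noise σ = 12 (20 % of the wall/blood contrast).  Additive
  Gaussian noise approximates magnitude-MR Rician noise at these SNRs and
  keeps Gaussian-mixture recovery exact.
* LGE volume — remote wall 60, enhancing infarct 160, σ = 20.
* early-enhancement volume — remote wall 60, enhancing infarct 110, MVO core
  20, σ = 10.

The infarct occupies an angular sector (default 60°, raised-cosine taper
15°) over a long-axis slab, growing from the endocardium outward to a
transmural fraction f ∈ [0, 1] (sub-endocardial infarcts are the clinically
expected pattern).  The optional MVO core is the innermost quantile of the
infarct's radial coordinate, so its voxel count is an exact fraction of the
infarct.  The follow-up volume applies a known smooth radial expansion about
the LV long axis — magnitude (s−1)·(distance from the axis) at the sector
center, raised-cosine tapered to zero at the angular and long-axis sector
edges — by inverse resampling of the noise-free baseline (forward field at
baseline voxel centers is therefore exactly the stored truth), with an
independent noise draw.  All generators are bit-reproducible under a seed.

The phantom grid defaults to 64³ voxels at 1.8 × 1.8 × 2.4 mm.  True 8 mm
CMR slices would undersample the analytic shell used by the geometric
oracles; the mild through-plane anisotropy retains the feature the code must
handle without degrading the ground truth.

What the phantom does *not* emulate: trabeculation and papillary muscles,
through-plane motion, intensity bias fields, inter-sequence misalignment
beyond rigid offsets, and — importantly — intramyocardial texture.  A real
myocardium carries intensity features that help registration pin motion
*along* the wall; the phantom wall is homogeneous, so tangential motion is
fundamentally unobservable in it (see Registration).  Passing tests on the
phantom therefore validate the machinery and its calibration, not clinical
accuracy.

## Registration

Similarity is Studholme's normalized mutual information,
NMI = (H(A)+H(B))/H(A,B) ∈ [1, 2], from a joint histogram (64 bins default
for the standalone metric, 32 in the registration drivers) binned linearly
between the 1st–99th masked intensity percentiles, with out-of-domain
samples excluded.

**Rigid/affine** registration uses SimpleITK's multi-resolution framework
(Mattes mutual information, regular deterministic sampling with a fixed
seed, ITK pinned to one thread for bit-reproducibility).  The result is
reduced to a plain 4×4 matrix; rigid results are re-orthonormalized.  A
returned transform never has lower masked NMI than the identity
initialization — otherwise the identity is returned and flagged.

**Free-form deformation** is a cubic B-spline displacement lattice
(`FFDTransform`), evaluated exactly from the 4×4×4 surrounding control
coefficients; with an affine prealignment A the full map is
T(x) = A(x + u(x)).  The optimizer is an in-package deterministic
Gauss-Seidel coordinate search, coarse-to-fine: the lattice starts at
2^(levels−1) times the final control spacing (default final spacing 18 mm,
3 levels) and is refined between levels by exact dyadic B-spline
subdivision while the fixed image moves down a matching pyramid.  Candidate
moves of one control-point component (initial step 1.5 voxels, halved when a
sweep accepts nothing, floor 0.1 mm) are scored by the exact change in NMI —
maintained incrementally on the joint histogram — minus a bending-energy
penalty (axis-wise squared second differences of the coefficients divided by
the control spacing; weight 5·10⁻⁴).  Only improving moves are accepted.

This greedy design is deliberate: deformation modes the intensities cannot
constrain (e.g. motion along a homogeneous band — the aperture problem) are
never rewarded and hence never introduced, which matters directly for the
differential remodeling statistic.  Three robustness rules were found
necessary: pyramid levels with too few masked voxels for a stable joint
histogram are skipped; the no-worse-than-initialization guarantee keeps the
best transform across the level hierarchy; caches are re-synchronized to the
exact B-spline after every sweep.

**Longitudinal guidance.** The baseline and follow-up volumes are first
rigidly aligned on whole-image intensity.  The FFD then runs between the
*segmentations*: EM-denoised images (per-voxel posterior-weighted class
means, smoothed by 1 voxel), restricted to a 3-voxel dilation of the
myocardium.  On raw noisy intensities the optimizer can climb noise —
tangential moves inside the homogeneous wall are intensity-neutral except
for the noise they resample — which corrupts 1-ring distances; denoised
guidance removes that channel.  Raw-intensity registration remains available
(`registration.segmentation_guided: false`).

## Segmentation

The probabilistic atlas holds four co-registered probability fields
(background, LV blood, LV wall, RV blood) plus an intensity template; the
synthetic atlas is the blurred (σ = 1 voxel) indicator set of a reference
phantom.  Atlas-to-target alignment registers the template (affine, with an
optional FFD stage; the default cohort configuration uses affine only, since
phantom subjects differ from the template by a similarity transform plus the
infarct).  Warped probabilities are renormalized per voxel.

EM segmentation alternates posteriors ∝ prior·N(I; μ_k, σ_k²) with
posterior-weighted mean/variance updates; priors carry the mixing role, so
no separate weights are estimated when an atlas is present.  Initialization
is prior-weighted statistics; variances are floored at 10⁻⁶ of the squared
intensity range; zero-prior classes are dropped with a warning; the
log-likelihood is non-decreasing; ties in the hard argmax go to the lowest
class code.  With a uniform prior the routine degenerates to a plain
Gaussian-mixture classifier (quantile-split initialization, learned
weights), which matches the infarct GMM fitter on shared 1D data.

Segmentation accuracy can be scored against reference surfaces by the
symmetric mean vertex-to-surface distance (exact point-triangle distances
with a KD-tree candidate search).

## Infarct quantification

LGE intensities within the myocardium are fitted with a two-component 1D
Gaussian mixture (median-split initialization, variance floor, monotone
log-likelihood); the higher-mean component is the enhancing (infarcted)
distribution and a voxel is infarct when its enhancing posterior exceeds
0.5 (ties conservative).  A unimodality warning is set when the components
are not meaningfully separated (means closer than 0.1 pooled SD, or
Ashman's D < 2).

Transmural extent at each epicardial vertex is the fraction of
infarct-positive among wall-positive samples on the segment to its nearest
endocardial vertex (32 samples; the same construction as wall thickness);
lines without wall-positive samples are flagged undefined.  MVO is detected
on the aligned early-enhancement volume as infarct voxels below
(remote mean − 2 SD), keeping connected components of at least 0.1 ml.
Infarct size is the infarct/myocardium volume ratio in percent.

## Meshes and the remodeling statistic

Endocardial and epicardial surfaces are 0.5-level marching-cubes
iso-surfaces of the smoothed blood-pool and blood+wall indicators (padded so
surfaces close), cleaned (merged vertices, degenerate faces removed, largest
component kept).  Mesh coarsening, when wanted, is done via the
marching-cubes step size.  Wall thickness at an epicardial vertex is the
distance to the nearest endocardial vertex.

Local remodeling at vertex v is the percentage change of the mean 1-ring
neighbor separation under the longitudinal transform:
d₀(v) = mean‖x_v − x_u‖ over neighbors u, d₁(v) the same after mapping both
endpoints, remodeling(v) = 100·(d₁−d₀)/d₀.  By construction it is exactly
100·(s−1) under a global similarity of ratio s, exactly 0 under rigid
motion, and never reads the infarct segmentation — so it is independent of
infarct size.  It is computed on the epicardial mesh (the rendered surface
of choice); the endocardial mesh can be substituted.  Vertices are labelled
infarct when transmural extent exceeds a threshold (default 0, i.e. any
infarct along the wall line), remote at zero extent, undefined where the
extent is undefined.

## Cohort pipeline and statistics

Per subject: atlas → EM segmentation of the baseline; surfaces and wall
thickness; LGE rigidly aligned to the baseline stack → GMM infarct →
transmural extent; early enhancement aligned → MVO; follow-up rigidly
aligned → EM segmentation → segmentation-guided FFD → remodeling map.
End-diastolic volume and mass are reported both by voxel counting
(blood-pool volume; wall volume × 1.05 g/ml) and, for the follow-up time
point, from the closed endo/epicardial meshes mapped through the recovered
transform — the stored EDV pair and the >20 % global-remodeling flag use the
mesh-based volumes of both time points so the comparison is internally
consistent.  Failed subjects are marked and excluded from cohort statistics;
the CLI exits nonzero if more than 20 % fail.

Cohort statistics mirror the study design: a paired two-tailed t-test of
infarct- vs remote-region mean remodeling (pairing is a package choice — each
subject contributes both regional means), Welch t-tests of infarct remodeling
by MVO status and by global-remodeling status, and a one-way ANOVA of
remodeling across transmural-extent bins (default edges 0, 0.25, 0.5, 0.75,
1.0 plus an extent-0 group; the 0.5 boundary is where wall dilatation is
expected to appear).  The ANOVA pools per-vertex values across subjects —
the per-vertex map is the unit of the transmurality analysis — while
per-subject bin means are kept in the per-subject results.  Results are reported as
mean ± SE with the 95 % CI of the difference and two-tailed P; α = 0.05; no
multiple-testing correction.  Degenerate inputs (zero variance, empty bins)
have defined outcomes rather than NaNs.

The default synthetic cohort has 20 subjects in two arms: sector expansion
s = 1.12 with an MVO core versus s = 1.02 without, with per-subject jitter
of the geometry (±8 %), sector orientation (uniform), transmural fraction
(0.3–1.0) and all noise draws.

## Calibration and its reductions

Type-I-error calibration of the cohort statistic runs the
registration-through-statistic chain on null subjects (s = 1: the follow-up
differs from baseline only by a fresh noise draw) and measures how often the
paired infarct-vs-remote test rejects at α = 0.05.  To fit a test-suite
budget this uses reduced conditions: a 36³ grid, the reference-geometry atlas used
directly as the spatial prior (no atlas registration step), the ground-truth
infarct mask in place of the GMM stage, and 200 cohorts of 8 subsampled from
a pool of 64 independent null subjects.  The rate estimator is unbiased for the
per-cohort rejection probability, but cohort overlap inflates its
variance relative to 200 fully independent cohorts, so the tolerance band
(5 % ± 3 %) absorbs both binomial and pooling noise.

## Known limitations

* Tangential (along-wall) motion is unobservable in the homogeneous phantom
  wall; the recovered differential remodeling is attenuated relative to the
  generator's true field (the statistic's *direction* and ordering across
  effect sizes are what the tests assert).
* The EM segmenter has no Markov-random-field smoothing or bias-field
  correction; the GMM infarct rule is the posterior-0.5 cut without
  morphological cleanup.
* The FFD carries no diffeomorphism guarantee; foldover is discouraged only
  by the bending penalty and greedy NMI acceptance.
* Global indices at follow-up derive from meshes mapped through the
  recovered transform rather than an independent follow-up segmentation.
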