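# Methods

This note documents the models and numerical choices behind `pvsq`,
the assumptions they rest on, and what the synthetic test surface does
and does not demonstrate about real data.

## Imaging pipeline

### Intensity normalization

T1-weighted volumes from different sessions differ by an overall
intensity scale (coil loading, scanner calibration, head position).
Because the PVS segmentation applies one fixed vesselness threshold to
every exam, each volume is first rescaled multiplicatively so that the
white-matter mean equals 110 — a conventional WM reference value for
T1w intensity normalization. Two estimators of the WM mean are
offered:

- `mask_mean` (default): the plain mean inside the supplied WM mask.
  The pipeline assumes a curated WM mask is an input, so this is the
  most direct estimator.
- `fcm`: the mean of voxels hard-assigned to the brightest cluster of
  a 1-D fuzzy c-means clustering (k = 3 for CSF/GM/WM-like classes,
  fuzziness m = 2, tolerance 1e−5 on memberships, ≤ 100 iterations,
  k-means++-style seeded initialization). This mode mimics FCM-based
  normalizers when masks are broad or unedited. The FCM fixed point is
  the standard one: means are membership^m-weighted averages,
  memberships follow inverse-distance weighting with exponent
  2/(m−1).

Normalization is multiplicative only (no offset), which makes the
whole downstream pipeline exactly invariant to a global intensity
factor — a property the test suite asserts voxel-for-voxel. Applying
it twice is a no-op within floating-point rounding.

### Hessian and vesselness

The Frangi vesselness at scale σ uses the γ-normalized Hessian of the
scale-space volume. The discretization is Gaussian smoothing at
σ (per-axis, in voxel units σ/spacing) followed by central
differences: [1, −2, 1] for pure second derivatives and the 3×3 cross
stencil for mixed ones, multiplied by σᵢσⱼ (voxel units), which equals
the mm-unit derivative times σ². This operator is exact on quadratics
and agrees with a brute-force finite-difference computation of the
smoothed volume to machine precision, which is how the implementation
is validated. Boundary handling is reflect-mode; when a region of
interest is supplied, the convolutions still see the full image (the
filter support extends past the mask) and the output is zeroed outside
the ROI; masking the image before filtering is available as an option.

Eigenvalues of the per-voxel symmetric 3×3 Hessian are obtained by a
batched symmetric eigensolver and sorted by absolute value. The
vesselness functional uses α = β = 0.5 and c = 2 with the dark-tube
polarity condition λ₂ > 0 ∧ λ₃ > 0; a voxel with λ₃ = 0 has no
structure and scores 0. c = 2 is interpreted on the normalized
intensity scale (WM ≈ 110), which is the reason normalization precedes
filtering. The dark-tube rule is algebraically identical to running
the bright-tube rule on the negated image (the Hessian is linear), and
the tests assert the two paths agree exactly.

**Scale set.** The default is {0.6, 0.7} mm on a 1 mm grid, chosen by
calibration on tube phantoms with known ground truth — the same
parameter-tuning-by-inspection procedure a practitioner would use on
pilot exams. Larger scale sets (e.g. adding 1.0–1.5 mm) detect the
same tubes but their response halo at the fixed 0.05 threshold inflates
the segmented volume roughly two-fold, and σ = 0.5 with the
central-difference kernel is hypersensitive to single-voxel noise
dips. The set is configurable; anyone interested in PVS calibers above
~1.5 mm radius should extend it and recalibrate.

**A caveat on blobs.** The blobness ratio R_B suppresses spherical
structures only near their centers. The inflection shell of a dark
sphere has eigenvalues ≈ (0, c, c) — locally indistinguishable from a
tube — so a large hypointense blob produces a tube-like ring response.
This is inherent to Hessian shape analysis, not an implementation
artifact; in the pipeline such structures are removed by the
150-voxel size cap instead.

### Segmentation and quantification

Candidate voxels are those inside the WM mask with vesselness
strictly greater than 0.05. Connected components are labeled at
26-connectivity (permissive, avoids fragmenting thin oblique tubes;
configurable to 18 or 6). Components with fewer than 5 voxels are
removed as noise islands; components with more than 150 voxels are
removed whole, the rationale being that catheters and confluent WM
hypointensities are objects, not PVS. "Morphological clean-up" is
exactly these two size filters; no opening/closing is applied by
default. Size bounds are counted in voxels on the native grid (the
method is defined on 1 mm isotropic data; a warning is emitted
otherwise). The component table records every candidate component with
voxel count, centroid, and retained/rejection status, so filter
behavior is auditable per exam.

PVS volume is the retained voxel count × voxel volume (cm³); the PVS
ratio is 1000 × PVS volume / WM volume (‰). The identity
`ratio = 1000·volume/wm_volume` is exact by construction.

## Synthetic data

### Tube phantoms

The phantom emulates the features of a T1w exam that the pipeline is
sensitive to, not anatomy: a bright WM compartment (thick-shelled
ellipsoid, outer semi-axes 0.84 and inner cavity 0.25 of the
half-grid; the cavity is CSF-dark), dark tubes with piecewise-linear
mildly-curved centerlines (≤ 25° bend per segment) rasterized by
distance-to-centerline, a 0.5-voxel Gaussian point-spread blur,
additive white Gaussian noise, and a global intensity scale factor.
Defaults: 64³ grid at 1 mm, 12 tubes of radius 0.8–1.2 mm and length
8–20 mm, WM 150 / PVS 55 / background 10 raw intensity, noise SD 1.5.

The noise default corresponds to a WM SNR of ~100 (≈1.6% of the
WM–PVS contrast). This is the regime in which a fixed 0.05 vesselness
threshold operates with negligible false-positive load — the regime
the reference parameters presuppose: at noise SD ≥ 2 the γ-normalized
Hessian of white voxel noise alone produces hundreds of ≥5-voxel
supra-threshold clusters per 64³ volume, and no plausible PVS burden
could be measured at ~10‰ under those conditions. Real scanner noise
is additionally band-limited by reconstruction filtering, which the
white-noise phantom does not model; Rician noise is available behind a
flag.

Confounders, each with an exact ground-truth mask disjoint from the
PVS mask:

- **catheter**: one near-straight tube of radius 2.2–2.5 mm and length
  14–20 mm (> 150 voxels — removed by the size cap);
- **hypointense blobs**: two patches of radius 3.6–4.5 mm (> 150
  voxels, emulating confluent WM hypointensity);
- **speckle islands**: ~25 one-to-two-voxel dips of depth 4 (≈2.7
  noise SD) applied after the blur — the "noise islands" the <5-voxel
  rule exists to remove. Deeper or full-contrast speckles would
  nucleate genuine ≥5-voxel detections, which the size rule by design
  retains; they are kept ≥5 voxels away from tubes and blobs so a
  speckle can never merge with the detection halo of a real structure.

Tubes are placed with a margin inside the WM (distance transform >
radius + 0.6 voxels) and kept ≥2 dilation steps apart so ground-truth
components stay countable. A tube radius that cannot fit in the shell
raises a geometry error. Everything is driven by one integer seed and
is bit-reproducible; the global scale multiplies the final volume, so
scale equivariance is exact.

What phantom tests do **not** show: performance on real anatomy
(curved cortical ribbons, basal ganglia, partial-volume CSF),
bias fields, motion, or registration error. They validate the
algorithmic chain — normalization invariance, tube enhancement,
size-filter behavior, volume arithmetic — against exact ground truth.

### Cohort simulation

`generate_cohort` simulates per-exam tables with the additive
fixed-effect structure of the full model: per-time-point offsets,
anesthesia, shunt, sex, age slope, dose offsets, a per-patient random
intercept (SD 1.5‰) and residual noise (SD 1.0‰). Defaults encode
the developing study's conditions: 241 patients; retention
210/209/198/161 per time point as per-TP dropout probabilities;
TP means ≈ 9.8/10.3/8.6/9.3‰; anesthesia −0.5‰, shunt −1.1‰,
male +0.6‰, age slope 0.18‰/yr; dose offsets (RD baseline)
SD +0.3, HD −0.4‰. Baseline age is 3.3 + Gamma(2.2, 3.2) years
(mean ≈ 10.3, reference age for the intercept), advancing
0.25/0.75/0.5–0.75 years along the 0M→3M→12M→FollowUp calendar.
Anesthesia is drawn per exam (58%), shunt per patient (25%), sex 62%
male, dose 12/41/47% RD/SD/HD — all independent.

The PVS-volume response shares the linear predictor scaled by 0.55
with its own intercept (4.7 cm³) and age slope (0.14 cm³/yr), so the
two responses are correlated within an exam.

Limitations of the design: covariates are mutually independent,
whereas in real cohorts anesthesia correlates strongly with age; there
is no dose-by-period interaction, so per-dose differences in paired
deltas are not simulated; and the volume response is a scaled copy of
the ratio predictor, so divergences between ratio and volume trends
(e.g. from WM-volume growth) are not reproduced.

## Statistics

The full model is a linear mixed model with the six fixed effects
(TP and dose unordered categoricals with baselines 0M and RD; age
continuous; sex, anesthesia, shunt binary) and a per-patient random
intercept, estimated by REML (statsmodels MixedLM; gradient-based
optimization with a derivative-free Powell fallback when the
random-intercept variance sits on the zero boundary). Fixed-effect
tests and confidence intervals are large-sample Wald z statistics —
no small-sample degrees-of-freedom correction is applied, and the fit
object records this. With ~200 patients the 95% intervals achieve
nominal coverage in simulation. When the pooled OLS fit is numerically
exact (zero residual variance), the REML objective is degenerate and
the model returns the OLS coefficients with zero variances — this is
the correct limit, not an approximation.

Pairwise contrasts are Wald tests on linear combinations of the fixed
effects, Bonferroni-adjusted within each declared family: the 6 TP
pairs, the 3 dose pairs, and singleton families for anesthesia, shunt
and sex (p_adj = min(1, m·p)). The paired model applies no
multiplicity adjustment.

Paired deltas are built per patient for the consecutive periods
(0M,3M), (3M,12M), (12M,FollowUp), requiring both exams, both
measurements, and matching anesthesia and shunt flags; delta = later −
earlier. Each period × dose cell is tested against zero with a
two-sided one-sample t-test (cells with n < 2 or zero SD are reported
untestable); dose levels are compared within a period by one-way
ANOVA.

The QC rule flags values with |x − mean| > k·SD (sample SD, default
k = 2) and draws a seeded random sample of 20 in-range indices for
manual review. A constant input has SD 0 and flags nothing.

## Numerical and reproducibility choices

- Threshold comparison is strict (> 0.05); size bounds are inclusive
  (5 and 150 voxels are retained).
- Component labels are assigned in scan order of each component's
  first voxel, so component tables are deterministic.
- All randomness flows from integer seeds through
  `numpy.random.default_rng`; identical configuration + seed gives
  byte-identical measurement CSVs and statistics reports, which the
  test suite checks.
- Problem sizes used by the validation scripts — 64³ phantoms, batches
  of 20, cohorts of 200–241 patients, 100 replicate fits — were chosen
  to estimate each quantity well inside its acceptance band while a
  full run stays in the minutes range on one CPU.
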