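# Methods

## Problem and model

In ultrasound-guided prostate radiotherapy a transperineal 3D ultrasound
scan is acquired at simulation and the prostate is contoured, yielding a
reference positioning volume (RPV). Before each treatment fraction a guide
scan is acquired with the probe in the same position; the prostate has
moved by an unknown interfraction displacement, corrected with a couch
shift. `echomatch` estimates that displacement as a pure translation
`d = (d_LR, d_AP, d_SI)` in mm on patient axes, with the convention that
`d` maps the RPV position onto the prostate position in the guide scan
(GPV = RPV + d); the couch correction is `-d`. Rotations and deformations
are out of scope by design: couch corrections are translations and the
clinical comparator software quantifies none either.

## The matcher

The similarity is a *masked* (weighted) normalized cross-correlation: the
reference is cropped to the RPV bounding box, the binary contour becomes a
weight map `w`, and for each candidate integer displacement `d`

    NCC(d) = Σ w (T − T̄)(G_d − Ḡ_d) / sqrt( Σ w (T − T̄)² · Σ w (G_d − Ḡ_d)² )

with `T̄`, `Ḡ_d` the `w`-weighted means. Weighting by the anatomical
contour rather than its bounding rectangle keeps periprostatic structures
(bladder, rectum gas) from dominating the score; NCC itself is invariant
to positive affine intensity maps, absorbing gain and offset differences
between scan days. The score volume over the displacement lattice is
evaluated with three FFT cross-correlations (of the guide with `w`,
`w·(T − T̄)`, and of the squared guide with `w`), so the full correlation
map costs a handful of FFTs regardless of lattice size. Guide patches with
zero weighted variance receive a `-inf` sentinel and are excluded.

Two search modes exist. *Automated*: the lattice spans `±max_shift_mm`
(default 15 mm) around zero displacement. *Semi-automated*: the user marks
the approximate prostate location with a template-sized rectangular
window, which is expanded by `window_margin_vox` (default 15) voxels on
each side; the lattice holds every displacement keeping the template
inside it. The margin is applied per side: a review window must enclose
plausible ±8 mm interfraction motion, which a split (7.5-voxel) margin
would not at 0.55 mm voxels. Both lattices are clipped to displacements
keeping the template inside the guide, retaining zero when feasible.

### Regularization

Raw correlation maps from feature-poor or decorrelated scans can carry
spurious distant maxima. The matcher therefore maximizes

    R(d) = (K_σ ∗ NCC)(d) − λ · ‖d − d₀‖²

where `K_σ` is a Gaussian kernel over the displacement lattice
(`smooth_sigma_vox`, default 1.0 lattice voxels), `λ` (`lambda_reg`,
default 1e-3 per mm²) is a quadratic penalty pulling the peak toward the
search-region centre `d₀` (zero displacement in automated mode, the window
centre in semi-automated mode), and distances are in mm. Both default
weights are deliberately gentle: at 5 mm the penalty costs 0.025
correlation units. `λ = σ = 0` recovers the plain argmax exactly, which is
how the matcher is validated against an exhaustive brute-force oracle. The
peak distance `‖d*(λ) − d₀‖` is non-increasing in `λ` (a pairwise-
optimality argument), a property the tests sweep explicitly.

### Peak selection and subvoxel refinement

The integer peak is the global argmax of `R`, with ties broken by the
smallest Euclidean displacement norm and then lexicographically on
(LR, AP, SI), so results are deterministic on degenerate surfaces. A peak
touching the lattice boundary raises an `edge_peak` flag. Subvoxel
precision comes from an independent per-axis parabola through the peak and
its two neighbours, `δ = (c₋₁ − c₊₁) / (2(c₋₁ − 2c₀ + c₊₁))`, clamped to
±0.5 voxel, with `δ = 0` and a flag on zero-curvature axes. The parabola
is fitted on the *raw* correlation surface, not on the regularized cost:
the smoothing kernel stabilizes which integer peak is chosen but flattens
and skews local curvature, and fitting on the unsmoothed surface reduces
the worst-case subvoxel error on noiseless phantoms from ~0.3 to ~0.06
voxel. The reported peak score is the raw NCC re-evaluated directly at the
integer peak (so a self-match scores exactly 1.0); a score below
`low_score_threshold` (default 0.4, configurable — a review aid, not a
clinical claim) raises a `low_score` flag.

Numerical notes: lattice scores are clipped to [−1, 1] against FFT
round-off; degenerate-variance patches are detected with a relative
(1e-12-scaled) threshold; template/guide grids must share spacing and be
axis-aligned (world = origin + index · spacing, no rotations).

## Synthetic phantoms

No imaging data are deposited, so the package carries a first-class
phantom generator emulating transperineal 3D ultrasound at 0.55 mm
isotropic voxels (the voxel scale implied by reporting 1.1 mm as
"2 pixels").

*Speckle.* Fully developed speckle is the envelope `sqrt(I² + Q²)` of two
independent low-pass-filtered unit-variance Gaussian fields — an I/Q
analogue whose amplitude is exactly Rayleigh distributed, the defining
statistic of fully developed speckle. Gaussian point-spread sigmas
(default (0.6, 0.8, 0.8) mm) set the speckle correlation length per axis.
A 100-seed Kolmogorov–Smirnov batch against the Rayleigh law (on
stride-decimated voxels, to break spatial correlation) passes at α = 0.01
for ≥ 95% of seeds.

*Anatomy.* The prostate is a hypoechoic ellipsoid (echogenicity 0.6
against background 1.0 — typical transperineal appearance) with default
semi-axes (22, 18, 20) mm (≈ 33 cc) and a ~1 mm soft capsule edge; the RPV
mask is the rasterized ellipsoid (voxelized volume within 5% of the
analytic value). Up to five bright Gaussian blobs (σ 0.8 mm, amplitude 3×
the background envelope RMS) stand in for prostatic calcifications; they
are placed uniformly at random strictly inside the ellipsoid with ≥ 4 mm
pairwise separation and rendered analytically, so they sit at exact
subvoxel positions.

*Interfraction motion.* Guide scans are built from the retained
pre-envelope I/Q pair: the fields are rigidly translated (linear
interpolation for subvoxel shifts), blended with fresh fields as
`ρ·old + sqrt(1 − ρ²)·new` (variance-preserving; `ρ` is the retained
speckle fraction), re-enveloped under the echogenicity map at the shifted
prostate position, landmarks are re-rendered at their exactly shifted
positions, and a gain/offset map `a·x + b` is applied last. The stored
ground truth equals the requested shift by construction, and noiseless
landmark matching reproduces it to < 1e-9 mm.

*Cohorts.* `generate_cohort` reproduces the study structure — one
reference plus `n_fractions` guides per patient, per-axis zero-mean normal
shifts (default SD 3 mm, truncated at ±10 mm), patient-level (never
fraction-level) train/test partition, and deterministic seed fan-out via
`numpy` SeedSequence so identical seeds give bit-identical cohorts. At the
study design (32 patients × 5 fractions, 20 training patients) this yields
160 pairs split 100/60.

What the phantom does *not* emulate: sector-scan geometry, attenuation and
shadowing, refraction, deformable anatomy, bladder/rectal filling changes.
Passing tests therefore demonstrate algorithmic correctness and noise
robustness under a controlled speckle model, not clinical performance on
patient scans.

## Gold standard and workflows

A landmark match is the arithmetic mean shift over 1–5 landmark pairs; the
gold standard is the mean of three observers' landmark matches, with a
repeat round (at most two, three rounds total) requested whenever the
interobserver difference exceeds 5 mm. "Interobserver difference" is read
as the maximum per-axis absolute pairwise difference, consistent with
per-axis reporting throughout; the mean of the *final* round (not pooled
rounds) defines the result, the conservative reading of "repeated".
Simulated observers perturb guide-side landmark positions only (reference
landmarks are contour-time annotations), with per-axis normal noise
defaulting to (0.8, 0.7, 0.7) mm — the published landmark-match error
spread, used as a calibration input.

The *Full* workflow reviews an automated match, falls back to a
semi-automated match on rejection, then to a manual match in the vendor
review software; the *Manually Initiated* workflow skips the automated
step. The manual stage is a human with a GUI and cannot be re-implemented;
it is modelled as the gold standard plus seeded per-axis normal noise with
SDs (2.1, 2.1, 1.8) mm, calibrated to the published manual-matching error
spread — preserving the statistical role of the fallback without claiming
to reproduce human matching. Reviewers are simulated either with
per-method Bernoulli rejection probabilities (the published rejection
rates are calibration inputs, not test targets) or, by default,
deterministically (reject on `low_score` or `edge_peak`). Review times
draw from per-method triangular distributions; the semi-automated and
manual triangles follow the published workflow-time rows, the automated
one is a configuration default. Wall-clock match times are
hardware-dependent and excluded from serialized outputs, which keeps a
pipeline run byte-reproducible for fixed config and seed; timing
comparisons are explicitly not an evaluation target. In cohort replay the
algorithmic results are computed once per fraction and shared across
observers (as in a retrospective review where the algorithm output is
observer-independent), so deterministic decisions give exactly zero
interobserver variation — the structural analogue of a near-zero median
IOV.

## Evaluation statistics

Errors are signed per-axis differences `E = match − gold`. Summaries give
signed mean/SD/min/max plus median and IQR of `|E|`, quartiles by linear
interpolation between order statistics (the common "type 7" convention;
none is stated in the source material). Method comparisons use
Mann–Whitney U (location of |E|) and Ansari–Bradley (dispersion), exact by
permutation enumeration for small tie-free samples (crossover at pooled
size 12, bounded by enumeration cost) and tie-corrected normal
approximation otherwise; both delegate to `scipy.stats` and are
cross-validated in the tests against an independent full-enumeration
oracle. Correlation with the gold standard is Pearson's r per axis
(Spearman behind a flag — the source is silent on which was used). The
"paired F-test" for variances is implemented as the Pitman–Morgan
procedure (t-test on the correlation between paired sums and differences),
the only standard paired-variance test consistent with the description.
Normality screening uses Shapiro–Wilk at α = 0.05 (described in the source
as a *t*-test, which does not test normality; a standard normality test is
the closest defensible reading). IOV is, per fraction and axis, the
maximum absolute pairwise observer difference, summarized by 25/50/75%
quantiles and IQR across fractions. Degenerate inputs (single record,
zero variance, constant samples) return NaN markers rather than zeros.

## Problem sizes used in the automated checks

The acceptance script and test suite run the full stack at reduced phantom
scale, chosen once as a package default for desk-scale validation:
32-voxel cubes for structural checks, 64-cubes (prostate semi-axes
(12, 10, 11) mm) for shift-recovery and invariance checks, and an
(80, 72, 76) grid for the 20-patient × 5-fraction noise-robustness cohort
(speckle retention ρ = 0.9, gain uniform in ±20%, shift SD 3 mm). Against
known truth this cohort yields per-axis |E| medians ≈ 0.02 mm and SDs
≈ 0.03 mm — comfortably inside the 1-voxel (0.55 mm) median and 2-voxel
(1.1 mm) SD bounds asserted by the tests. Those bounds are self-set at the
scale of the published per-axis algorithm errors; they are not a
reproduction of the clinical tables, which would require the undeposited
patient scans.

## Known limitations

- Translation-only; any real rotation or deformation aliases into the
  translation estimate and the correlation score.
- The phantom's rigid, speckle-only motion model is favourable to
  correlation matching; clinical error levels will be larger.
- Parabolic subvoxel refinement carries a small interpolation bias (here
  ≤ ~0.06 voxel on noiseless phantoms); a self-match with refinement
  enabled returns ~0.01 mm rather than exactly zero because a sampled
  correlation surface is never perfectly symmetric.
- The manual-match surrogate and observer models are statistical stand-ins
  calibrated to published summary numbers; they carry no human-factors
  content, so simulated rejection rates and timings are inputs, not
  findings.
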