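# echomatch

Rigid 3D template matching for interfraction prostate motion in
ultrasound-guided radiotherapy, with a speckle phantom simulator, a
landmark gold standard, clinical review-workflow replay, and the error
statistics to evaluate it all.

## The problem

In prostate radiotherapy guided by transperineal 3D ultrasound, a
reference scan is acquired at simulation and the prostate contour drawn on
it (the reference positioning volume, RPV). Before each treatment fraction
a guide scan shows the prostate displaced by day-to-day (interfraction)
motion, which must be measured and corrected with a couch shift. Manual
matching is slow and observer-dependent; `echomatch` implements an
automated matcher and the semi-automated workflows that wrap it.

## The method

The matcher maximizes a masked normalized cross-correlation over a lattice
of candidate translations `d` (mm, patient axes LR/AP/SI):

    NCC(d) = Σ w (T − T̄)(G_d − Ḡ_d) / sqrt( Σ w (T − T̄)² · Σ w (G_d − Ḡ_d)² )

where `T` is the reference cropped to the RPV bounding box, `w` the
contour weights, and `G_d` the guide patch at displacement `d`. The
correlation map is regularized before peak search,

    R(d) = (K_σ ∗ NCC)(d) − λ ‖d − d₀‖²,

(Gaussian smoothing plus a quadratic distance penalty toward the search
centre `d₀`), the integer argmax is refined per axis by parabolic
interpolation to subvoxel precision, and the result is returned with its
peak NCC, flags and a reviewable match summary (contoured central planes
plus the correlation map). The convention throughout: `d` maps the RPV
onto the guide-scan prostate (GPV = RPV + d); the couch correction is
`−d`. See `docs/methods.md` for the full model, parameter defaults and
limitations.

Because no scan data are deposited, the package includes a first-class
phantom module: Rayleigh-statistics speckle (envelope of two filtered I/Q
fields), a hypoechoic prostate ellipsoid, calcification landmarks, rigid
interfraction shifts with speckle decorrelation and gain changes, and
whole 32-patient × 5-fraction cohorts with known ground truth.

## Worked example

```python
from echomatch import (
    Displacement3D, MotionSpec, PhantomSpec,
    apply_motion, generate_reference, match,
)

spec = PhantomSpec(grid_shape=(64, 64, 64),
                   prostate_semi_axes_mm=(12, 10, 11),
                   n_landmarks=3, seed=42)
bundle = generate_reference(spec)

motion = MotionSpec(shift_mm=Displacement3D(2.2, -1.1, 3.3),
                    decorrelation_rho=0.9, gain=1.15, noise_seed=7)
guide, landmarks, truth = apply_motion(bundle, motion)

result = match(bundle.reference, bundle.rpv_mask, guide)
d = result.displacement.as_array()
print(f"estimated shift (LR, AP, SI): ({d[0]:.3f}, {d[1]:.3f}, {d[2]:.3f}) mm")
print(f"peak NCC: {result.peak_score:.3f}   flags: {result.flags}")
print(f"couch correction: ({-d[0]:.3f}, {-d[1]:.3f}, {-d[2]:.3f}) mm")
```

prints

```
estimated shift (LR, AP, SI): (2.201, -1.104, 3.305) mm
peak NCC: 0.820   flags: []
couch correction: (-2.201, 1.104, -3.305) mm
```

The phantom moved the prostate by (2.2, −1.1, 3.3) mm with 10% speckle
decorrelation and a 15% gain change; the matcher recovers the shift to a
few hundredths of a millimetre. The peak NCC of 0.82 (rather than 1.0)
reflects the deliberate fraction-to-fraction image change; an empty flag
list means the match needs no special review attention.

The same operations are scriptable from the shell:

```
echomatch phantom  --config config.yaml --seed 7 --out cohort/
echomatch match    --ref cohort/patient_001/reference.nii.gz \
                   --rpv cohort/patient_001/rpv.nii.gz \
                   --guide cohort/patient_001/guide_1.nii.gz \
                   --out match.json --summary summary.png
echomatch workflow --cohort cohort/ --mode full --seed 7 --out outcomes.csv
echomatch evaluate --matches matches.csv --gold gold.csv --out report.json
echomatch pipeline --config config.yaml --seed 7 --out run/
```

`pipeline` chains everything (cohort → matches → gold standard →
workflows → error report) and is byte-reproducible for a fixed config and
seed.

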