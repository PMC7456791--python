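"""Synthetic transperineal 3D ultrasound phantoms with known interfraction motion.

The phantom emulates the data model of ultrasound-guided prostate
radiotherapy: a simulation-day *reference* scan with a contoured reference
positioning volume (RPV), and per-fraction *guide* scans in which the
prostate has moved rigidly by an unknown (here: known) translation.

Speckle model
-------------
Fully developed speckle is generated as the envelope ``sqrt(I^2 + Q^2)`` of
two independent, low-pass-filtered, unit-variance Gaussian random fields (an
in-phase/quadrature analogue). The envelope amplitude is then Rayleigh
distributed, the defining statistic of fully developed speckle, and the
Gaussian point-spread filter sets the speckle correlation length per axis.
The envelope is modulated by an echogenicity map — a hypoechoic prostate
ellipsoid against brighter background tissue — and up to five bright
Gaussian blobs stand in for prostatic calcifications, the endogenous
fiducial landmarks used for gold-standard matching.

Guide scans are *not* regenerated from scratch: the pre-envelope I/Q field
pair is retained and rigidly translated, then partially blended with fresh
fields (``rho * old + sqrt(1 - rho^2) * new``) so that fraction-to-fraction
speckle decorrelation, intensity gain and offset changes can be dialled in
while the underlying anatomy moves coherently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grids import BinaryMask3D, Displacement3D, VoxelGrid3D

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "MotionSpec",
    "FractionRecord",
    "PatientRecord",
    "CohortDataset",
    "PhantomError",
    "generate_reference",
    "apply_motion",
    "generate_cohort",
]


class PhantomError(ValueError):
    """Raised when a phantom cannot be generated under its constraints."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic reference scan.

    Defaults describe a realistic prostate study: 0.55 mm isotropic voxels,
    a ~33 cc prostate ellipsoid, hypoechoic (0.6) against background (1.0),
    and sub-millimetre speckle correlation lengths.
    """

    grid_shape: Tuple[int, int, int] = (112, 96, 104)
    voxel_mm: float = 0.55
    prostate_semi_axes_mm: Tuple[float, float, float] = (22.0, 18.0, 20.0)
    prostate_center_mm: Optional[Tuple[float, float, float]] = None
    echo_background: float = 1.0
    echo_prostate: float = 0.6
    n_landmarks: int = 3
    landmark_amp: float = 3.0  # in units of background envelope RMS
    landmark_sigma_mm: float = 0.8
    psf_sigma_mm: Tuple[float, float, float] = (0.6, 0.8, 0.8)
    edge_mm: float = 1.0  # echogenicity transition width at the capsule
    seed: int = 0

    def __post_init__(self) -> None:
        shape = np.asarray(self.grid_shape, dtype=int)
        if shape.shape != (3,) or np.any(shape < 32):
            raise PhantomError("grid_shape must be 3 axes of at least 32 voxels")
        if self.voxel_mm <= 0:
            raise PhantomError("voxel_mm must be positive")
        if not 0 <= self.n_landmarks <= 5:
            raise PhantomError("n_landmarks must lie in 0..5")
        semi = np.asarray(self.prostate_semi_axes_mm, dtype=float)
        if np.any(semi <= 0):
            raise PhantomError("prostate semi-axes must be positive")
        extent = shape * self.voxel_mm
        center = self.center_mm()
        lo_margin = center - semi
        hi_margin = extent - (center + semi)
        if np.any(lo_margin < 5.0) or np.any(hi_margin < 5.0):
            raise PhantomError(
                "prostate ellipsoid must fit inside the grid with >= 5 mm margin"
            )

    def center_mm(self) -> np.ndarray:
        if self.prostate_center_mm is not None:
            return np.asarray(self.prostate_center_mm, dtype=float)
        return np.asarray(self.grid_shape, dtype=float) * self.voxel_mm / 2.0

    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, dtype=float) * self.voxel_mm


@dataclass
class PhantomBundle:
    """A reference scan, its RPV mask, landmarks and retained speckle state."""

    reference: VoxelGrid3D
    rpv_mask: BinaryMask3D
    landmarks_ref: List[Tuple[int, np.ndarray]]
    speckle_state: Tuple[np.ndarray, np.ndarray]
    spec: PhantomSpec


@dataclass(frozen=True)
class MotionSpec:
    """One interfraction perturbation: rigid shift plus image-quality change.

    ``decorrelation_rho`` is the retained fraction of the speckle field
    (1 = identical speckle, 0 = fully fresh); ``gain``/``offset`` model
    fraction-to-fraction intensity differences as ``a*x + b``.
    """

    shift_mm: Displacement3D = field(default_factory=lambda: Displacement3D(0, 0, 0))
    gain: float = 1.0
    offset: float = 0.0
    decorrelation_rho: float = 1.0
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.decorrelation_rho <= 1.0:
            raise PhantomError("decorrelation_rho must lie in [0, 1]")
        if self.gain <= 0:
            raise PhantomError("gain must be positive")


@dataclass
class FractionRecord:
    fraction_id: int
    guide: VoxelGrid3D
    true_shift: Displacement3D
    landmarks_guide: List[Tuple[int, np.ndarray]]


@dataclass
class PatientRecord:
    patient_id: int
    bundle: PhantomBundle
    fractions: List[FractionRecord]
    split_tag: str  # "train" or "test"


@dataclass
class CohortDataset:
    """A simulated study cohort: one reference per patient, several guides."""

    patients: List[PatientRecord]

    def n_pairs(self) -> int:
        return sum(len(p.fractions) for p in self.patients)

    def pairs(self, split: Optional[str] = None):
        for p in self.patients:
            if split is not None and p.split_tag != split:
                continue
            for f in p.fractions:
                yield p, f


def _smoothed_unit_fields(
    rng: np.random.Generator, shape, sigma_vox
) -> Tuple[np.ndarray, np.ndarray]:
    """Two independent low-pass-filtered random fields, each unit variance."""
    out = []
    for _ in range(2):
        f = rng.standard_normal(shape)
        f = ndimage.gaussian_filter(f, sigma=sigma_vox, mode="wrap")
        f /= f.std()
        out.append(f)
    return out[0], out[1]


def _normalized_radius(spec: PhantomSpec, center_mm: np.ndarray) -> np.ndarray:
    """Per-voxel normalized ellipsoid radius (1 at the capsule surface)."""
    coords = [
        (np.arange(n) * spec.voxel_mm - c) / a
        for n, c, a in zip(spec.grid_shape, center_mm, spec.prostate_semi_axes_mm)
    ]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    return np.sqrt(x * x + y * y + z * z)


def _echo_map(spec: PhantomSpec, center_mm: np.ndarray) -> np.ndarray:
    """Echogenicity: background outside, hypoechoic inside, ~1 mm soft capsule."""
    r = _normalized_radius(spec, center_mm)
    # approximate signed distance to the capsule in mm (positive inside)
    s = (1.0 - r) * float(min(spec.prostate_semi_axes_mm))
    inside = np.clip(0.5 + s / spec.edge_mm, 0.0, 1.0)
    return spec.echo_background + (spec.echo_prostate - spec.echo_background) * inside


def _render_landmarks(
    values: np.ndarray,
    spec: PhantomSpec,
    landmarks: Sequence[Tuple[int, np.ndarray]],
    amp_abs: float,
) -> None:
    """Add Gaussian blobs (analytic, subvoxel positions) in place."""
    sigma = spec.landmark_sigma_mm
    half = int(np.ceil(4 * sigma / spec.voxel_mm))
    for _, pos_mm in landmarks:
        cidx = pos_mm / spec.voxel_mm
        lo = np.maximum(np.floor(cidx).astype(int) - half, 0)
        hi = np.minimum(np.floor(cidx).astype(int) + half + 1, values.shape)
        axes = [
            (np.arange(l, h) * spec.voxel_mm - p) for l, h, p in zip(lo, hi, pos_mm)
        ]
        dx, dy, dz = np.meshgrid(*axes, indexing="ij")
        d2 = dx * dx + dy * dy + dz * dz
        values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amp_abs * np.exp(
            -d2 / (2 * sigma * sigma)
        )


def _place_landmarks(
    spec: PhantomSpec,
    rng: np.random.Generator,
    center_mm: np.ndarray,
    min_sep_mm: float = 4.0,
    max_tries: int = 5000,
) -> List[Tuple[int, np.ndarray]]:
    """Uniform rejection sampling strictly inside the ellipsoid, min separation."""
    semi = np.asarray(spec.prostate_semi_axes_mm)
    placed: List[np.ndarray] = []
    tries = 0
    while len(placed) < spec.n_landmarks:
        if tries >= max_tries:
            raise PhantomError(
                f"could not place {spec.n_landmarks} landmarks with "
                f">= {min_sep_mm} mm separation inside the ellipsoid "
                f"after {max_tries} tries"
            )
        tries += 1
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.sum(u * u) > 0.85**2:  # strictly interior, clear of the capsule
            continue
        pos = center_mm + u * semi
        if all(np.linalg.norm(pos - q) >= min_sep_mm for q in placed):
            placed.append(pos)
    return [(i, p) for i, p in enumerate(placed)]


def generate_reference(spec: PhantomSpec) -> PhantomBundle:
    """Generate one reference scan with RPV mask and landmarks.

    Deterministic: the same spec (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    center = spec.center_mm()
    sigma_vox = np.asarray(spec.psf_sigma_mm) / spec.voxel_mm
    i_field, q_field = _smoothed_unit_fields(rng, tuple(spec.grid_shape), sigma_vox)
    envelope = np.hypot(i_field, q_field)
    echo = _echo_map(spec, center)
    values = envelope * echo

    landmarks = _place_landmarks(spec, rng, center)
    # Rayleigh envelope of unit-variance I/Q has RMS sqrt(2); scale by background
    amp_abs = spec.landmark_amp * np.sqrt(2.0) * spec.echo_background
    _render_landmarks(values, spec, landmarks, amp_abs)

    mask = _normalized_radius(spec, center) <= 1.0
    reference = VoxelGrid3D(values, spacing_mm=spec.voxel_mm)
    rpv = BinaryMask3D(mask, spacing_mm=spec.voxel_mm)
    return PhantomBundle(reference, rpv, landmarks, (i_field, q_field), spec)


def apply_motion(
    bundle: PhantomBundle, motion: MotionSpec
) -> Tuple[VoxelGrid3D, List[Tuple[int, np.ndarray]], Displacement3D]:
    """Create a guide scan: translated anatomy, decorrelated speckle, new gain.

    The pre-envelope I/Q fields are translated (linear interpolation for
    subvoxel shifts), blended with fresh fields, re-enveloped, modulated by
    the echogenicity map at the *shifted* prostate position, landmarks are
    re-rendered at their exact shifted positions, and the intensity map
    ``gain * x + offset`` is applied last. The returned truth equals
    ``motion.shift_mm`` by construction.
    """
    spec = bundle.spec
    shift = motion.shift_mm.as_array()
    extent = spec.extent_mm()
    if np.any(np.abs(shift) > extent / 4.0):
        raise PhantomError(
            f"shift {shift} mm exceeds a quarter of the field extent {extent} mm"
        )

    shift_vox = shift / spec.voxel_mm
    i_field, q_field = bundle.speckle_state
    if np.any(shift_vox != 0):
        i_field = ndimage.shift(i_field, shift_vox, order=1, mode="reflect", prefilter=False)
        q_field = ndimage.shift(q_field, shift_vox, order=1, mode="reflect", prefilter=False)

    rho = motion.decorrelation_rho
    if rho < 1.0:
        rng = np.random.default_rng(motion.noise_seed)
        sigma_vox = np.asarray(spec.psf_sigma_mm) / spec.voxel_mm
        fi, fq = _smoothed_unit_fields(rng, tuple(spec.grid_shape), sigma_vox)
        w = np.sqrt(1.0 - rho * rho)
        i_field = rho * i_field + w * fi
        q_field = rho * q_field + w * fq

    center = spec.center_mm() + shift
    values = np.hypot(i_field, q_field) * _echo_map(spec, center)
    landmarks_guide = [(i, p + shift) for i, p in bundle.landmarks_ref]
    amp_abs = spec.landmark_amp * np.sqrt(2.0) * spec.echo_background
    _render_landmarks(values, spec, landmarks_guide, amp_abs)
    values = motion.gain * values + motion.offset

    guide = VoxelGrid3D(values, spacing_mm=spec.voxel_mm)
    return guide, landmarks_guide, motion.shift_mm


def _child_seed(*key: int) -> int:
    """Deterministic 31-bit seed fan-out from a tuple of integers."""
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] & 0x7FFFFFFF)


def _truncated_normal_shift(
    rng: np.random.Generator, sd_mm: np.ndarray, trunc_mm: float = 10.0
) -> np.ndarray:
    out = np.zeros(3)
    for ax in range(3):
        if sd_mm[ax] == 0:
            continue
        x = rng.normal(0.0, sd_mm[ax])
        while abs(x) > trunc_mm:
            x = rng.normal(0.0, sd_mm[ax])
        out[ax] = x
    return out


def generate_cohort(
    n_patients: int = 32,
    n_fractions: int = 5,
    shift_sd_mm=3.0,
    train_fraction_of_patients: float = 20 / 32,
    base_seed: int = 0,
    spec: Optional[PhantomSpec] = None,
    gain_range: Tuple[float, float] = (1.0, 1.0),
    decorrelation_rho: float = 1.0,
    shift_trunc_mm: float = 10.0,
) -> CohortDataset:
    """Generate a study-structured cohort with known per-fraction truth shifts.

    Each patient gets an independently seeded reference scan and
    ``n_fractions`` guide scans whose shifts are drawn per axis from a
    zero-mean normal (SD ``shift_sd_mm``, truncated at ``shift_trunc_mm``).
    Patients — never individual fractions — are partitioned into the train
    and test splits.
    """
    if n_patients < 1 or n_fractions < 1:
        raise PhantomError("need at least one patient and one fraction")
    base_spec = spec if spec is not None else PhantomSpec()
    sd = np.broadcast_to(np.asarray(shift_sd_mm, dtype=float), (3,))
    n_train = int(round(train_fraction_of_patients * n_patients))

    patients: List[PatientRecord] = []
    for p in range(n_patients):
        pspec = PhantomSpec(
            **{
                **{f: getattr(base_spec, f) for f in base_spec.__dataclass_fields__},
                "seed": _child_seed(base_seed, p, 0),
            }
        )
        bundle = generate_reference(pspec)
        fractions: List[FractionRecord] = []
        for f in range(n_fractions):
            rng = np.random.default_rng(_child_seed(base_seed, p, 1 + f))
            shift = _truncated_normal_shift(rng, sd, shift_trunc_mm)
            gain = float(rng.uniform(*gain_range))
            motion = MotionSpec(
                shift_mm=Displacement3D.from_array(shift),
                gain=gain,
                decorrelation_rho=decorrelation_rho,
                noise_seed=_child_seed(base_seed, p, 1 + f, 97),
            )
            guide, lm_guide, truth = apply_motion(bundle, motion)
            fractions.append(FractionRecord(f + 1, guide, truth, lm_guide))
        tag = "train" if p < n_train else "test"
        patients.append(PatientRecord(p + 1, bundle, fractions, tag))
    return CohortDataset(patients)
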