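"""Regularized 3D correlation template matching for interfraction motion.

The matcher estimates the rigid translation that maps the contoured prostate
(RPV) in a reference ultrasound volume onto its position in a treatment-day
guide volume. It is a translation-only method by design: couch corrections
are translations and the clinical comparator quantified no rotations.

Pipeline
--------
1. ``extract_template`` — crop the reference to the RPV bounding box; the
   binary contour becomes a weight map so the similarity is a *masked*
   (weighted) normalized cross-correlation over the anatomy, not a box.
2. ``build_search_region`` — a displacement lattice: either a symmetric
   ``±max_shift_mm`` window (automated mode) or one derived from a
   user-placed rectangular search window expanded by a fixed voxel margin
   (semi-automated mode).
3. ``ncc_volume`` — weighted NCC at every integer displacement of the
   lattice, evaluated with FFT cross-correlations, giving the reviewable
   correlation map.
4. ``regularize`` — Gaussian smoothing of the correlation map plus an
   additive quadratic distance penalty ``-lambda * ||d - d0||^2`` (mm^2),
   which stabilizes the peak on feature-poor or low-quality scans.
5. ``find_peak`` / ``refine_subvoxel`` — global argmax with deterministic
   tie-breaking, then independent per-axis parabolic interpolation for
   subvoxel precision.

Weighted NCC: with weights ``w`` and weighted means ``T̄, Ḡ``,

    score(d) = Σ w (T - T̄)(G_d - Ḡ_d) / sqrt(Σ w (T - T̄)² · Σ w (G_d - Ḡ_d)²)

which is invariant to positive affine intensity maps of either image and
bounded in [-1, 1].
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage, signal

from .grids import BinaryMask3D, Displacement3D, VoxelGrid3D

__all__ = [
    "Template",
    "CorrelationVolume",
    "RegistrationConfig",
    "MatchResult",
    "SearchLattice",
    "RegistrationError",
    "extract_template",
    "build_search_region",
    "ncc_volume",
    "ncc_at",
    "regularize",
    "find_peak",
    "refine_subvoxel",
    "match",
    "match_summary",
    "MatchSummary",
]

SENTINEL = -np.inf  # score assigned to degenerate (zero-variance) guide patches


class RegistrationError(ValueError):
    """Raised when a match cannot be computed (degenerate or infeasible input)."""


@dataclass
class Template:
    """The RPV-cropped reference patch and its contour weight map."""

    crop: VoxelGrid3D
    weights: np.ndarray
    world_offset_mm: np.ndarray  # world position of the crop corner voxel

    @property
    def shape(self) -> tuple:
        return self.crop.shape


@dataclass
class SearchLattice:
    """Inclusive integer displacement bounds (voxels) plus grid metadata."""

    lo: np.ndarray
    hi: np.ndarray
    base_index: np.ndarray  # template corner index in the guide at d = 0
    spacing_mm: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=int)
        self.hi = np.asarray(self.hi, dtype=int)
        if np.any(self.hi < self.lo):
            raise RegistrationError("empty search lattice")

    @property
    def shape(self) -> tuple:
        return tuple(self.hi - self.lo + 1)

    def center_mm(self) -> np.ndarray:
        return (self.lo + self.hi) / 2.0 * self.spacing_mm

    def contains(self, d_vox) -> bool:
        d = np.asarray(d_vox)
        return bool(np.all(d >= self.lo) and np.all(d <= self.hi))


@dataclass
class CorrelationVolume:
    """NCC score per integer displacement — the reviewable correlation map."""

    scores: np.ndarray  # 3D, indexed as displacement - lattice_origin
    lattice_origin: np.ndarray  # integer displacement (voxels) of scores[0,0,0]
    spacing_mm: np.ndarray

    def __post_init__(self) -> None:
        self.lattice_origin = np.asarray(self.lattice_origin, dtype=int)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)

    def displacement_vox(self, index) -> np.ndarray:
        return self.lattice_origin + np.asarray(index, dtype=int)

    def displacement_mm(self, index) -> np.ndarray:
        return self.displacement_vox(index) * self.spacing_mm


@dataclass(frozen=True)
class RegistrationConfig:
    """Tunables of the matcher.

    lambda_reg: quadratic penalty weight per mm^2 pulling the peak toward
        the search-region centre; 0 disables.
    smooth_sigma_vox: Gaussian smoothing of the correlation map (lattice
        voxels) before the peak search; 0 disables.
    window_margin_vox: semi-automated mode margin added on each side of the
        user-placed window.
    max_shift_mm: automated-mode search half-extent.
    low_score_threshold: NCC below which the match is flagged for review.
    """

    lambda_reg: float = 1e-3
    smooth_sigma_vox: float = 1.0
    window_margin_vox: int = 15
    max_shift_mm: float = 15.0
    subvoxel: bool = True
    low_score_threshold: float = 0.4

    def __post_init__(self) -> None:
        if self.lambda_reg < 0 or self.smooth_sigma_vox < 0 or self.window_margin_vox < 0:
            raise RegistrationError("regularization parameters must be non-negative")


@dataclass
class MatchResult:
    """A single match: displacement, quality score, provenance and flags."""

    displacement: Displacement3D
    peak_score: float
    method: str
    time_s: float = 0.0
    flags: List[str] = field(default_factory=list)
    correlation: Optional[CorrelationVolume] = None

    def to_dict(self) -> dict:
        return {
            "displacement_mm": list(self.displacement.as_array()),
            "peak_score": self.peak_score,
            "method": self.method,
            "time_s": self.time_s,
            "flags": list(self.flags),
        }


def extract_template(reference: VoxelGrid3D, rpv: BinaryMask3D) -> Template:
    """Crop the reference to the RPV bounding box with contour weights."""
    if not reference.same_geometry(rpv):
        raise RegistrationError("reference and RPV mask geometries differ")
    if not rpv.values.any():
        raise RegistrationError("RPV mask is empty")
    lo, hi = rpv.bounding_box()
    dims = hi - lo + 1
    if np.any(dims < 3):
        raise RegistrationError(
            f"RPV bounding box {tuple(dims)} is smaller than 3 voxels on an axis"
        )
    sl = tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))
    crop_values = np.asarray(reference.values[sl], dtype=float)
    weights = rpv.values[sl].astype(float)
    w_sum = weights.sum()
    t_mean = (weights * crop_values).sum() / w_sum
    t_var = (weights * (crop_values - t_mean) ** 2).sum()
    if t_var <= 0:
        raise RegistrationError("template has zero weighted intensity variance")
    crop = VoxelGrid3D(
        crop_values,
        spacing_mm=reference.spacing_mm,
        origin_mm=reference.index_to_world(lo),
    )
    return Template(crop, weights, reference.index_to_world(lo))


def _base_index(template: Template, guide: VoxelGrid3D) -> np.ndarray:
    """Template corner voxel index in the guide grid at zero displacement."""
    cont = guide.world_to_index(template.world_offset_mm)
    base = np.rint(cont).astype(int)
    if np.any(np.abs(cont - base) > 1e-3):
        raise RegistrationError(
            "template world offset is not aligned with the guide voxel grid"
        )
    return base


def build_search_region(
    guide: VoxelGrid3D,
    template: Template,
    mode: str = "automated",
    window_box_mm: Optional[Tuple] = None,
    config: RegistrationConfig = RegistrationConfig(),
) -> SearchLattice:
    """Displacement lattice for the requested workflow mode.

    Automated mode searches ``±max_shift_mm`` around zero displacement.
    Semi-automated mode requires a user-placed rectangular window
    (``window_box_mm`` = (lo_corner_mm, hi_corner_mm) marking the
    approximate prostate location); the window is expanded by
    ``window_margin_vox`` voxels on each side and the lattice holds every
    displacement keeping the template inside it. Both lattices are clipped
    to displacements that keep the template inside the guide; zero
    displacement is retained whenever feasible.
    """
    spacing = guide.spacing_mm
    tshape = np.asarray(template.shape)
    gshape = np.asarray(guide.shape)
    if np.any(tshape > gshape):
        raise RegistrationError("template is larger than the guide volume")
    base = _base_index(template, guide)
    feas_lo = -base
    feas_hi = gshape - tshape - base

    if mode == "automated":
        half = np.floor(config.max_shift_mm / spacing).astype(int)
        lo, hi = -half, half
    elif mode in ("semi", "semi_automated"):
        if window_box_mm is None:
            raise RegistrationError("semi-automated mode requires a search window")
        wlo_mm, whi_mm = (np.asarray(c, dtype=float) for c in window_box_mm)
        wlo = np.rint(guide.world_to_index(np.minimum(wlo_mm, whi_mm))).astype(int)
        whi = np.rint(guide.world_to_index(np.maximum(wlo_mm, whi_mm))).astype(int)
        wlo -= config.window_margin_vox
        whi += config.window_margin_vox
        if np.any(whi < 0) or np.any(wlo > gshape - 1):
            raise RegistrationError("search window lies entirely outside the guide")
        wlo = np.maximum(wlo, 0)
        whi = np.minimum(whi, gshape - 1)
        if np.any(whi - wlo + 1 < tshape):
            raise RegistrationError("search window is smaller than the template")
        lo = wlo - base
        hi = whi + 1 - tshape - base
    else:
        raise RegistrationError(f"unknown search mode {mode!r}")

    lo = np.maximum(lo, feas_lo)
    hi = np.minimum(hi, feas_hi)
    if np.any(hi < lo):
        raise RegistrationError("search lattice is empty after clipping to the guide")
    return SearchLattice(lo, hi, base, spacing)


def ncc_volume(
    template: Template, guide: VoxelGrid3D, lattice: SearchLattice
) -> CorrelationVolume:
    """Weighted NCC at every lattice displacement, via FFT cross-correlations.

    With fixed weights ``w`` the three displacement-dependent sums
    ``Σ w·G``, ``Σ w·G²`` and ``Σ w(T-T̄)·G`` are cross-correlations of the
    guide with ``w`` and with ``w(T-T̄)``, so the whole score volume costs a
    handful of FFTs. Guide patches with zero weighted variance receive a
    ``-inf`` sentinel.
    """
    w = template.weights
    t = np.asarray(template.crop.values, dtype=float)
    w_sum = w.sum()
    t_mean = (w * t).sum() / w_sum
    tc = w * (t - t_mean)
    t_var = (tc * (t - t_mean)).sum()
    if t_var <= 0:
        raise RegistrationError("template has zero weighted intensity variance")

    tshape = np.asarray(template.shape)
    glo = lattice.base_index + lattice.lo
    ghi = lattice.base_index + lattice.hi + tshape  # exclusive
    sub = np.asarray(guide.values[tuple(slice(a, b) for a, b in zip(glo, ghi))],
                     dtype=float)

    s_g = signal.correlate(sub, w, mode="valid", method="fft")
    s_g2 = signal.correlate(sub * sub, w, mode="valid", method="fft")
    s_tg = signal.correlate(sub, tc, mode="valid", method="fft")
    g_var = s_g2 - s_g * s_g / w_sum

    scale = np.abs(s_g2).max() + 1.0
    degenerate = g_var <= 1e-12 * scale
    g_var = np.where(degenerate, 1.0, g_var)
    scores = s_tg / np.sqrt(t_var * g_var)
    scores = np.clip(scores, -1.0, 1.0)
    scores[degenerate] = SENTINEL
    if np.all(degenerate):
        raise RegistrationError("every guide patch in the lattice is degenerate")
    return CorrelationVolume(scores, lattice.lo, guide.spacing_mm)


def ncc_at(template: Template, guide: VoxelGrid3D, d_vox) -> float:
    """Direct (non-FFT) weighted NCC at one integer displacement."""
    base = _base_index(template, guide)
    p = base + np.asarray(d_vox, dtype=int)
    tshape = np.asarray(template.shape)
    if np.any(p < 0) or np.any(p + tshape > np.asarray(guide.shape)):
        raise RegistrationError("displacement places the template outside the guide")
    patch = np.asarray(
        guide.values[tuple(slice(a, a + n) for a, n in zip(p, tshape))], dtype=float
    )
    w = template.weights
    t = np.asarray(template.crop.values, dtype=float)
    w_sum = w.sum()
    t_mean = (w * t).sum() / w_sum
    g_mean = (w * patch).sum() / w_sum
    tc = t - t_mean
    gc = patch - g_mean
    t_var = (w * tc * tc).sum()
    g_var = (w * gc * gc).sum()
    if g_var <= 0:
        return SENTINEL
    return float((w * tc * gc).sum() / np.sqrt(t_var * g_var))


def regularize(
    corr: CorrelationVolume,
    d0: Displacement3D,
    config: RegistrationConfig = RegistrationConfig(),
) -> CorrelationVolume:
    """Smooth the correlation map and subtract a quadratic distance penalty.

    R(d) = (K_sigma * corr)(d) - lambda * ||d - d0||^2  (distance in mm).
    With lambda = 0 and sigma = 0 the input is returned unchanged.
    Sentinel entries are excluded from smoothing and preserved.
    """
    scores = np.array(corr.scores, dtype=float)
    finite = np.isfinite(scores)
    if config.smooth_sigma_vox > 0:
        fill = scores[finite].min() if finite.any() else 0.0
        scores[~finite] = fill
        scores = ndimage.gaussian_filter(
            scores, sigma=config.smooth_sigma_vox, mode="nearest"
        )
    if config.lambda_reg > 0:
        idx = np.indices(scores.shape)
        diff2 = np.zeros(scores.shape)
        d0_arr = d0.as_array()
        for ax in range(3):
            d_mm = (idx[ax] + corr.lattice_origin[ax]) * corr.spacing_mm[ax]
            diff2 += (d_mm - d0_arr[ax]) ** 2
        scores = scores - config.lambda_reg * diff2
    scores[~finite] = SENTINEL
    return CorrelationVolume(scores, corr.lattice_origin, corr.spacing_mm)


def find_peak(cost: CorrelationVolume) -> Tuple[np.ndarray, float, bool]:
    """Global argmax with deterministic tie-breaking.

    Ties on the maximum are broken by the smallest Euclidean displacement
    norm (mm), then lexicographically on (LR, AP, SI). Returns the integer
    displacement (voxels), the peak value and an edge flag set when the
    peak touches the lattice boundary.
    """
    scores = cost.scores
    finite = np.isfinite(scores)
    if not finite.any():
        raise RegistrationError("correlation volume contains no finite scores")
    vmax = scores[finite].max()
    cand = np.argwhere(finite & (scores == vmax))
    d_vox = cand + cost.lattice_origin
    d_mm = d_vox * cost.spacing_mm
    norms = np.einsum("ij,ij->i", d_mm, d_mm)
    order = np.lexsort((d_vox[:, 2], d_vox[:, 1], d_vox[:, 0], norms))
    best = cand[order[0]]
    edge = bool(
        np.any(best == 0) or np.any(best == np.asarray(scores.shape) - 1)
    )
    return best + cost.lattice_origin, float(vmax), edge


def refine_subvoxel(
    cost: CorrelationVolume, peak_vox: np.ndarray
) -> Tuple[Displacement3D, List[str]]:
    """Per-axis parabolic interpolation around the integer peak.

    delta = (c[-1] - c[+1]) / (2 (c[-1] - 2 c[0] + c[+1])), clamped to
    [-0.5, 0.5]. A boundary peak or a zero-curvature axis keeps the integer
    position on that axis and sets a flag.
    """
    flags: List[str] = []
    idx = np.asarray(peak_vox, dtype=int) - cost.lattice_origin
    shape = np.asarray(cost.scores.shape)
    delta = np.zeros(3)
    if np.any(idx == 0) or np.any(idx == shape - 1):
        flags.append("edge_peak")
    else:
        for ax in range(3):
            sl = list(idx)
            sl[ax] = slice(idx[ax] - 1, idx[ax] + 2)
            cm, c0, cp = cost.scores[tuple(sl)]
            if not (np.isfinite(cm) and np.isfinite(cp)):
                flags.append(f"degenerate_neighbor_axis_{ax}")
                continue
            curv = cm - 2 * c0 + cp
            if curv == 0:
                flags.append(f"zero_curvature_axis_{ax}")
                continue
            delta[ax] = np.clip((cm - cp) / (2 * curv), -0.5, 0.5)
    mm = (np.asarray(peak_vox, dtype=float) + delta) * cost.spacing_mm
    return Displacement3D.from_array(mm), flags


def match(
    reference: VoxelGrid3D,
    rpv: BinaryMask3D,
    guide: VoxelGrid3D,
    config: RegistrationConfig = RegistrationConfig(),
    mode: str = "automated",
    window_box_mm: Optional[Tuple] = None,
    keep_correlation: bool = True,
) -> MatchResult:
    """End-to-end match: template → lattice → NCC → regularize → peak → subvoxel.

    The reported ``peak_score`` is the raw (unregularized) weighted NCC,
    re-evaluated directly at the integer peak. A ``low_score`` flag marks
    matches below the review threshold, ``edge_peak`` marks peaks on the
    lattice boundary.
    """
    t0 = time.perf_counter()
    template = extract_template(reference, rpv)
    lattice = build_search_region(guide, template, mode, window_box_mm, config)
    corr = ncc_volume(template, guide, lattice)
    d0 = Displacement3D.from_array(lattice.center_mm())
    cost = regularize(corr, d0, config)
    peak_vox, _, edge = find_peak(cost)
    flags: List[str] = []
    if config.subvoxel:
        # integer peak selection uses the regularized cost; the parabola is
        # fitted on the raw correlation surface, whose curvature around the
        # peak is not flattened by the smoothing kernel
        disp, sub_flags = refine_subvoxel(corr, peak_vox)
        flags.extend(f for f in sub_flags if f != "edge_peak")
    else:
        disp = Displacement3D.from_array(peak_vox * guide.spacing_mm)
    peak_score = ncc_at(template, guide, peak_vox)
    if edge:
        flags.append("edge_peak")
    if peak_score < config.low_score_threshold:
        flags.append("low_score")
    method = "automated" if mode == "automated" else "semi_automated"
    return MatchResult(
        displacement=disp,
        peak_score=peak_score,
        method=method,
        time_s=time.perf_counter() - t0,
        flags=flags,
        correlation=corr if keep_correlation else None,
    )


@dataclass
class MatchSummary:
    """Reviewable match summary: contoured central planes plus correlation map."""

    ref_sagittal: np.ndarray
    ref_coronal: np.ndarray
    guide_sagittal: np.ndarray
    guide_coronal: np.ndarray
    rpv_sagittal_outline: np.ndarray
    rpv_coronal_outline: np.ndarray
    gpv_sagittal_outline: np.ndarray
    gpv_coronal_outline: np.ndarray
    corr_slice: np.ndarray
    corr_peak_rc: Tuple[int, int]
    plane_indices: Tuple[int, int]  # (sagittal LR index, coronal AP index)

    def save(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 3, figsize=(12, 7))
        panels = [
            (self.ref_sagittal, self.rpv_sagittal_outline, "reference sagittal (RPV)"),
            (self.guide_sagittal, self.gpv_sagittal_outline, "guide sagittal (GPV)"),
            (self.ref_coronal, self.rpv_coronal_outline, "reference coronal (RPV)"),
            (self.guide_coronal, self.gpv_coronal_outline, "guide coronal (GPV)"),
        ]
        for ax, (img, outline, title) in zip(axes.flat[:4], panels):
            ax.imshow(img.T, cmap="gray", origin="lower")
            ys, xs = np.nonzero(outline.T)
            ax.plot(xs, ys, ".", ms=1, color="tab:orange")
            ax.set_title(title, fontsize=9)
            ax.axis("off")
        ax = axes.flat[4]
        ax.imshow(self.corr_slice.T, cmap="viridis", origin="lower")
        ax.plot(self.corr_peak_rc[0], self.corr_peak_rc[1], "r+", ms=12)
        ax.set_title("correlation map (central slice)", fontsize=9)
        axes.flat[5].axis("off")
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)


def _outline(mask2d: np.ndarray) -> np.ndarray:
    return mask2d & ~ndimage.binary_erosion(mask2d)


def match_summary(
    reference: VoxelGrid3D,
    guide: VoxelGrid3D,
    rpv: BinaryMask3D,
    result: MatchResult,
) -> MatchSummary:
    """Central sagittal/coronal planes with RPV/GPV contours and the correlation map.

    The GPV is the RPV translated by the match result; plane indices are
    taken at the centre of the shifted RPV bounding box.
    """
    d_vox = result.displacement.as_array() / guide.spacing_mm
    d_int = np.rint(d_vox).astype(int)
    gpv = np.zeros(guide.shape, dtype=bool)
    lo_r, hi_r = rpv.bounding_box()
    # shift the mask voxelwise; clip to the guide extent
    idx = np.argwhere(rpv.values)
    shifted = idx + d_int
    keep = np.all((shifted >= 0) & (shifted < np.asarray(guide.shape)), axis=1)
    if not keep.any():
        raise RegistrationError("shifted contour lies entirely outside the guide")
    gpv[tuple(shifted[keep].T)] = True

    lo_g = lo_r + d_int
    hi_g = hi_r + d_int
    center = np.clip(
        (lo_g + hi_g) // 2, 0, np.asarray(guide.shape) - 1
    )
    i_sag, j_cor = int(center[0]), int(center[1])

    corr = result.correlation
    if corr is None:
        raise RegistrationError("match result carries no correlation volume")
    peak_idx = np.rint(d_vox).astype(int) - corr.lattice_origin
    peak_idx = np.clip(peak_idx, 0, np.asarray(corr.scores.shape) - 1)
    corr_slice = np.array(corr.scores[:, :, peak_idx[2]])
    corr_slice[~np.isfinite(corr_slice)] = np.nanmin(
        np.where(np.isfinite(corr_slice), corr_slice, np.nan)
    ) if np.isfinite(corr_slice).any() else -1.0

    return MatchSummary(
        ref_sagittal=np.asarray(reference.values[i_sag, :, :], dtype=float),
        ref_coronal=np.asarray(reference.values[:, j_cor, :], dtype=float),
        guide_sagittal=np.asarray(guide.values[i_sag, :, :], dtype=float),
        guide_coronal=np.asarray(guide.values[:, j_cor, :], dtype=float),
        rpv_sagittal_outline=_outline(rpv.values[i_sag, :, :]),
        rpv_coronal_outline=_outline(rpv.values[:, j_cor, :]),
        gpv_sagittal_outline=_outline(gpv[i_sag, :, :]),
        gpv_coronal_outline=_outline(gpv[:, j_cor, :]),
        corr_slice=corr_slice,
        corr_peak_rc=(int(peak_idx[0]), int(peak_idx[1])),
        plane_indices=(i_sag, j_cor),
    )
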