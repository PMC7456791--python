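"""Matcher: template extraction, NCC, regularization, peaks, end-to-end."""

import numpy as np
import pytest

from conftest import brute_argmax_ncc
from echomatch import (
    BinaryMask3D,
    CorrelationVolume,
    Displacement3D,
    MotionSpec,
    RegistrationConfig,
    VoxelGrid3D,
    apply_motion,
    build_search_region,
    extract_template,
    find_peak,
    match,
    match_summary,
    ncc_volume,
    refine_subvoxel,
    regularize,
)
from echomatch.registration import RegistrationError


def _ball_mask(shape, center, radius):
    idx = np.indices(shape)
    d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    return d2 <= radius**2


@pytest.fixture()
def random_pair():
    rng = np.random.default_rng(0)
    ref = VoxelGrid3D(rng.random((48, 48, 48)), spacing_mm=1.0)
    mask = BinaryMask3D(
        _ball_mask((48, 48, 48), (24, 24, 24), 10), spacing_mm=1.0
    )
    return ref, mask


class TestExtractTemplate:
    def test_full_volume_mask(self, random_pair):
        ref, _ = random_pair
        mask = BinaryMask3D(np.ones(ref.shape, bool), spacing_mm=1.0)
        t = extract_template(ref, mask)
        assert t.shape == ref.shape
        assert np.allclose(t.world_offset_mm, ref.origin_mm)

    def test_sphere_bounding_box(self, random_pair):
        ref, mask = random_pair
        t = extract_template(ref, mask)
        assert t.shape == (21, 21, 21)

    def test_empty_mask_fails(self, random_pair):
        ref, _ = random_pair
        empty = BinaryMask3D(np.zeros(ref.shape, bool), spacing_mm=1.0)
        with pytest.raises(RegistrationError, match="empty"):
            extract_template(ref, empty)

    def test_constant_reference_fails(self, random_pair):
        _, mask = random_pair
        flat = VoxelGrid3D(np.ones((48, 48, 48)), spacing_mm=1.0)
        with pytest.raises(RegistrationError, match="variance"):
            extract_template(flat, mask)

    def test_tiny_bbox_fails(self, random_pair):
        ref, _ = random_pair
        m = np.zeros(ref.shape, bool)
        m[24, 24, 24] = True
        with pytest.raises(RegistrationError, match="3 voxels"):
            extract_template(ref, BinaryMask3D(m, spacing_mm=1.0))


class TestBuildSearchRegion:
    def test_semi_window_margin_15_gives_51_cube(self):
        """A 21-cube template with 15-voxel margin per side spans a 51-cube
        window, i.e. 31 candidate displacements per axis before clipping."""
        rng = np.random.default_rng(1)
        guide = VoxelGrid3D(rng.random((96, 96, 96)), spacing_mm=1.0)
        ref = VoxelGrid3D(rng.random((96, 96, 96)), spacing_mm=1.0)
        mask = BinaryMask3D(_ball_mask((96, 96, 96), (48, 48, 48), 10),
                            spacing_mm=1.0)
        t = extract_template(ref, mask)
        window = (t.world_offset_mm, t.world_offset_mm + 20.0)  # template-size box
        lat = build_search_region(guide, t, "semi", window)
        assert lat.shape == (31, 31, 31)
        assert lat.contains((0, 0, 0))

    def test_automated_lattice_spans_27_voxels_at_default_spacing(self):
        rng = np.random.default_rng(2)
        guide = VoxelGrid3D(rng.random((120, 120, 120)), spacing_mm=0.55)
        ref = VoxelGrid3D(rng.random((120, 120, 120)), spacing_mm=0.55)
        mask = BinaryMask3D(_ball_mask((120, 120, 120), (60, 60, 60), 8),
                            spacing_mm=0.55)
        t = extract_template(ref, mask)
        lat = build_search_region(guide, t, "automated")
        assert np.all(lat.lo == -27) and np.all(lat.hi == 27)

    def test_clipping_retains_zero(self, random_pair):
        ref, mask = random_pair
        t = extract_template(ref, mask)
        lat = build_search_region(ref, t, "automated",
                                  config=RegistrationConfig(max_shift_mm=40))
        assert lat.contains((0, 0, 0))
        # template bbox is [14, 34]; only +-14 displacements stay inside
        assert np.all(lat.lo == -14) and np.all(lat.hi == 13)

    def test_window_outside_guide_fails(self, random_pair):
        ref, mask = random_pair
        t = extract_template(ref, mask)
        with pytest.raises(RegistrationError, match="outside"):
            build_search_region(ref, t, "semi", ((500, 500, 500), (520, 520, 520)))

    def test_semi_without_window_fails(self, random_pair):
        ref, mask = random_pair
        t = extract_template(ref, mask)
        with pytest.raises(RegistrationError, match="window"):
            build_search_region(ref, t, "semi")


class TestNccVolume:
    def test_self_correlation_is_one(self, random_pair):
        ref, mask = random_pair
        t = extract_template(ref, mask)
        lat = build_search_region(ref, t, "automated",
                                  config=RegistrationConfig(max_shift_mm=3))
        corr = ncc_volume(t, ref, lat)
        center = tuple(-lat.lo)
        assert corr.scores[center] == pytest.approx(1.0, abs=1e-6)
        assert corr.scores[np.isfinite(corr.scores)].max() <= 1.0

    def test_integer_shift_argmax(self, random_pair):
        ref, mask = random_pair
        shifted = VoxelGrid3D(np.roll(ref.values, (3, -2, 5), axis=(0, 1, 2)),
                              spacing_mm=1.0)
        t = extract_template(ref, mask)
        lat = build_search_region(shifted, t, "automated",
                                  config=RegistrationConfig(max_shift_mm=7))
        corr = ncc_volume(t, shifted, lat)
        peak, val, _ = find_peak(corr)
        assert tuple(peak) == (3, -2, 5)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_affine_intensity_invariance(self, random_pair):
        ref, mask = random_pair
        t = extract_template(ref, mask)
        lat = build_search_region(ref, t, "automated",
                                  config=RegistrationConfig(max_shift_mm=4))
        a = ncc_volume(t, ref, lat)
        transformed = VoxelGrid3D(2.0 * ref.values + 10.0, spacing_mm=1.0)
        b = ncc_volume(t, transformed, lat)
        assert np.allclose(a.scores, b.scores, atol=1e-9)

    def test_scores_bounded(self, random_pair):
        ref, mask = random_pair
        t = extract_template(ref, mask)
        lat = build_search_region(ref, t, "automated",
                                  config=RegistrationConfig(max_shift_mm=10))
        corr = ncc_volume(t, ref, lat)
        finite = corr.scores[np.isfinite(corr.scores)]
        assert finite.min() >= -1.0 and finite.max() <= 1.0


class TestRegularize:
    def _volume(self, scores, origin=(-10, -10, -10)):
        return CorrelationVolume(scores, np.asarray(origin), np.ones(3))

    def test_identity_limit(self):
        rng = np.random.default_rng(3)
        corr = self._volume(rng.uniform(-1, 1, (21, 21, 21)))
        out = regularize(corr, Displacement3D(0, 0, 0),
                         RegistrationConfig(lambda_reg=0, smooth_sigma_vox=0))
        assert np.array_equal(out.scores, corr.scores)

    def test_quadratic_penalty_prefers_near_peak(self):
        """0.90 at 8 mm vs 0.85 at 1 mm: lambda=1e-3/mm^2 flips the winner
        (0.90 - 0.064 = 0.836 < 0.85 - 0.001 = 0.849)."""
        scores = np.full((21, 5, 5), -1.0)
        origin = np.array([-10, -2, -2])
        scores[18, 2, 2] = 0.90  # d = (8, 0, 0)
        scores[11, 2, 2] = 0.85  # d = (1, 0, 0)
        corr = CorrelationVolume(scores, origin, np.ones(3))
        out = regularize(corr, Displacement3D(0, 0, 0),
                         RegistrationConfig(lambda_reg=1e-3, smooth_sigma_vox=0))
        assert out.scores[18, 2, 2] == pytest.approx(0.836)
        assert out.scores[11, 2, 2] == pytest.approx(0.849)
        peak, _, _ = find_peak(out)
        assert tuple(peak) == (1, 0, 0)

    def test_peak_distance_non_increasing_in_lambda(self):
        d0 = Displacement3D(0, 0, 0)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            corr = self._volume(rng.uniform(-1, 1, (17, 17, 17)),
                                origin=(-8, -8, -8))
            dists = []
            for lam in np.linspace(0, 0.05, 20):
                cfg = RegistrationConfig(lambda_reg=lam, smooth_sigma_vox=0)
                peak, _, _ = find_peak(regularize(corr, d0, cfg))
                dists.append(np.linalg.norm(peak))
            assert all(b <= a + 1e-12 for a, b in zip(dists, dists[1:]))

    def test_sentinel_preserved(self):
        scores = np.full((5, 5, 5), 0.5)
        scores[0, 0, 0] = -np.inf
        corr = self._volume(scores, origin=(-2, -2, -2))
        out = regularize(corr, Displacement3D(0, 0, 0), RegistrationConfig())
        assert np.isneginf(out.scores[0, 0, 0])


class TestFindPeak:
    def test_single_maximum(self):
        scores = np.zeros((5, 5, 5))
        scores[1, 2, 3] = 1.0
        corr = CorrelationVolume(scores, np.array([-2, -2, -2]), np.ones(3))
        peak, val, edge = find_peak(corr)
        assert tuple(peak) == (-1, 0, 1) and val == 1.0 and not edge

    def test_uniform_ties_break_to_zero(self):
        corr = CorrelationVolume(np.ones((5, 5, 5)), np.array([-2, -2, -2]),
                                 np.ones(3))
        peak, _, _ = find_peak(corr)
        assert tuple(peak) == (0, 0, 0)

    def test_edge_flag(self):
        scores = np.zeros((5, 5, 5))
        scores[0, 2, 2] = 1.0
        corr = CorrelationVolume(scores, np.array([-2, -2, -2]), np.ones(3))
        _, _, edge = find_peak(corr)
        assert edge

    def test_all_sentinel_fails(self):
        corr = CorrelationVolume(np.full((3, 3, 3), -np.inf),
                                 np.array([-1, -1, -1]), np.ones(3))
        with pytest.raises(RegistrationError):
            find_peak(corr)


class TestRefineSubvoxel:
    def _corr(self, triplet):
        scores = np.zeros((3, 3, 3))
        scores[:, 1, 1] = triplet
        scores[1, :, 1] = [triplet[1]] * 3
        scores[1, 1, :] = [triplet[1]] * 3
        return CorrelationVolume(scores, np.array([-1, -1, -1]), np.full(3, 0.55))

    def test_symmetric_neighbors_give_zero(self):
        corr = self._corr([0.8, 1.0, 0.8])
        disp, flags = refine_subvoxel(corr, np.zeros(3, int))
        assert disp.as_array() == pytest.approx([0, 0, 0])

    def test_parabola_vertex(self):
        corr = self._corr([0.8, 1.0, 0.9])
        disp, _ = refine_subvoxel(corr, np.zeros(3, int))
        # delta = (0.8 - 0.9) / (2 * (0.8 - 2 + 0.9)) = 1/6 voxel
        assert disp.d_lr == pytest.approx(0.55 / 6.0, abs=1e-12)

    def test_zero_curvature_flagged(self):
        corr = self._corr([0.9, 1.0, 1.1])  # colinear: curvature 0
        disp, flags = refine_subvoxel(corr, np.zeros(3, int))
        assert disp.d_lr == 0.0
        assert any("zero_curvature" in f for f in flags)

    def test_boundary_peak_keeps_integer(self):
        corr = self._corr([0.8, 1.0, 0.9])
        disp, flags = refine_subvoxel(corr, np.array([-1, 0, 0]))
        assert "edge_peak" in flags
        assert disp.as_array() == pytest.approx([-0.55, 0, 0])

    def test_delta_clamped_to_half_voxel(self):
        corr = self._corr([0.98, 1.0, 0.999])  # near-flat: big raw delta
        disp, _ = refine_subvoxel(corr, np.zeros(3, int))
        assert abs(disp.d_lr) <= 0.5 * 0.55 + 1e-12


class TestMatchEndToEnd:
    def test_identity_match(self, tiny_bundle):
        res = match(
            tiny_bundle.reference, tiny_bundle.rpv_mask, tiny_bundle.reference,
            RegistrationConfig(subvoxel=False),
        )
        assert res.displacement.as_array() == pytest.approx([0, 0, 0])
        assert res.peak_score == 1.0  # direct re-evaluation is exact here
        assert res.method == "automated"

    def test_phantom_truth_recovered(self, bundle64):
        truth = Displacement3D(2.2, -1.1, 3.3)
        guide, _, _ = apply_motion(bundle64, MotionSpec(shift_mm=truth))
        res = match(bundle64.reference, bundle64.rpv_mask, guide)
        err = np.abs(res.displacement.as_array() - truth.as_array())
        assert np.all(err <= 0.25 * 0.55)

    def test_shift_equivariance_integer(self, bundle64):
        spec = bundle64.spec
        rng = np.random.default_rng(4)
        for _ in range(5):
            k = rng.integers(-8, 9, size=3)
            shift = Displacement3D.from_array(k * spec.voxel_mm)
            guide, _, _ = apply_motion(bundle64, MotionSpec(shift_mm=shift))
            res = match(bundle64.reference, bundle64.rpv_mask, guide,
                        RegistrationConfig(subvoxel=False))
            assert res.displacement.as_array() == pytest.approx(
                shift.as_array(), abs=1e-12
            )

    def test_intensity_invariance(self, bundle64):
        guide, _, _ = apply_motion(
            bundle64, MotionSpec(shift_mm=Displacement3D(1.7, -0.6, 2.9))
        )
        base = match(bundle64.reference, bundle64.rpv_mask, guide)
        scaled = VoxelGrid3D(1.7 * guide.values + 8.0, spacing_mm=guide.spacing_mm)
        res = match(bundle64.reference, bundle64.rpv_mask, scaled)
        diff = np.abs(res.displacement.as_array() - base.displacement.as_array())
        assert diff.max() < 1e-6

    def test_oracle_equivalence_unregularized(self):
        """lambda=0, sigma=0, subvoxel off: the matcher must equal the
        exhaustive brute-force weighted-NCC argmax exactly."""
        from echomatch import PhantomSpec, generate_reference

        cfg = RegistrationConfig(lambda_reg=0.0, smooth_sigma_vox=0.0,
                                 subvoxel=False, max_shift_mm=5 * 0.55)
        for seed in range(3):
            b = generate_reference(PhantomSpec(
                grid_shape=(32, 32, 32), prostate_semi_axes_mm=(3.5, 3.2, 3.4),
                n_landmarks=1, seed=seed,
            ))
            guide, _, _ = apply_motion(b, MotionSpec(
                shift_mm=Displacement3D(1.1, -1.65, 0.55),
                decorrelation_rho=0.8, noise_seed=seed,
            ))
            res = match(b.reference, b.rpv_mask, guide, cfg)
            t = extract_template(b.reference, b.rpv_mask)
            lo, _ = b.rpv_mask.bounding_box()
            d_brute, _ = brute_argmax_ncc(
                t.crop.values, t.weights, guide.values, lo, [-5] * 3, [5] * 3
            )
            assert np.array_equal(
                np.rint(res.displacement.as_array() / 0.55).astype(int), d_brute
            )

    def test_constant_guide_fails(self, tiny_bundle):
        flat = VoxelGrid3D(np.ones(tiny_bundle.reference.shape),
                           spacing_mm=tiny_bundle.reference.spacing_mm)
        with pytest.raises(RegistrationError):
            match(tiny_bundle.reference, tiny_bundle.rpv_mask, flat)

    def test_low_score_flag(self, tiny_bundle):
        rng = np.random.default_rng(9)
        noise = VoxelGrid3D(rng.random(tiny_bundle.reference.shape),
                            spacing_mm=tiny_bundle.reference.spacing_mm)
        res = match(tiny_bundle.reference, tiny_bundle.rpv_mask, noise)
        assert "low_score" in res.flags


class TestMatchSummary:
    def test_zero_shift_contours_coincide(self, tiny_bundle):
        res = match(tiny_bundle.reference, tiny_bundle.rpv_mask,
                    tiny_bundle.reference, RegistrationConfig(subvoxel=False))
        s = match_summary(tiny_bundle.reference, tiny_bundle.reference,
                          tiny_bundle.rpv_mask, res)
        assert np.array_equal(s.rpv_sagittal_outline, s.gpv_sagittal_outline)
        assert np.array_equal(s.rpv_coronal_outline, s.gpv_coronal_outline)

    def test_shifted_contour_displaced_in_coronal_panel(self, bundle64):
        shift = Displacement3D(10 * 0.55, 0, 0)
        guide, _, _ = apply_motion(bundle64, MotionSpec(shift_mm=shift))
        res = match(bundle64.reference, bundle64.rpv_mask, guide,
                    RegistrationConfig(subvoxel=False))
        s = match_summary(bundle64.reference, guide, bundle64.rpv_mask, res)
        # coronal panels are (LR, SI) images: GPV columns = RPV columns + 10
        rpv_cols = np.nonzero(s.rpv_coronal_outline.any(axis=1))[0]
        gpv_cols = np.nonzero(s.gpv_coronal_outline.any(axis=1))[0]
        assert gpv_cols.min() == rpv_cols.min() + 10
        assert gpv_cols.max() == rpv_cols.max() + 10

    def test_correlation_panel_peak_matches_result(self, bundle64, tmp_path):
        shift = Displacement3D(2 * 0.55, -3 * 0.55, 0.55)
        guide, _, _ = apply_motion(bundle64, MotionSpec(shift_mm=shift))
        res = match(bundle64.reference, bundle64.rpv_mask, guide,
                    RegistrationConfig(subvoxel=False))
        s = match_summary(bundle64.reference, guide, bundle64.rpv_mask, res)
        d_vox = np.rint(res.displacement.as_array() / 0.55).astype(int)
        expected = d_vox[:2] - res.correlation.lattice_origin[:2]
        assert s.corr_peak_rc == tuple(expected)
        assert np.unravel_index(np.argmax(s.corr_slice), s.corr_slice.shape) == (
            tuple(expected)
        )
        s.save(tmp_path / "summary.png")  # renders without error
        assert (tmp_path / "summary.png").stat().st_size > 0
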