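"""Registration, fluorescence ROI, surface interpolation, VOI masking."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from svdose import voi
from svdose.svoct import AngioVolume
from svdose.voi import FiducialSet, SimilarityTransform


def _umeyama_complex(src, dst):
    """Closed-form similarity fit via complex least squares (cross-check).

    Writing points as complex numbers z, the proper similarity is
    w = a z + b; least squares gives a, b in closed form.
    """
    z = src[:, 0] + 1j * src[:, 1]
    w = dst[:, 0] + 1j * dst[:, 1]
    zc, wc = z - z.mean(), w - w.mean()
    a = np.vdot(zc, wc) / np.vdot(zc, zc)
    b = w.mean() - a * z.mean()
    return abs(a), np.rad2deg(np.angle(a)), (b.real, b.imag)


class TestEstimateSimilarity:
    def _pairs(self, tf, n=6, seed=0, jitter=0.0):
        rng = np.random.default_rng(seed)
        src = rng.uniform(0, 100, size=(n, 2))
        dst = tf.apply(src) + jitter * rng.normal(size=(n, 2))
        return FiducialSet(source=src, target=dst)

    def test_recovers_known_transform_exactly(self):
        tf = SimilarityTransform(1.1, 15.0, (8.0, -5.0))
        got = voi.estimate_similarity(self._pairs(tf))
        assert got.scale == pytest.approx(1.1, abs=1e-9)
        assert got.rotation_deg == pytest.approx(15.0, abs=1e-9)
        assert got.translation[0] == pytest.approx(8.0, abs=1e-9)
        assert got.translation[1] == pytest.approx(-5.0, abs=1e-9)
        assert got.residual_rms <= 1e-9

    def test_identity_pairs(self):
        src = np.array([[0.0, 0.0], [10.0, 0.0], [3.0, 7.0]])
        got = voi.estimate_similarity(FiducialSet(source=src, target=src.copy()))
        assert got.scale == pytest.approx(1.0, abs=1e-12)
        assert got.rotation_deg == pytest.approx(0.0, abs=1e-12)
        assert got.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_closed_form(self):
        tf = SimilarityTransform(0.8, -30.0, (2.0, 4.0))
        fids = self._pairs(tf, n=8, jitter=0.3, seed=3)
        got = voi.estimate_similarity(fids)
        s, r, t = _umeyama_complex(fids.source, fids.target)
        assert got.scale == pytest.approx(s, abs=1e-9)
        assert got.rotation_deg == pytest.approx(r, abs=1e-9)
        assert got.translation == pytest.approx(t, abs=1e-6)

    def test_jittered_fiducials_monte_carlo(self):
        """RMS bounded by 3 sigma; parameter error shrinks with more pairs."""
        tf = SimilarityTransform(1.05, 10.0, (3.0, -2.0))
        sigma = 0.5
        errs = {6: [], 50: []}
        for n in errs:
            for trial in range(100):
                fids = self._pairs(tf, n=n, seed=1000 + trial, jitter=sigma)
                got = voi.estimate_similarity(fids)
                assert got.residual_rms <= 3 * sigma
                errs[n].append(abs(got.scale - tf.scale)
                               + abs(got.rotation_deg - tf.rotation_deg) / 60.0)
        assert np.mean(errs[50]) < np.mean(errs[6])

    def test_degenerate_pairs_rejected(self):
        src = np.array([[5.0, 5.0], [5.0, 5.0]])
        with pytest.raises(ValueError):
            voi.estimate_similarity(FiducialSet(source=src, target=src.copy()))
        with pytest.raises(ValueError):
            FiducialSet(source=np.array([[1.0, 2.0]]), target=np.array([[1.0, 2.0]]))

    @given(st.integers(0, 500))
    def test_roundtrip_recovery_property(self, seed):
        rng = np.random.default_rng(seed)
        tf = SimilarityTransform(
            float(rng.uniform(0.5, 2.0)), float(rng.uniform(-180, 180)),
            tuple(rng.uniform(-20, 20, 2)),
        )
        src = rng.uniform(0, 50, size=(5, 2))
        got = voi.estimate_similarity(FiducialSet(source=src, target=tf.apply(src)))
        # composition with the inverse is the identity
        back = got.inverse().apply(tf.apply(src))
        assert np.max(np.abs(back - src)) < 1e-6


class TestBinarizeFluorescence:
    def test_uniform_bright_image_all_true(self):
        img = np.full((10, 12), 200, dtype=np.uint8)
        assert voi.binarize_fluorescence(img).all()

    def test_separable_intensities_recover_footprint(self):
        footprint = np.zeros((20, 20), dtype=bool)
        footprint[5:15, 4:16] = True
        img = np.where(footprint, 200, 20).astype(np.uint8)
        assert np.array_equal(voi.binarize_fluorescence(img), footprint)

    def test_largest_component_retained(self):
        img = np.zeros((60, 60), dtype=np.uint8)
        img[5:45, 5:30] = 200  # 1000 px
        img[50:58, 50:55] = 200  # 40 px speck
        mask = voi.binarize_fluorescence(img)
        assert mask[10, 10] and not mask[52, 52]
        assert mask.sum() == 40 * 25

    def test_holes_filled(self):
        img = np.zeros((20, 20), dtype=np.uint8)
        img[2:18, 2:18] = 200
        img[8:10, 8:10] = 0  # interior hole
        assert voi.binarize_fluorescence(img)[8, 8]

    def test_empty_mask_is_error(self):
        with pytest.raises(ValueError, match="threshold"):
            voi.binarize_fluorescence(np.full((5, 5), 10, dtype=np.uint8))


class TestWarpMask:
    def test_identity(self):
        rng = np.random.default_rng(2)
        mask = rng.uniform(size=(12, 9)) > 0.5
        tf = SimilarityTransform(1.0, 0.0, (0.0, 0.0))
        assert np.array_equal(voi.warp_mask(mask, tf, mask.shape), mask)

    def test_pure_translation_pixel_exact(self):
        mask = np.zeros((30, 20), dtype=bool)
        mask[3:8, 4:9] = True
        tf = SimilarityTransform(1.0, 0.0, (10.0, 0.0))
        out = voi.warp_mask(mask, tf, mask.shape)
        expected = np.zeros_like(mask)
        expected[13:18, 4:9] = True
        assert np.array_equal(out, expected)

    def test_rotation_90_matches_hand_rotated(self):
        # an asymmetric L-shape rotated 90 degrees about the origin with a
        # translation that brings it back into frame
        mask = np.zeros((8, 8), dtype=bool)
        mask[1:6, 1:3] = True
        mask[4:6, 1:5] = True
        tf = SimilarityTransform(1.0, 90.0, (7.0, 0.0))
        out = voi.warp_mask(mask, tf, (8, 8))
        # hand-rotation: (x, y) -> (7 - y, x)
        expected = np.zeros((8, 8), dtype=bool)
        xs, ys = np.nonzero(mask)
        expected[7 - ys, xs] = True
        assert np.array_equal(out, expected)

    def test_out_of_bounds_false(self):
        mask = np.ones((5, 5), dtype=bool)
        tf = SimilarityTransform(1.0, 0.0, (100.0, 100.0))
        assert not voi.warp_mask(mask, tf, (5, 5)).any()


class TestInterpolateSurface:
    def test_linear_midpoint(self):
        c0 = (0, np.full(4, 10.0))
        c1 = (20, np.full(4, 30.0))
        dense = voi.interpolate_surface([c0, c1], 21)
        assert np.allclose(dense[:, 10], 20.0)

    def test_identical_contours_constant(self):
        prof = np.array([5.0, 6.0, 7.0])
        dense = voi.interpolate_surface([(0, prof), (20, prof)], 25)
        assert np.allclose(dense, prof[:, None])

    def test_constant_extrapolation(self):
        dense = voi.interpolate_surface(
            [(5, np.full(2, 10.0)), (15, np.full(2, 20.0))], 25
        )
        assert np.allclose(dense[:, :5], 10.0)
        assert np.allclose(dense[:, 16:], 20.0)

    def test_tilted_plane_recovered(self):
        """Three contours sampled from a plane reproduce it to <= 1 voxel."""
        x = np.arange(16)
        plane = lambda y: 5.0 + 0.3 * x + 0.4 * y
        contours = [(y, plane(y)) for y in (0, 20, 40)]
        dense = voi.interpolate_surface(contours, 41)
        truth = np.stack([plane(y) for y in range(41)], axis=1)
        assert np.max(np.abs(dense - truth)) <= 1.0

    def test_single_contour_warns_constant(self):
        with pytest.warns(UserWarning, match="single contour"):
            dense = voi.interpolate_surface([(0, np.full(3, 9.0))], 10)
        assert np.allclose(dense, 9.0)


class TestBuildVOI:
    def test_full_roi_zero_surface(self):
        mask = voi.build_voi(np.ones((4, 5), bool), np.zeros((4, 5)), 6).mask
        assert mask.all() and mask.shape == (4, 5, 6)

    def test_empty_roi(self):
        assert not voi.build_voi(np.zeros((4, 5), bool), np.zeros((4, 5)), 6).mask.any()

    def test_below_surface_only(self):
        surf = np.full((3, 3), 4.0)
        mask = voi.build_voi(np.ones((3, 3), bool), surf, 8).mask
        assert not mask[:, :, :4].any() and mask[:, :, 4:].all()

    @given(st.integers(0, 200))
    def test_monotone_in_roi(self, seed):
        rng = np.random.default_rng(seed)
        roi2 = rng.uniform(size=(6, 6)) > 0.4
        roi1 = roi2 & (rng.uniform(size=(6, 6)) > 0.4)
        surf = rng.uniform(0, 5, size=(6, 6))
        m1 = voi.build_voi(roi1, surf, 8).mask
        m2 = voi.build_voi(roi2, surf, 8).mask
        assert not (m1 & ~m2).any()


class TestMaskAndResize:
    def _vol(self, arr):
        return AngioVolume(variance=arr, voxel_pitch_um=(1, 1, 1),
                           mouse_id="L1", day=17, dose_class="low")

    def test_same_target_masks_only(self):
        rng = np.random.default_rng(1)
        arr = rng.uniform(1, 2, size=(8, 8, 8))
        m = voi.build_voi(np.ones((8, 8), bool), np.full((8, 8), 4.0), 8)
        out = voi.mask_and_resize(self._vol(arr), m, (8, 8, 8))
        assert out.volume.shape == (8, 8, 8)
        assert not out.volume[:, :, :4].any()
        # masking + rescale only: proportional to the masked input
        masked = np.where(m.mask, arr, 0)
        assert np.allclose(out.volume, masked / masked.max(), atol=1e-6)

    def test_constant_volume_rescales_to_one(self):
        m = voi.build_voi(np.ones((8, 8), bool), np.zeros((8, 8)), 8)
        out = voi.mask_and_resize(self._vol(np.full((8, 8, 8), 3.7)), m, (4, 4, 4))
        assert np.allclose(out.volume, 1.0)

    def test_zero_volume_stays_zero(self):
        m = voi.build_voi(np.ones((4, 4), bool), np.zeros((4, 4)), 4)
        out = voi.mask_and_resize(self._vol(np.zeros((4, 4, 4))), m, (4, 4, 4))
        assert not out.volume.any()

    def test_values_in_unit_interval_and_provenance(self):
        rng = np.random.default_rng(9)
        arr = rng.exponential(size=(16, 8, 12))
        roi = np.zeros((16, 8), bool)
        roi[4:12, 2:6] = True
        m = voi.build_voi(roi, np.full((16, 8), 2.0), 12)
        out = voi.mask_and_resize(self._vol(arr), m, (8, 8, 8))
        assert out.volume.min() >= 0.0 and out.volume.max() <= 1.0
        assert (out.mouse_id, out.day, out.dose_class) == ("L1", 17, "low")

    def test_shape_mismatch_rejected(self):
        m = voi.build_voi(np.ones((4, 4), bool), np.zeros((4, 4)), 4)
        with pytest.raises(ValueError, match="shape"):
            voi.mask_and_resize(self._vol(np.zeros((5, 4, 4))), m, (4, 4, 4))
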