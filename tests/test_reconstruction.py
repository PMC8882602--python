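"""Inverse mirroring, polar spline fitting, and compensation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cutmirror.augmentation import CutSpec, cut_diag, cut_hv, dcma, hvcma, snap_center
from cutmirror.metrics import dice
from cutmirror.reconstruction import (
    CompensationSpec,
    PolarBoundary,
    SplineConfig,
    assemble_quadrants,
    combine_complex,
    extract_boundary,
    fit_and_intercept,
    invert_quadrant,
    reconstruct_complex,
    reconstruct_single,
    to_polar,
    triple_expand,
)
from cutmirror.synthetic import PhantomSpec, make_phantom
from conftest import random_mask


class TestInvertQuadrant:
    @settings(deadline=None, max_examples=30)
    @given(h=st.integers(4, 20), w=st.integers(4, 20), data=st.data())
    def test_hv_round_trip_is_exact(self, h, w, data):
        """Forward HVCMA then inversion reproduces every quadrant of a
        random mask bit-exactly, four times over."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
        mask = random_mask(rng, (h, w))
        r = data.draw(st.integers(1, h - 1))
        c = data.draw(st.integers(1, w - 1))
        cut = CutSpec(float(r), float(c), r, c)
        aug = hvcma(mask, cut)
        qs = cut_hv(mask, cut)
        for label in aug.images:
            for est in invert_quadrant(aug.images[label], aug.meta[label]):
                np.testing.assert_array_equal(est, qs.parts[label].astype(bool))

    @settings(deadline=None, max_examples=30)
    @given(h=st.integers(4, 20), w=st.integers(4, 20), data=st.data())
    def test_diag_round_trip_is_exact(self, h, w, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
        mask = random_mask(rng, (h, w))
        r = data.draw(st.integers(1, h - 1))
        c = data.draw(st.integers(1, w - 1))
        cut = CutSpec(float(r), float(c), r, c)
        aug = dcma(mask, cut)
        from cutmirror.augmentation import pad_to_centered_square

        padded, _ = pad_to_centered_square(mask, cut)
        qs = cut_diag(padded)
        for label in aug.images:
            for est in invert_quadrant(aug.images[label], aug.meta[label]):
                np.testing.assert_array_equal(est, qs.parts[label].astype(bool))

    def test_zeroed_block_gives_one_empty_estimate(self):
        mask = np.ones((6, 6), bool)
        cut = CutSpec(3.0, 3.0, 3, 3)
        aug = hvcma(mask, cut)
        seg = aug.images["br"].copy()
        seg[:3, :3] = 0  # kill the top-left block only
        estimates = invert_quadrant(seg, aug.meta["br"])
        empties = [not e.any() for e in estimates]
        assert sum(empties) == 1

    def test_shape_mismatch_rejected(self):
        mask = np.ones((6, 6), bool)
        aug = hvcma(mask, CutSpec(3.0, 3.0, 3, 3))
        with pytest.raises(ValueError, match="shape"):
            invert_quadrant(np.ones((4, 4), bool), aug.meta["br"])

    def test_estimates_have_quadrant_shape(self):
        mask = random_mask(np.random.default_rng(0), (9, 7))
        cut = CutSpec(4.0, 3.0, 4, 3)
        aug = hvcma(mask, cut)
        for est in invert_quadrant(aug.images["tr"], aug.meta["tr"]):
            assert est.shape == (4, 4)  # rows [0,4) x cols [3,7)


class TestExtractBoundary:
    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        contour = extract_boundary(m)
        assert len(contour) > 0
        # all vertices within the pixel's half-open boundary square
        assert np.all(np.abs(contour - 2.0) <= 0.5 + 1e-9)

    def test_filled_square_perimeter(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 7:17] = True
        contour = extract_boundary(m)
        assert contour[:, 0].min() >= 4.0 and contour[:, 0].max() <= 15.0
        assert contour[:, 1].min() >= 6.0 and contour[:, 1].max() <= 17.0
        # contour encloses the block: spans at least its extent
        assert contour[:, 0].max() - contour[:, 0].min() >= 9
        assert contour[:, 1].max() - contour[:, 1].min() >= 9

    def test_largest_component_only(self):
        m = np.zeros((20, 20), bool)
        m[2:12, 2:7] = True  # 50 px
        m[16, 16:19] = True  # 3 px
        contour = extract_boundary(m)
        assert contour[:, 1].max() < 8  # never visits the small blob

    def test_empty_mask(self):
        assert extract_boundary(np.zeros((4, 4), bool)).shape == (0, 2)


class TestToPolar:
    def test_point_right_of_center(self):
        pb = to_polar(np.array([[5.0, 9.0]]), center=(5.0, 5.0))
        assert pb.thetas[0] == pytest.approx(0.0)
        assert pb.radii[0] == pytest.approx(4.0)

    def test_point_above_center_positive_angle(self):
        pb = to_polar(np.array([[2.0, 5.0]]), center=(5.0, 5.0))
        assert pb.thetas[0] == pytest.approx(math.pi / 2)

    def test_3_4_5_triangle(self):
        pb = to_polar(np.array([[8.0, 9.0]]), center=(5.0, 5.0))
        assert pb.radii[0] == pytest.approx(5.0)
        assert pb.thetas[0] == pytest.approx(math.atan2(-3, 4))

    def test_center_point_flagged(self):
        pb = to_polar(np.array([[5.0, 5.0], [5.0, 7.0]]), center=(5.0, 5.0))
        assert pb.n_center_points == 1
        assert np.all(np.diff(pb.thetas) >= 0)


class TestTripleExpand:
    def test_three_copies_sorted(self):
        pb = PolarBoundary((0, 0), np.array([-1.0, 0.5, 2.0]), np.array([3.0, 4.0, 5.0]))
        tt, rr = triple_expand(pb)
        assert tt.size == 9 and rr.size == 9
        assert np.all(np.diff(tt) >= 0)
        assert tt.min() == pytest.approx(-1.0 - 2 * math.pi)
        assert set(np.round(rr, 6)) == {3.0, 4.0, 5.0}

    def test_empty_rejected(self):
        pb = PolarBoundary((0, 0), np.array([]), np.array([]))
        with pytest.raises(ValueError, match="no boundary points"):
            triple_expand(pb)


class TestFitAndIntercept:
    def test_circle_samples_recovered(self):
        t = np.linspace(-math.pi, math.pi, 72, endpoint=False)
        pb = PolarBoundary((0, 0), t, np.full(72, 10.0))
        tt, rr = triple_expand(pb)
        fitted = fit_and_intercept(tt, rr, SplineConfig(smoothing_p=0.99, n_samples=360))
        assert np.all(np.abs(fitted.radii - 10.0) < 0.1)

    def test_p_one_interpolates(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(-math.pi, math.pi, 40))
        r = 10 + np.sin(2 * t)
        pb = PolarBoundary((0, 0), t, r)
        tt, rr = triple_expand(pb)
        fitted_spline_cfg = SplineConfig(smoothing_p=1.0, n_samples=720)
        from scipy.interpolate import make_smoothing_spline

        spline = make_smoothing_spline(tt, rr, lam=0.0)
        assert np.allclose(spline(t), r, atol=1e-8)

    def test_radii_nonnegative(self):
        t = np.linspace(-math.pi, math.pi, 50, endpoint=False)
        r = np.where(np.abs(t) < 0.3, 0.0, 5.0)  # sharp dip toward zero
        pb = PolarBoundary((0, 0), t, r)
        tt, rr = triple_expand(pb)
        fitted = fit_and_intercept(tt, rr, SplineConfig(smoothing_p=0.9))
        assert np.all(fitted.radii >= 0)

    def test_period3_consistency(self):
        """On periodic input the fitted spline nearly repeats at +/- 2*pi
        inside the fitted span."""
        t = np.linspace(-math.pi, math.pi, 90, endpoint=False)
        r = 12 + 2 * np.cos(3 * t)
        pb = PolarBoundary((0, 0), t, r)
        tt, rr = triple_expand(pb)
        from scipy.interpolate import make_smoothing_spline

        spline = make_smoothing_spline(tt, rr, lam=(1 - 0.99) / 0.99)
        probe = np.linspace(-2.0, 2.0, 41)
        assert np.allclose(spline(probe), spline(probe + 2 * math.pi), atol=0.05)
        assert np.allclose(spline(probe), spline(probe - 2 * math.pi), atol=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_and_intercept(np.array([0.0, 1.0]), np.array([1.0, 1.0]), SplineConfig())

    def test_single_period_rejected(self):
        t = np.linspace(-3, 3, 30)
        with pytest.raises(ValueError, match="period"):
            fit_and_intercept(t, np.ones(30), SplineConfig())


def oracle_segmentations(mask, cut, mode):
    """Forward-augment the ground truth: the perfect segmenter."""
    fwd = hvcma if mode == "hv" else dcma
    aug = fwd(mask, cut)
    return {label: aug.images[label].astype(bool) for label in aug.images}, aug.meta


class TestReconstructSingle:
    @pytest.mark.parametrize("mode", ["hv", "diag"])
    def test_disc_oracle_round_trip(self, disc_phantom, mode):
        _, mask = disc_phantom
        cut = snap_center(mask)
        segs, meta = oracle_segmentations(mask, cut, mode)
        rec = reconstruct_single(segs, meta, cut, SplineConfig())
        assert dice(mask, rec.mask) >= 0.98

    @pytest.mark.parametrize("mode", ["hv", "diag"])
    def test_rotated_ellipse_oracle_round_trip(self, ellipse_phantom, mode):
        _, mask = ellipse_phantom
        cut = snap_center(mask)
        segs, meta = oracle_segmentations(mask, cut, mode)
        rec = reconstruct_single(segs, meta, cut, SplineConfig())
        assert dice(mask, rec.mask) >= 0.97

    def test_translation_equivariance(self):
        spec_a = PhantomSpec(height=128, width=128, center=(64.0, 64.0),
                             axes=(20.0, 14.0), boundary_roughness=0.0,
                             speckle_sigma=0.0, seed=9)
        spec_b = PhantomSpec(height=128, width=128, center=(54.0, 76.0),
                             axes=(20.0, 14.0), boundary_roughness=0.0,
                             speckle_sigma=0.0, seed=9)
        scores = []
        for spec in (spec_a, spec_b):
            _, mask = make_phantom(spec)
            cut = snap_center(mask)
            segs, meta = oracle_segmentations(mask, cut, "hv")
            rec = reconstruct_single(segs, meta, cut, SplineConfig())
            scores.append(dice(mask, rec.mask))
        assert scores[0] == pytest.approx(scores[1], abs=1e-3)

    def test_all_empty_raises(self):
        mask = np.zeros((32, 32), bool)
        mask[10:20, 10:20] = True
        cut = snap_center(mask)
        aug = hvcma(mask, cut)
        empty = {label: np.zeros_like(aug.images[label], dtype=bool)
                 for label in aug.images}
        with pytest.raises(ValueError, match="no tumor"):
            reconstruct_single(empty, aug.meta, cut, SplineConfig())


class TestCompensationSpec:
    def test_u_measure_is_8h(self):
        comp = CompensationSpec(h=math.pi / 9)
        assert comp.measure == pytest.approx(8 * math.pi / 9)

    def test_u_and_complement_partition(self):
        comp = CompensationSpec(h=math.pi / 9)
        t = np.linspace(-math.pi, math.pi, 100001)
        inside = comp.contains(t)
        # measure check by uniform sampling: |U| / 2pi == 8h / 2pi
        assert inside.mean() == pytest.approx((8 * comp.h) / (2 * math.pi), abs=1e-3)

    def test_overlapping_h_rejected(self):
        with pytest.raises(ValueError):
            CompensationSpec(h=math.pi / 3)


class TestCombineComplex:
    def _pb(self, r_fn, source):
        t = np.linspace(-math.pi, math.pi, 120, endpoint=False)
        return PolarBoundary((0.0, 0.0), t, r_fn(t), source=source)

    def test_identical_inputs_pass_through(self):
        hv = self._pb(lambda t: np.full_like(t, 8.0), "hv")
        dg = self._pb(lambda t: np.full_like(t, 8.0), "diag")
        out = combine_complex(hv, dg, CompensationSpec())
        assert np.all(out.radii == 8.0)
        assert out.source == "combined"

    def test_theta_determines_source(self):
        hv = self._pb(lambda t: np.full_like(t, 5.0), "hv")
        dg = self._pb(lambda t: np.full_like(t, 9.0), "diag")
        comp = CompensationSpec()
        out = combine_complex(hv, dg, comp)
        in_u = comp.contains(out.thetas)
        assert np.all(out.radii[in_u] == 9.0)
        assert np.all(out.radii[~in_u] == 5.0)

    def test_h_zero_degenerates_to_hv(self):
        hv = self._pb(lambda t: 6 + np.cos(t), "hv")
        dg = self._pb(lambda t: np.full_like(t, 99.0), "diag")
        out = combine_complex(hv, dg, CompensationSpec(h=0.0))
        # U degenerates to the five exact cut angles (measure zero);
        # everywhere else the samples come from the HV cloud
        cut_angles = np.array([-math.pi, -math.pi / 2, 0.0, math.pi / 2, math.pi])
        on_cut = np.min(np.abs(out.thetas[:, None] - cut_angles[None, :]), axis=1) < 1e-12
        assert np.all(out.radii[~on_cut] < 99.0)
        assert np.count_nonzero(on_cut) <= 5

    def test_empty_region_falls_back(self):
        # diag cloud has no samples inside U at all
        t_out = np.array([0.8, 1.0, 2.0, -2.0, -1.0])
        dg = PolarBoundary((0.0, 0.0), t_out, np.full(5, 7.0), source="diag")
        hv = self._pb(lambda t: np.full_like(t, 5.0), "hv")
        out = combine_complex(hv, dg, CompensationSpec())
        assert len(out) > 0
        assert np.all(np.isfinite(out.radii))


class TestReconstructComplex:
    def test_disc_not_degraded_by_compensation(self, disc_phantom):
        _, mask = disc_phantom
        cut = snap_center(mask)
        segs_hv, meta_hv = oracle_segmentations(mask, cut, "hv")
        segs_dg, meta_dg = oracle_segmentations(mask, cut, "diag")
        d_hv = dice(mask, reconstruct_single(segs_hv, meta_hv, cut, SplineConfig()).mask)
        d_dg = dice(mask, reconstruct_single(segs_dg, meta_dg, cut, SplineConfig()).mask)
        rec = reconstruct_complex(segs_hv, meta_hv, segs_dg, meta_dg, cut, SplineConfig())
        d_cx = dice(mask, rec.mask)
        assert d_cx >= 0.98
        assert d_cx >= min(d_hv, d_dg) - 0.01

    def test_corruption_inside_u_is_compensated(self, disc_phantom):
        """Dilating the HV segmentations only near theta = 0 (inside U)
        hurts single-mode reconstruction; complex mode replaces that
        angular region with clean DIAG data and must do better."""
        from cutmirror.synthetic import SegmenterSpec, segment

        _, mask = disc_phantom
        cut = snap_center(mask)
        segs_hv, meta_hv = oracle_segmentations(mask, cut, "hv")
        corrupt = SegmenterSpec(kind="perturbed_oracle", perturb_radius=5,
                                band_angles=(0.0,), band_halfwidth=math.pi / 9, seed=11)
        segs_hv = {label: segment(None, segs_hv[label], corrupt)
                   for label in segs_hv}
        segs_dg, meta_dg = oracle_segmentations(mask, cut, "diag")
        d_single = dice(mask, reconstruct_single(segs_hv, meta_hv, cut, SplineConfig()).mask)
        d_complex = dice(mask, reconstruct_complex(
            segs_hv, meta_hv, segs_dg, meta_dg, cut, SplineConfig()).mask)
        assert d_complex > d_single

    def test_discontinuous_cloud_fits_without_failure(self):
        """The combined cloud may jump at U's endpoints; the spline must
        absorb the jumps and stay finite."""
        t = np.linspace(-math.pi, math.pi, 200, endpoint=False)
        hv = PolarBoundary((0.0, 0.0), t, np.full_like(t, 10.0), source="hv")
        dg = PolarBoundary((0.0, 0.0), t, np.full_like(t, 16.0), source="diag")
        combined = combine_complex(hv, dg, CompensationSpec())
        tt, rr = triple_expand(combined)
        fitted = fit_and_intercept(tt, rr, SplineConfig(smoothing_p=0.99))
        assert np.all(np.isfinite(fitted.radii))
        assert np.all(fitted.radii >= 0)


class TestStarShapedExactness:
    def test_dice_improves_with_sampling_density(self, disc_phantom):
        _, mask = disc_phantom
        cut = snap_center(mask)
        segs, meta = oracle_segmentations(mask, cut, "hv")
        coarse = dice(mask, reconstruct_single(segs, meta, cut,
                                               SplineConfig(n_samples=24)).mask)
        fine = dice(mask, reconstruct_single(segs, meta, cut,
                                             SplineConfig(n_samples=720)).mask)
        assert fine >= coarse
        assert fine >= 0.99
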