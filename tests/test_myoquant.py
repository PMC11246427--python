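"""Myotube mask, myogenic index, and orientation-order statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import i0, i1

from micropat import (
    coherency_score,
    local_orientation,
    myogenic_index,
    myotube_mask,
    orientation_histogram,
    orientation_order_parameter,
    straighten_along_polyline,
)
from micropat.myoquant import HIST_BIN_EDGES, OrientationHistogram

from conftest import stripe_image


def oop_from_angles(angles_deg, weights=None):
    """Independent oracle: per-sample doubled-angle order-tensor averaging."""
    th = np.radians(np.asarray(angles_deg, float)) * 2.0
    w = np.ones_like(th) if weights is None else np.asarray(weights, float)
    C = (w * np.cos(th)).sum() / w.sum()
    S = (w * np.sin(th)).sum() / w.sum()
    return float(np.hypot(C, S))


class TestMyotubeMask:
    def test_blank_channel(self):
        mask, count = myotube_mask(np.zeros((32, 32)))
        assert not mask.any() and count == 0

    def test_counts_ribbons_but_not_specks(self):
        img = np.zeros((120, 120))
        img[10:20, 5:115] = 100.0  # three 10x110 ribbons
        img[50:60, 5:115] = 100.0
        img[90:100, 5:115] = 100.0
        img[35, 35] = 100.0  # two sub-size specks
        img[70:72, 70:72] = 100.0
        mask, count = myotube_mask(img, threshold=50.0, min_size_px=200)
        assert count == 3

    def test_count_monotone_in_min_size(self):
        rng = np.random.default_rng(0)
        img = (rng.random((100, 100)) < 0.3).astype(float) * 100
        counts = [
            myotube_mask(img, threshold=50.0, min_size_px=s)[1] for s in (1, 5, 20, 80)
        ]
        assert counts == sorted(counts, reverse=True)


class TestMyogenicIndex:
    def _nuclei(self, rows, cols):
        return pd.DataFrame({"row_px": rows, "col_px": cols})

    def test_three_of_ten_inside(self):
        mask = np.zeros((20, 20), bool)
        mask[:10, :10] = True
        nuclei = self._nuclei([1, 2, 3, 15, 15, 15, 15, 15, 15, 15], [1, 2, 3] + [15] * 7)
        res = myogenic_index(nuclei, mask)
        assert res.nuclei_total == 10 and res.nuclei_in_myotubes == 3
        assert res.myogenic_index == pytest.approx(0.3)

    def test_region_mask_excludes_nuclei(self):
        mask = np.ones((10, 10), bool)
        region = np.zeros((10, 10), bool)
        region[:, 5:] = True
        nuclei = self._nuclei([1, 2, 3], [0, 1, 7])
        res = myogenic_index(nuclei, mask, region_mask=region, region="on")
        assert res.nuclei_total == 1 and res.myogenic_index == 1.0

    def test_zero_nuclei_flagged_undefined(self):
        res = myogenic_index(self._nuclei([], []), np.zeros((5, 5), bool))
        assert res.undefined and np.isnan(res.myogenic_index)

    def test_label_raster_input(self):
        labels = np.zeros((20, 20), int)
        labels[2:5, 2:5] = 1
        labels[12:15, 12:15] = 2
        mask = np.zeros((20, 20), bool)
        mask[:8, :8] = True
        res = myogenic_index(labels, mask)
        assert res.nuclei_total == 2 and res.nuclei_in_myotubes == 1


class TestLocalOrientation:
    @pytest.mark.parametrize("angle", [0.0, 30.0, 60.0, -45.0])
    def test_stripe_modal_orientation(self, angle):
        field = local_orientation(stripe_image(angle), tensor_sigma=3)
        hist = orientation_histogram(field, weight="energy")
        mode = hist.bin_centers[np.argmax(hist.counts)]
        assert abs(mode - angle) <= 1.0

    def test_rotation_by_90_shifts_orientation(self):
        img = stripe_image(30.0)
        rot = np.rot90(img)  # 90-degree CCW rotation: 30 -> -60 (mod 180)
        f = local_orientation(rot, tensor_sigma=3)
        hist = orientation_histogram(f, weight="energy")
        mode = hist.bin_centers[np.argmax(hist.counts)]
        assert abs(mode - (-60.0)) <= 1.0

    def test_isotropic_noise_has_low_coherency(self):
        rng = np.random.default_rng(1)
        field = local_orientation(rng.normal(size=(256, 256)), tensor_sigma=8)
        assert field.mean_coherency < 0.25

    def test_constant_image_all_invalid(self):
        field = local_orientation(np.full((32, 32), 3.0))
        assert not field.valid.any()
        assert np.all(field.energy == 0)


class TestOrientationHistogram:
    def test_single_angle_single_bin(self):
        hist = orientation_histogram(np.full((16, 16), 0.1))
        assert hist.counts[hist.counts > 0].size == 1
        # 0.1 deg falls in the [0, 0.5) bin
        assert hist.counts[np.searchsorted(HIST_BIN_EDGES, 0.1) - 1] == 256

    def test_total_equals_masked_pixel_count(self, stripes30):
        field = local_orientation(stripes30, tensor_sigma=3)
        mask = np.zeros(stripes30.shape, bool)
        mask[:40] = True
        hist = orientation_histogram(field, mask=mask)
        assert hist.total == (field.valid & mask).sum()

    def test_empty_mask_flagged(self, stripes30):
        field = local_orientation(stripes30, tensor_sigma=3)
        with pytest.warns(UserWarning, match="empty"):
            hist = orientation_histogram(field, mask=np.zeros(stripes30.shape, bool))
        assert hist.empty and hist.total == 0

    def test_out_of_range_angles_rejected(self):
        with pytest.raises(ValueError, match="-90"):
            orientation_histogram(np.array([[95.0]]))


class TestOrientationOrderParameter:
    def test_single_bin_is_one(self):
        counts = np.zeros(360)
        counts[180] = 1000
        assert orientation_order_parameter(counts) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_histogram_is_exactly_zero(self):
        assert orientation_order_parameter(np.ones(360)) == pytest.approx(0.0, abs=1e-12)

    def test_75_25_split_oracle(self):
        # 75% at 0 deg, 25% at 90 deg (wrapped to -90): C = 0.75 - 0.25, S = 0
        counts = np.zeros(360)
        counts[180] = 75  # bin [0, 0.5)
        counts[0] = 25  # bin [-90, -89.5)
        got = orientation_order_parameter(counts)
        assert got == pytest.approx(0.5, abs=1e-3)
        centers = (HIST_BIN_EDGES[:-1] + HIST_BIN_EDGES[1:]) / 2
        want = oop_from_angles(np.repeat(centers, counts.astype(int)))
        assert got == pytest.approx(want, abs=1e-12)

    def test_invariant_under_global_rotation(self):
        rng = np.random.default_rng(2)
        ang = np.degrees(rng.vonmises(0, 3, 20000)) / 2
        base = orientation_order_parameter(orientation_histogram(ang).counts)
        shifted = (ang + 37.0 + 90) % 180 - 90
        rot = orientation_order_parameter(orientation_histogram(shifted).counts)
        assert rot == pytest.approx(base, abs=2e-3)  # binning error only

    @pytest.mark.parametrize("kappa", [0.0, 2.0, 8.0])
    def test_von_mises_closed_form_limit(self, kappa):
        # axial von Mises sample: OOP -> I1(kappa) / I0(kappa)
        rng = np.random.default_rng(3)
        n = 200_000
        if kappa == 0:
            ang = rng.uniform(-90, 90, n)
        else:
            ang = np.degrees(rng.vonmises(0, kappa, n)) / 2
        got = orientation_order_parameter(orientation_histogram(ang).counts)
        want = i1(kappa) / i0(kappa)
        assert got == pytest.approx(want, abs=4 / np.sqrt(n) + 1e-3)

    def test_histogram_path_matches_per_pixel_averaging(self, stripes30):
        # binning at 0.5 deg may move each angle by < 0.25 deg
        field = local_orientation(stripes30, tensor_sigma=3)
        hist = orientation_histogram(field)
        via_hist = orientation_order_parameter(hist)
        direct = oop_from_angles(field.orientation_deg[field.valid])
        assert via_hist == pytest.approx(direct, abs=2 * np.sin(np.radians(0.5)))

    def test_zero_weight_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            orientation_order_parameter(np.zeros(360))
        with pytest.raises(ValueError, match="360"):
            orientation_order_parameter(np.ones(10))


class TestStraighten:
    def test_horizontal_polyline_equals_crop(self):
        rng = np.random.default_rng(4)
        img = rng.random((40, 60))
        verts = np.array([[5.0, 20.0], [54.0, 20.0]])  # (x, y) µm at 1 µm/px
        out = straighten_along_polyline(img, verts, band_width_um=7, px_size_um=1.0)
        assert out.shape == (7, 49)
        crop = img[17:24, 5:54]
        assert np.allclose(out, crop, atol=1e-9)

    def test_output_dimensions_match_arc_and_band(self):
        img = np.zeros((100, 100))
        verts = np.array([[10.0, 10.0], [40.0, 10.0], [40.0, 50.0]])  # L-shape, arc 70
        with pytest.warns(UserWarning, match="curvature"):  # sharp corner
            out = straighten_along_polyline(img, verts, band_width_um=10, px_size_um=1.0)
        assert out.shape == (10, 70)

    def test_curved_stripe_straightening_raises_coherency(self):
        # semicircular stripe: its orientations span 180 deg, so global
        # coherency is poor until the band is straightened along its spine
        n = 110
        img = np.zeros((n, n))
        rr, cc = np.mgrid[0:n, 0:n]
        rad = np.hypot(rr - 55, cc - 55)
        ang = np.arctan2(55 - rr, cc - 55)  # y-up polar angle
        img[(rad > 29) & (rad < 41) & (ang > 0)] = 100.0
        t = np.linspace(np.radians(12), np.radians(168), 60)
        verts = np.stack([55 + 35 * np.cos(t), 55 - 35 * np.sin(t)], axis=1)
        straight = straighten_along_polyline(img, verts, band_width_um=24, px_size_um=1.0)
        assert coherency_score(straight, 8) > coherency_score(img, 8) + 0.1

    def test_single_vertex_errors(self):
        with pytest.raises(ValueError, match="vertices"):
            straighten_along_polyline(np.zeros((10, 10)), np.array([[1.0, 1.0]]), 5, 1.0)

    def test_tight_curvature_warns(self):
        t = np.linspace(0, np.pi, 30)
        verts = np.stack([10 + 3 * np.cos(t), 10 + 3 * np.sin(t)], axis=1)
        with pytest.warns(UserWarning, match="curvature"):
            straighten_along_polyline(np.zeros((20, 20)), verts, band_width_um=12, px_size_um=1.0)


class TestCoherencyScore:
    def test_parallel_stripes_score_high(self, stripes30):
        assert coherency_score(stripes30, 3) > 0.9

    def test_isotropic_noise_scores_low(self):
        rng = np.random.default_rng(5)
        assert coherency_score(rng.normal(size=(256, 256)), 8) < 0.25

    def test_constant_image_undefined(self):
        assert np.isnan(coherency_score(np.full((32, 32), 2.0)))

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(6)
        for _ in range(3):
            s = coherency_score(rng.random((64, 64)), 2)
            assert 0.0 <= s <= 1.0
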