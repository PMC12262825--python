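"""Allocentric map scores: autocorrelogram, grid score, border score,
spatial information, field detection and classification rules."""

import numpy as np
import pytest

from openfield import (
    ArenaGeometry,
    classify_cell,
    detect_fields,
    grid_score,
    population_normalized_map,
    spatial_autocorrelation,
    spatial_information,
)
from openfield.spatial import annulus_rotation_correlations, border_score, estimate_ring_radii
from openfield.tuning import RateMap2D


def make_map(fn, n=48, bin_size=2.5):
    xs = (np.arange(n) + 0.5) * bin_size
    X, Y = np.meshgrid(xs, xs)
    rate = fn(X, Y).astype(float)
    occ = np.ones((n, n))
    return RateMap2D(bin_size, occ, rate.copy(), rate.copy(), rate.copy())


def hex_lattice(X, Y, spacing=40.0, orientation=7.0):
    angs = np.deg2rad(orientation + np.array([0.0, 60.0, 120.0]))
    k = 4 * np.pi / (np.sqrt(3) * spacing)
    z = sum(np.cos(k * (np.cos(a) * X + np.sin(a) * Y)) for a in angs)
    return ((z + 1.5) / 4.5) ** 2


def square_lattice(X, Y, spacing=40.0):
    return (np.cos(2 * np.pi * X / spacing) + np.cos(2 * np.pi * Y / spacing) + 2.0) / 4.0


def central_bump(X, Y, sigma=15.0):
    return np.exp(-((X - 60) ** 2 + (Y - 60) ** 2) / (2 * sigma**2))


class TestAutocorrelation:
    def test_zero_shift_correlation_is_one(self):
        rng = np.random.default_rng(0)
        rm = make_map(lambda X, Y: rng.gamma(2, 1, X.shape))
        ac = spatial_autocorrelation(rm)
        assert ac[ac.shape[0] // 2, ac.shape[1] // 2] == pytest.approx(1.0)

    def test_point_reflection_symmetry(self):
        rng = np.random.default_rng(1)
        rm = make_map(lambda X, Y: rng.gamma(2, 1, X.shape))
        ac = spatial_autocorrelation(rm)
        flipped = ac[::-1, ::-1]
        both = np.isfinite(ac) & np.isfinite(flipped)
        assert np.allclose(ac[both], flipped[both], atol=1e-9)

    def test_matches_bruteforce_shift_loop(self):
        rng = np.random.default_rng(2)
        rm = make_map(lambda X, Y: rng.gamma(2, 1, X.shape), n=12)
        ac = spatial_autocorrelation(rm, min_overlap=5)
        r = rm.rate_smoothed
        n = r.shape[0]
        for dy, dx in [(0, 3), (-2, 1), (4, -4), (5, 5)]:
            a, b = [], []
            for iy in range(n):
                for ix in range(n):
                    jy, jx = iy + dy, ix + dx
                    if 0 <= jy < n and 0 <= jx < n:
                        a.append(r[iy, ix])
                        b.append(r[jy, jx])
            brute = np.corrcoef(a, b)[0, 1]
            assert ac[n - 1 + dy, n - 1 + dx] == pytest.approx(brute, abs=1e-8)

    def test_fourfold_symmetric_map_gives_fourfold_symmetric_autocorr(self):
        rm = make_map(central_bump)
        ac = spatial_autocorrelation(rm)
        rot = np.rot90(ac)
        both = np.isfinite(ac) & np.isfinite(rot)
        assert np.allclose(ac[both], rot[both], atol=1e-4)

    def test_constant_map_correlations_undefined(self):
        rm = make_map(lambda X, Y: np.ones_like(X))
        ac = spatial_autocorrelation(rm)
        assert not np.isfinite(ac).any()


class TestGridScore:
    def test_hexagonal_lattice_scores_above_grid_threshold(self):
        assert grid_score(make_map(hex_lattice)) > 0.4

    def test_square_lattice_scores_negative(self):
        assert grid_score(make_map(square_lattice)) < 0.0

    def test_single_bump_cannot_pass_grid_threshold(self):
        assert grid_score(make_map(central_bump)) < 0.4

    def test_rotating_hexagonal_map_60_degrees_preserves_score(self):
        s0 = grid_score(make_map(lambda X, Y: hex_lattice(X, Y, orientation=7.0)))
        s60 = grid_score(make_map(lambda X, Y: hex_lattice(X, Y, orientation=67.0)))
        assert abs(s0 - s60) < 0.05

    def test_rotation_correlations_match_bruteforce_resampling(self):
        # independent oracle: rotate annulus coordinates directly and sample
        # the autocorrelogram bilinearly
        rm = make_map(hex_lattice)
        ac = spatial_autocorrelation(rm)
        inner, outer = estimate_ring_radii(ac)
        angles, corrs = annulus_rotation_correlations(ac, inner, outer)

        from scipy.ndimage import map_coordinates

        c = ac.shape[0] // 2
        yy, xx = np.indices(ac.shape)
        rad = np.hypot(yy - c, xx - c)
        annulus = (rad >= inner) & (rad <= outer) & np.isfinite(ac)
        pts_y, pts_x = np.nonzero(annulus)
        filled = np.where(np.isfinite(ac), ac, 0.0)
        for target in (60.0, 90.0, 120.0):
            th = np.deg2rad(target)
            ry = c + (pts_y - c) * np.cos(th) - (pts_x - c) * np.sin(th)
            rx = c + (pts_y - c) * np.sin(th) + (pts_x - c) * np.cos(th)
            sampled = map_coordinates(filled, [ry, rx], order=1)
            brute = np.corrcoef(ac[pts_y, pts_x], sampled)[0, 1]
            mine = corrs[int(np.argmin(np.abs(angles - target)))]
            assert mine == pytest.approx(brute, abs=0.05)


class TestBorderScore:
    def test_full_wall_strip_hand_example(self):
        n = 48
        rate = np.zeros((n, n))
        rate[0, :] = 5.0
        rm = RateMap2D(2.5, np.ones((n, n)), rate.copy(), rate.copy(), rate.copy())
        res = border_score(rm, ArenaGeometry())
        assert res.c == pytest.approx(1.0)
        assert res.d == pytest.approx(1.25 / 60.0)
        assert res.score == pytest.approx(0.959, abs=1e-3)

    def test_central_field_scores_minus_one(self):
        rm = make_map(lambda X, Y: (central_bump(X, Y, sigma=8.0) > 0.5).astype(float))
        res = border_score(rm, ArenaGeometry())
        assert res.c == 0.0
        assert res.score == pytest.approx(-1.0)

    def test_small_fields_disqualified(self):
        n = 48
        rate = np.zeros((n, n))
        rate[0, :5] = 5.0  # 5 bins = 31 cm^2 < 200 cm^2
        rm = RateMap2D(2.5, np.ones((n, n)), rate.copy(), rate.copy(), rate.copy())
        assert border_score(rm, ArenaGeometry()) is None

    def test_score_always_within_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            rm = make_map(lambda X, Y: rng.gamma(1.0, 1.0, X.shape))
            res = border_score(rm, ArenaGeometry())
            if res is not None:
                assert -1.0 <= res.score <= 1.0


class TestSpatialInformation:
    def test_uniform_map_carries_no_information(self):
        assert spatial_information(np.full(16, 3.0), np.ones(16)) == pytest.approx(0.0, abs=1e-12)

    def test_four_bin_worked_example(self):
        si = spatial_information(np.array([8.0, 0, 0, 0]), np.ones(4))
        assert si == pytest.approx(2.0)

    def test_invariant_to_rate_scaling(self):
        rng = np.random.default_rng(4)
        rate = rng.gamma(2, 1, 30)
        occ = rng.uniform(0.5, 2.0, 30)
        assert spatial_information(rate * 7.3, occ) == pytest.approx(spatial_information(rate, occ))

    def test_nonnegative_for_random_maps(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            si = spatial_information(rng.gamma(1, 1, 50), rng.uniform(0.1, 1, 50))
            assert si >= -1e-12


class TestFields:
    def test_single_bump_centroid_recovered(self):
        fs = detect_fields(make_map(central_bump))
        assert len(fs) == 1
        assert fs.centroids[0] == pytest.approx((60.0, 60.0), abs=2.5)

    def test_uniform_map_is_one_field_centered(self):
        fs = detect_fields(make_map(lambda X, Y: np.ones_like(X)))
        assert len(fs) == 1
        assert fs.centroids[0] == pytest.approx((60.0, 60.0), abs=1e-9)

    def test_fields_below_minimum_area_rejected(self):
        n = 48
        rate = np.zeros((n, n))
        rate[5:9, 5:9] = 5.0     # 16 bins = 100 cm^2
        rate[30:34, 30:34] = 5.0
        rm = RateMap2D(2.5, np.ones((n, n)), rate.copy(), rate.copy(), rate.copy())
        assert len(detect_fields(rm, min_area_cm2=150.0)) == 0


class TestPopulationMap:
    def test_identical_maps_average_to_rescaled_map(self):
        rm = make_map(central_bump)
        out = population_normalized_map([rm, rm, rm])
        expected = (rm.rate_smoothed - np.nanmin(rm.rate_smoothed)) / np.ptp(rm.rate_smoothed)
        assert np.allclose(out["mean_map"], expected)

    def test_map_plus_complement_average_to_half(self):
        rm = make_map(central_bump)
        out = population_normalized_map([rm, rm], invert=[False, True])
        assert np.allclose(out["mean_map"], 0.5, atol=1e-12)


class TestClassificationRules:
    BASE_SCORES = {
        "grid_score": float("nan"), "border_score": float("nan"), "spatial_information": 0.5,
        "hd_mvl": 0.5, "hd_peak_rate": 5.0, "cb_mvl": 0.1, "cb_peak_rate": 5.0,
        "cd_linear_r2": 0.1, "cd_gaussian_r2": 0.1, "cd_peak_rate": 5.0,
    }
    THRESHOLDS = {
        "spatial_information": 0.3, "hd_mvl": 0.1, "cb_mvl": 0.1,
        "cd_linear_r2": 0.3, "cd_gaussian_r2": 0.3,
    }

    def test_grid_requires_location_and_score(self):
        cls = classify_cell({"location"}, {**self.BASE_SCORES, "grid_score": 0.5}, self.THRESHOLDS)
        assert cls.grid
        cls = classify_cell(set(), {**self.BASE_SCORES, "grid_score": 0.5}, self.THRESHOLDS)
        assert not cls.grid

    def test_grid_takes_precedence_over_border(self):
        scores = {**self.BASE_SCORES, "grid_score": 0.5, "border_score": 0.8}
        cls = classify_cell({"location"}, scores, self.THRESHOLDS)
        assert cls.grid and not cls.border and not cls.nongrid_spatial

    def test_nongrid_requires_neither_grid_nor_border(self):
        scores = {**self.BASE_SCORES, "grid_score": 0.1, "border_score": 0.2}
        cls = classify_cell({"location"}, scores, self.THRESHOLDS)
        assert cls.nongrid_spatial and not cls.grid and not cls.border

    def test_hd_mvl_floor_blocks_weakly_tuned_cells(self):
        scores = {**self.BASE_SCORES, "hd_mvl": 0.15}
        cls = classify_cell({"hd"}, scores, self.THRESHOLDS)
        assert not cls.hd  # exceeds its shuffle threshold but fails the 0.2 floor

    def test_peak_rate_floor_enforced(self):
        scores = {**self.BASE_SCORES, "hd_peak_rate": 0.5}
        cls = classify_cell({"hd"}, scores, self.THRESHOLDS)
        assert not cls.hd

    def test_missing_scores_fail_silently(self):
        cls = classify_cell({"location", "hd", "center_distance"}, {}, {})
        assert cls.unclassified

    def test_por_region_reports_lm_hd_label(self):
        cls = classify_cell({"hd"}, self.BASE_SCORES, self.THRESHOLDS, region="POR")
        assert cls.hd and "lm_hd" in cls.labels
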