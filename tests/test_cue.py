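"""Cue-manipulation statistics: bidirectionality, bidirectional von Mises
fits, modulation indices, direction shifts and rotated-map correlations."""

import numpy as np
import pytest
from scipy.special import iv

from openfield import fit_bidirectional_von_mises, preferred_direction_shift, rotated_map_correlations
from openfield.cue import VonMisesFit, bidirectionality_from_angles, cue_modulation_indices, rotate_map_quarter_turns
from openfield.tuning import CircularTuningCurve, RateMap2D

ANGLES = np.arange(0.0, 360.0, 0.5)


def _vm(mu, kappa):
    return np.exp(kappa * (np.cos(np.deg2rad(ANGLES - mu)) - 1.0))


def make_curve(rates):
    rates = np.asarray(rates, dtype=float)
    n = rates.size
    centers = (np.arange(n) + 0.5) * (360.0 / n)
    return CircularTuningCurve(360.0 / n, centers, np.ones(n), rates)


def curve_from_profile(fn, n=30):
    centers = (np.arange(n) + 0.5) * (360.0 / n)
    return make_curve(fn(centers))


class TestBidirectionality:
    def test_symmetric_bimodal_curve_scores_one(self):
        counts = _vm(45.0, 3.0) + _vm(225.0, 3.0)
        out = bidirectionality_from_angles(ANGLES, counts, dt=1.0)
        assert out["mvl_normal"] == pytest.approx(0.0, abs=1e-9)
        assert out["bi"] == pytest.approx(1.0)

    def test_equal_first_and_second_harmonics_score_zero(self):
        # f = 2 + cos + cos2: MVL_normal and MVL_doubled both equal 1/4
        counts = 2.0 + np.cos(np.deg2rad(ANGLES)) + np.cos(2 * np.deg2rad(ANGLES))
        out = bidirectionality_from_angles(ANGLES, counts, dt=1.0)
        assert out["bi"] == pytest.approx(0.0, abs=5e-3)

    def test_unimodal_von_mises_matches_bessel_moment_oracle(self):
        # oracle: MVL_normal = I1(k)/I0(k), MVL_doubled = I2(k)/I0(k)
        counts = _vm(77.0, 2.0)
        out = bidirectionality_from_angles(ANGLES, counts, dt=1.0)
        m1 = iv(1, 2.0) / iv(0, 2.0)
        m2 = iv(2, 2.0) / iv(0, 2.0)
        expected = (m2 - m1) / (m2 + m1)
        assert out["bi"] == pytest.approx(expected, abs=0.005)

    def test_invariant_to_uniform_rate_scaling(self):
        counts = _vm(10.0, 1.5)
        a = bidirectionality_from_angles(ANGLES, counts, dt=1.0)["bi"]
        b = bidirectionality_from_angles(ANGLES, counts * 9.0, dt=1.0)["bi"]
        assert a == pytest.approx(b, abs=1e-12)


class TestVonMisesFit:
    def test_noiseless_bidirectional_curve_recovers_lobe_direction(self):
        curve = curve_from_profile(
            lambda c: 1.0 + 4.0 * np.exp(2.0 * (np.cos(np.deg2rad(c - 45.0)) - 1.0))
            + 4.0 * np.exp(2.0 * (np.cos(np.deg2rad(c - 225.0)) - 1.0))
        )
        fit = fit_bidirectional_von_mises(curve, mode="peak")
        assert min(abs((fit.mu - 45.0) % 180.0), abs(180.0 - (fit.mu - 45.0) % 180.0)) < 2.0
        assert fit.r2 > 0.999

    def test_flat_curve_yields_negligible_amplitudes(self):
        fit = fit_bidirectional_von_mises(make_curve(np.full(30, 5.0)), mode="peak")
        assert fit.amp1 < 0.01 * fit.offset
        assert fit.amp2 < 0.01 * fit.offset

    def test_trough_fit_mirrors_peak_fit(self):
        rates = 1.0 + 4.0 * np.exp(3.0 * (np.cos(np.deg2rad(np.arange(6, 360, 12) - 100.0)) - 1.0))
        peak_fit = fit_bidirectional_von_mises(make_curve(rates), mode="peak")
        mirrored = make_curve(rates.max() - rates)
        trough_fit = fit_bidirectional_von_mises(mirrored, mode="trough")
        assert trough_fit.mu == pytest.approx(peak_fit.mu, abs=2.0)
        assert trough_fit.max_fit - trough_fit.min_fit == pytest.approx(
            peak_fit.max_fit - peak_fit.min_fit, rel=0.02
        )

    def test_unequal_lobes_ordered_largest_first(self):
        curve = curve_from_profile(
            lambda c: 0.5 + 6.0 * np.exp(2.5 * (np.cos(np.deg2rad(c - 300.0)) - 1.0))
            + 2.0 * np.exp(2.5 * (np.cos(np.deg2rad(c - 120.0)) - 1.0))
        )
        fit = fit_bidirectional_von_mises(curve)
        assert fit.amp1 >= fit.amp2
        assert abs((fit.mu - 300.0 + 180.0) % 360.0 - 180.0) < 5.0


class TestModulationIndices:
    def test_symmetric_lobes_give_equal_indices(self):
        fit = VonMisesFit("peak", 30.0, 4.0, 4.0, 2.0, 1.0, max_fit=5.0, min_fit=1.0, r2=1.0)
        mi_s, mi_n = cue_modulation_indices(fit, session1_preferred_deg=25.0)
        assert mi_s == pytest.approx(mi_n)

    def test_purely_unidirectional_fit_scores_one_and_zero(self):
        fit = VonMisesFit("peak", 30.0, 5.0, 0.0, 3.0, 0.0, max_fit=5.0, min_fit=0.0, r2=1.0)
        mi_s, mi_n = cue_modulation_indices(fit, session1_preferred_deg=30.0)
        assert mi_s == pytest.approx(1.0, abs=1e-6)
        # the opposite lobe only sees the first lobe's antipodal tail exp(-2k)
        assert mi_n < np.exp(-2 * fit.kappa) + 1e-9

    def test_flat_fit_scores_zero(self):
        fit = VonMisesFit("peak", 30.0, 0.0, 0.0, 1.0, 4.0, max_fit=4.0, min_fit=4.0, r2=0.0)
        mi_s, _ = cue_modulation_indices(fit, session1_preferred_deg=30.0)
        assert mi_s == pytest.approx(0.0)

    def test_south_lobe_is_circularly_nearest(self):
        fit = VonMisesFit("peak", 10.0, 5.0, 2.0, 2.0, 0.0, max_fit=5.0, min_fit=0.1, r2=1.0)
        mi_s_near, _ = cue_modulation_indices(fit, session1_preferred_deg=350.0)   # nearest 10
        mi_s_far, _ = cue_modulation_indices(fit, session1_preferred_deg=170.0)    # nearest 190
        assert mi_s_near > mi_s_far


class TestDirectionShift:
    def test_identical_curves_do_not_shift(self):
        c = curve_from_profile(lambda a: _peaked(a, 40.0))
        assert preferred_direction_shift(c, c) == pytest.approx(0.0)

    def test_quarter_turn_reported_signed(self):
        c1 = curve_from_profile(lambda a: _peaked(a, 40.0))
        c2 = curve_from_profile(lambda a: _peaked(a, 130.0))
        assert preferred_direction_shift(c1, c2) == pytest.approx(90.0, abs=1e-6)

    def test_three_quarter_turn_wraps_negative(self):
        c1 = curve_from_profile(lambda a: _peaked(a, 40.0))
        c2 = curve_from_profile(lambda a: _peaked(a, 310.0))
        assert preferred_direction_shift(c1, c2) == pytest.approx(-90.0, abs=1e-6)

    def test_undefined_preference_flagged(self):
        flat = make_curve(np.zeros(30))
        c = curve_from_profile(lambda a: _peaked(a, 40.0))
        assert np.isnan(preferred_direction_shift(flat, c))


def _peaked(angles, mu):
    return np.exp(3.0 * (np.cos(np.deg2rad(angles - mu)) - 1.0))


class TestRotatedMapCorrelations:
    @staticmethod
    def _world_map(fn, n=48, bin_size=2.5):
        xs = (np.arange(n) + 0.5) * bin_size
        X, Y = np.meshgrid(xs, xs)
        rate = fn(X, Y).astype(float)
        return RateMap2D(bin_size, np.ones((n, n)), rate.copy(), rate.copy(), rate.copy())

    def test_map_correlates_perfectly_with_itself_at_zero(self):
        m = self._world_map(lambda X, Y: np.exp(-((X - 90) ** 2 + (Y - 40) ** 2) / 300.0))
        corr = rotated_map_correlations(m, m)
        assert corr[0] == pytest.approx(1.0)

    def test_ninety_degree_copy_correlates_at_ninety(self):
        # map2 is map1 rotated +90 deg in world coordinates about the center
        fn = lambda X, Y: np.exp(-((X - 90) ** 2 + (Y - 40) ** 2) / 300.0) + 0.3 * np.exp(
            -((X - 30) ** 2 + (Y - 100) ** 2) / 500.0
        )
        m1 = self._world_map(fn)
        # world rotation +90: (x, y) -> (s - y, x), i.e. the pre-image of (x, y) is (y, s - x)
        m2 = self._world_map(lambda X, Y: fn(Y, 120.0 - X))
        corr = rotated_map_correlations(m1, m2)
        assert corr[90] == pytest.approx(1.0, abs=1e-9)
        assert corr[90] > corr[0]

    def test_isotropic_map_correlates_equally_at_all_rotations(self):
        m = self._world_map(lambda X, Y: np.exp(-((X - 60) ** 2 + (Y - 60) ** 2) / 800.0))
        corr = rotated_map_correlations(m, m)
        vals = list(corr.values())
        assert np.allclose(vals, vals[0], atol=1e-9)

    def test_quarter_turn_helper_consistent_with_world_rotation(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(48, 48))
        four = rotate_map_quarter_turns(arr, 4)
        assert np.array_equal(four, arr)
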