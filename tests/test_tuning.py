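"""Rate maps, tuning curves, spike-shift shuffling and occupancy
resampling."""

import numpy as np
import pytest

from openfield import (
    ArenaGeometry,
    SpikeTrain,
    TrackingData,
    TuningModel,
    compute_rate_map,
    circular_tuning_curve,
    distance_tuning_curve,
    generate_spikes,
    resample_equal_occupancy,
    shuffle_spike_train,
    shuffle_threshold,
)
from openfield.tuning import nan_gaussian_smooth


class TestRateMap:
    def test_no_spikes_gives_all_zero_map(self, short_tracking, arena):
        rm = compute_rate_map(short_tracking, SpikeTrain(np.empty(0)), arena)
        assert np.nansum(rm.rate_smoothed) == 0.0
        assert np.nansum(rm.counts) == 0

    def test_single_spike_lands_in_exactly_one_bin(self, short_tracking, arena):
        rm = compute_rate_map(short_tracking, SpikeTrain(np.array([10.0])), arena)
        assert np.nansum(rm.counts) == 1
        assert (rm.counts > 0).sum() == 1

    def test_spike_count_conserved(self, long_tracking, arena):
        model = TuningModel(kind="hd", baseline_rate=3.0, peak_rate=3.0)
        spikes = generate_spikes(long_tracking, model, seed=0)
        rm = compute_rate_map(long_tracking, spikes, arena)
        assert np.nansum(rm.counts) == len(spikes)

    def test_smoothing_preserves_mean_under_full_occupancy(self):
        # edge-renormalized kernel: mean rate unchanged within 1%
        rng = np.random.default_rng(0)
        rate = rng.gamma(2.0, 1.0, size=(48, 48))
        sm = nan_gaussian_smooth(rate, 1.5)
        assert np.nanmean(sm) == pytest.approx(np.nanmean(rate), rel=0.01)

    def test_unvisited_bins_stay_missing(self, arena):
        t = np.arange(0, 10, 1 / 30)
        tr = TrackingData(t, np.full_like(t, 10.0), np.full_like(t, 10.0), np.zeros_like(t))
        rm = compute_rate_map(tr, SpikeTrain(np.array([1.0])), arena)
        assert np.isnan(rm.rate_smoothed[47, 47])
        assert np.isfinite(rm.rate_smoothed[rm.visited]).all()


class TestCircularCurve:
    def test_single_occupied_bin_gives_unit_mvl(self):
        angles = np.full(100, 6.0)  # all frames in the first 12-degree bin
        counts = np.ones(100)
        c = circular_tuning_curve(angles, counts, dt=1 / 30)
        assert c.mvl == pytest.approx(1.0)
        assert c.preferred_direction == pytest.approx(6.0)

    def test_flat_curve_has_zero_mvl(self):
        angles = np.repeat(np.arange(6.0, 360.0, 12.0), 10)
        counts = np.ones_like(angles)
        c = circular_tuning_curve(angles, counts, dt=1 / 30)
        assert c.mvl == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_bins_cancel(self):
        angles = np.concatenate([np.full(50, 6.0), np.full(50, 186.0)])
        counts = np.ones(100)
        c = circular_tuning_curve(angles, counts, dt=1 / 30)
        assert c.mvl == pytest.approx(0.0, abs=1e-12)

    def test_mvl_matches_bruteforce_complex_sum(self, long_tracking):
        model = TuningModel(kind="hd", baseline_rate=0.5, peak_rate=8.0, kappa=3.0)
        spikes = generate_spikes(long_tracking, model, seed=2)
        c = circular_tuning_curve(long_tracking.hd, spikes.counts_per_frame(long_tracking), long_tracking.dt)
        ok = np.isfinite(c.rate)
        num = sum(r * np.exp(1j * np.deg2rad(th)) for r, th in zip(c.rate[ok], c.bin_centers[ok]))
        brute = abs(num) / c.rate[ok].sum()
        assert c.mvl == pytest.approx(brute, abs=1e-12)

    def test_all_zero_rates_flagged_undefined(self):
        c = circular_tuning_curve(np.repeat(np.arange(0, 360, 12.0), 3), np.zeros(90), dt=1 / 30)
        assert np.isnan(c.mvl) and np.isnan(c.preferred_direction)


class TestDistanceCurve:
    @staticmethod
    def _tracking_with_rate(rate_fn, frames_per_bin=3000, fps=30.0, seed=0):
        """Frames spread over distances with spike counts matching rate_fn."""
        arena = ArenaGeometry()
        dmax = 60.0 * np.sqrt(2.0)
        dists = np.repeat(np.arange(2.0, dmax, 4.0), frames_per_bin)
        rng = np.random.default_rng(seed)
        ang = rng.uniform(0, 2 * np.pi, dists.size)
        x = np.clip(60.0 + dists * np.cos(ang), 0, 120)
        y = np.clip(60.0 + dists * np.sin(ang), 0, 120)
        d_real = np.hypot(x - 60, y - 60)
        t = np.arange(dists.size) / fps
        tr = TrackingData(t, x, y, np.zeros_like(t))
        lam = rate_fn(d_real) / fps
        base = np.floor(lam)
        frac = lam - base
        extra = (np.arange(lam.size) % 100) < np.round(frac * 100)  # deterministic fractional part
        counts = (base + extra).astype(int)
        times = np.repeat(t, counts) + 1e-4
        return tr, SpikeTrain(times), arena

    def test_linear_profile_recovered_with_unit_r2(self):
        tr, sp, arena = self._tracking_with_rate(lambda d: 2.0 + 0.1 * d)
        c = distance_tuning_curve(tr, sp, arena)
        assert c.linear_r2 > 0.99
        assert c.linear_slope == pytest.approx(0.1, rel=0.1)

    def test_constant_rate_explains_no_variance(self):
        tr, sp, arena = self._tracking_with_rate(lambda d: 3.0 + 0.0 * d)
        c = distance_tuning_curve(tr, sp, arena)
        assert c.linear_r2 == pytest.approx(0.0, abs=0.02)

    def test_gaussian_bump_profile_recovered(self):
        tr, sp, arena = self._tracking_with_rate(
            lambda d: 1.0 + 8.0 * np.exp(-((d - 30.0) ** 2) / (2 * 10.0**2))
        )
        c = distance_tuning_curve(tr, sp, arena)
        assert c.gaussian_r2 > 0.99
        assert c.gaussian_params[1] == pytest.approx(30.0, abs=1.0)


class TestShuffle:
    def test_forced_shift_wraps_correctly(self):
        sp = SpikeTrain(np.array([5.0, 1195.0]))
        out = shuffle_spike_train(sp, 1200.0, shift=30.0)
        assert np.allclose(out.spike_times, [25.0, 35.0])  # 1195+30 wraps to 25

    def test_full_duration_shift_is_identity(self):
        sp = SpikeTrain(np.array([5.0, 100.0, 600.0]))
        out = shuffle_spike_train(sp, 1200.0, shift=1200.0)
        assert np.allclose(out.spike_times, sp.spike_times)

    def test_spike_count_and_isis_preserved_modulo_one_wrap(self):
        rng = np.random.default_rng(5)
        sp = SpikeTrain(np.sort(rng.uniform(0, 1200, 200)))
        out = shuffle_spike_train(sp, 1200.0, seed=1)
        assert len(out) == len(sp)
        isi_in = np.sort(np.diff(np.r_[sp.spike_times, sp.spike_times[0] + 1200.0]))
        isi_out = np.sort(np.diff(np.r_[out.spike_times, out.spike_times[0] + 1200.0]))
        assert np.allclose(isi_in, isi_out, atol=1e-9)

    def test_short_session_rejected(self):
        with pytest.raises(ValueError):
            shuffle_spike_train(SpikeTrain(np.array([1.0])), 50.0, min_shift=30.0)

    def test_constant_statistic_threshold_is_that_constant(self):
        sp = SpikeTrain(np.sort(np.random.default_rng(0).uniform(0, 600, 100)))
        thr = shuffle_threshold(lambda s: 0.42, sp, 600.0, n_shuffles=50, seed=0)
        assert thr == pytest.approx(0.42)

    def test_random_shifts_cover_allowed_range(self):
        sp = SpikeTrain(np.array([0.0]))
        shifts = [shuffle_spike_train(sp, 1200.0, seed=s).spike_times[0] for s in range(50)]
        assert min(shifts) >= 30.0 and max(shifts) <= 1170.0


class TestResampling:
    def test_two_bin_case_forced_to_minimum(self, arena):
        # 10 s in one 15 cm bin, 4 s in another -> both resampled to 4 s
        t = np.arange(0, 14, 1 / 30)
        x = np.where(t < 10, 7.0, 22.0)
        tr = TrackingData(t, x, np.full_like(t, 7.0), np.zeros_like(t))
        sub, _ = resample_equal_occupancy(tr, SpikeTrain(np.empty(0)), arena, seed=0)
        in_a = (sub.x < 15).sum()
        in_b = (sub.x >= 15).sum()
        assert in_a == in_b == 4 * 30

    def test_output_occupancy_flat_across_visited_bins(self, long_tracking, arena):
        model = TuningModel(kind="hd", baseline_rate=2.0, peak_rate=2.0)
        spikes = generate_spikes(long_tracking, model, seed=1)
        sub_tr, sub_sp = resample_equal_occupancy(long_tracking, spikes, arena, seed=3)
        counts, _, _ = np.histogram2d(sub_tr.y, sub_tr.x, bins=8, range=[[0, 120], [0, 120]])
        visited = counts[counts > 0]
        assert visited.max() - visited.min() < 1  # within one frame
        # never increases occupancy
        before, _, _ = np.histogram2d(long_tracking.y, long_tracking.x, bins=8, range=[[0, 120], [0, 120]])
        assert np.all(counts <= before)
        # retained spikes fall inside retained frames
        kept_frames = set(np.round(sub_tr.time * 30).astype(int))
        spike_frames = np.floor(sub_sp.spike_times * 30).astype(int)
        assert all(f in kept_frames for f in spike_frames)

    def test_already_equal_occupancy_is_identity(self, arena):
        # one frame in each of the 64 bins
        centers = (np.arange(8) + 0.5) * 15.0
        xx, yy = np.meshgrid(centers, centers)
        t = np.arange(64) / 30.0
        tr = TrackingData(t, xx.ravel(), yy.ravel(), np.zeros(64))
        sub, _ = resample_equal_occupancy(tr, SpikeTrain(np.empty(0)), arena, seed=0)
        assert len(sub) == 64
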