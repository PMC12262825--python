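"""Tuning-curve machinery: rate maps, circular/linear tuning curves,
spike-shift shuffling and occupancy-equalizing resampling.

All estimators are occupancy-normalized: a bin's rate is the spike count
attributed to the bin divided by the time spent there. Spikes are assigned
to the tracking frame whose interval contains them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage, optimize

from .circstats import mvl as _mvl, circmean_deg
from .geometry import ArenaGeometry
from .session import SpikeTrain, TrackingData


# ------------------------------------------------------------- 2D rate maps
@dataclass(frozen=True)
class RateMap2D:
    """Binned, smoothed allocentric firing-rate map with occupancy.

    Arrays are indexed ``[iy, ix]`` with row 0 the southernmost row and
    column 0 the westernmost column (row-major from the southwest corner).
    Unvisited bins are NaN in both raw and smoothed rate.
    """

    bin_size: float
    occupancy: np.ndarray       # seconds per bin
    counts: np.ndarray          # spikes per bin
    rate: np.ndarray            # raw rate, Hz; NaN where unvisited
    rate_smoothed: np.ndarray   # edge-renormalized Gaussian-smoothed rate, Hz

    @property
    def visited(self) -> np.ndarray:
        return self.occupancy > 0

    @property
    def occupancy_probability(self) -> np.ndarray:
        """P_i over visited bins (sums to 1); NaN where unvisited."""
        p = np.where(self.visited, self.occupancy, np.nan)
        return p / np.nansum(p)

    @property
    def mean_rate(self) -> float:
        """Occupancy-weighted overall mean rate (Hz)."""
        return float(np.nansum(self.occupancy_probability * self.rate_smoothed))

    @property
    def peak_rate(self) -> float:
        return float(np.nanmax(self.rate_smoothed))


def nan_gaussian_smooth(values: np.ndarray, sigma_bins: float) -> np.ndarray:
    """Gaussian smoothing with an edge-truncated, renormalized kernel.

    Missing (NaN) bins are excluded from the kernel support and remain NaN
    in the output, so rates are not suppressed at walls or next to
    unvisited bins.
    """
    valid = np.isfinite(values)
    filled = np.where(valid, values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma_bins, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(valid.astype(float), sigma_bins, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~valid] = np.nan
    return out


def compute_rate_map(
    tracking: TrackingData,
    spikes: SpikeTrain,
    arena: ArenaGeometry | None = None,
    bin_size: float = 2.5,
    smooth_sigma: float = 3.75,
) -> RateMap2D:
    """Allocentric firing-rate map on ``bin_size`` cm square bins.

    Rate is spikes/occupancy per bin; smoothing uses a Gaussian kernel of
    ``smooth_sigma`` cm (1.5 bins at the 2.5 cm default), renormalized at
    edges and around unvisited bins.
    """
    arena = arena or ArenaGeometry()
    side = arena.side_length
    n = int(round(side / bin_size))
    edges = np.linspace(0.0, side, n + 1)
    dt = tracking.dt

    x = np.clip(tracking.x, 0, np.nextafter(side, 0))
    y = np.clip(tracking.y, 0, np.nextafter(side, 0))
    occ, _, _ = np.histogram2d(y, x, bins=[edges, edges])
    occ *= dt
    if occ.sum() == 0:
        raise ValueError("zero total occupancy")

    counts_per_frame = spikes.counts_per_frame(tracking)
    cnt, _, _ = np.histogram2d(y, x, bins=[edges, edges], weights=counts_per_frame)

    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ > 0, cnt / occ, np.nan)
    smoothed = nan_gaussian_smooth(rate, smooth_sigma / bin_size)
    return RateMap2D(bin_size=bin_size, occupancy=occ, counts=cnt, rate=rate, rate_smoothed=smoothed)


def smoothed_occupancy(ratemap: RateMap2D, smooth_sigma: float = 3.75) -> np.ndarray:
    """Occupancy histogram smoothed with the same kernel as the rate map."""
    occ = np.where(ratemap.visited, ratemap.occupancy, np.nan)
    return nan_gaussian_smooth(occ, smooth_sigma / ratemap.bin_size)


# ----------------------------------------------------- circular tuning curves
@dataclass(frozen=True)
class CircularTuningCurve:
    """Occupancy-normalized circular tuning curve (default 12-degree bins).

    ``mvl`` is the mean vector length of the binned curve:
    ``|sum_b rate_b exp(i theta_b)| / sum_b rate_b`` over bin centers; the
    preferred direction is the argument of that sum. Both are NaN when the
    curve is all-zero or has no occupied bin.
    """

    bin_width: float
    bin_centers: np.ndarray     # deg, in [0, 360)
    occupancy_s: np.ndarray
    rate: np.ndarray            # Hz; NaN where unoccupied
    variable: str = "hd"

    @property
    def mvl(self) -> float:
        ok = np.isfinite(self.rate)
        if not ok.any() or np.nansum(self.rate) <= 0:
            return float("nan")
        return _mvl(self.bin_centers[ok], self.rate[ok])

    @property
    def preferred_direction(self) -> float:
        ok = np.isfinite(self.rate)
        if not ok.any() or np.nansum(self.rate) <= 0:
            return float("nan")
        return circmean_deg(self.bin_centers[ok], self.rate[ok])

    @property
    def peak_rate(self) -> float:
        return float(np.nanmax(self.rate))


def circular_tuning_curve(
    angles_deg: np.ndarray,
    spike_counts: np.ndarray,
    dt: float,
    bin_width: float = 12.0,
    variable: str = "hd",
) -> CircularTuningCurve:
    """Tuning curve of per-frame spike counts against a circular variable.

    ``angles_deg`` and ``spike_counts`` are per-frame and aligned; frames
    with non-finite angle (e.g. ill-defined bearing) are excluded.
    """
    angles = np.asarray(angles_deg, dtype=float)
    counts = np.asarray(spike_counts, dtype=float)
    if angles.shape != counts.shape:
        raise ValueError("angles and spike counts must be aligned per frame")
    ok = np.isfinite(angles)
    angles = np.mod(angles[ok], 360.0)
    counts = counts[ok]

    n_bins = int(round(360.0 / bin_width))
    idx = np.minimum((angles / bin_width).astype(int), n_bins - 1)
    occ = np.bincount(idx, minlength=n_bins) * dt
    spk = np.bincount(idx, weights=counts, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ > 0, spk / occ, np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return CircularTuningCurve(
        bin_width=bin_width, bin_centers=centers, occupancy_s=occ, rate=rate, variable=variable
    )


def hd_tuning_curve(
    tracking: TrackingData, spikes: SpikeTrain, bin_width: float = 12.0
) -> CircularTuningCurve:
    return circular_tuning_curve(
        tracking.hd, spikes.counts_per_frame(tracking), tracking.dt, bin_width, variable="hd"
    )


def center_bearing(tracking: TrackingData, reference_point) -> np.ndarray:
    """Egocentric bearing (deg, in [-180, 180)) of a reference point per frame.

    0 = directly ahead, +90 = to the animal's left (counterclockwise-
    positive, matching the HD convention). NaN within 1 cm of the
    reference point, where the bearing is ill-defined.
    """
    rx, ry = reference_point
    dx = rx - tracking.x
    dy = ry - tracking.y
    dist = np.hypot(dx, dy)
    bearing = np.mod(np.rad2deg(np.arctan2(dy, dx)) - tracking.hd + 180.0, 360.0) - 180.0
    return np.where(dist < 1.0, np.nan, bearing)


def center_bearing_curve(
    tracking: TrackingData,
    spikes: SpikeTrain,
    arena: ArenaGeometry | None = None,
    bin_width: float = 12.0,
) -> CircularTuningCurve:
    arena = arena or ArenaGeometry()
    bearings = center_bearing(tracking, arena.center)
    return circular_tuning_curve(
        bearings, spikes.counts_per_frame(tracking), tracking.dt, bin_width, variable="center_bearing"
    )


# ------------------------------------------------------ linear tuning curves
@dataclass(frozen=True)
class LinearTuningCurve:
    """Center-distance tuning curve with linear and Gaussian fits (4 cm bins)."""

    bin_width: float
    bin_centers: np.ndarray
    occupancy_s: np.ndarray
    rate: np.ndarray
    linear_r2: float
    gaussian_r2: float          # NaN when the fit did not converge
    linear_slope: float
    gaussian_params: tuple | None  # (amplitude, mean, width, offset)

    @property
    def peak_rate(self) -> float:
        return float(np.nanmax(self.rate))

    @property
    def best_r2(self) -> float:
        return float(np.nanmax([self.linear_r2, self.gaussian_r2]))


def _r_squared(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def distance_tuning_curve(
    tracking: TrackingData,
    spikes: SpikeTrain,
    arena: ArenaGeometry | None = None,
    bin_width: float = 4.0,
) -> LinearTuningCurve:
    """Firing rate vs distance from the arena center, with least-squares
    linear and Gaussian (amplitude/mean/width/offset) fits and their R^2."""
    arena = arena or ArenaGeometry()
    cx, cy = arena.center
    d = np.hypot(tracking.x - cx, tracking.y - cy)
    dmax = arena.side_length / 2.0 * np.sqrt(2.0)
    n_bins = int(np.ceil(dmax / bin_width))
    idx = np.minimum((d / bin_width).astype(int), n_bins - 1)
    occ = np.bincount(idx, minlength=n_bins) * tracking.dt
    spk = np.bincount(idx, weights=spikes.counts_per_frame(tracking), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ > 0, spk / occ, np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_width

    ok = np.isfinite(rate)
    xs, ys = centers[ok], rate[ok]
    if xs.size >= 2:
        slope, intercept = np.polyfit(xs, ys, 1)
        lin_r2 = _r_squared(ys, slope * xs + intercept)
    else:
        slope, lin_r2 = float("nan"), float("nan")

    gauss_r2, gauss_params = float("nan"), None
    if xs.size >= 5 and np.ptp(ys) > 0:
        def gauss(x, a, m, w, c):
            return a * np.exp(-((x - m) ** 2) / (2.0 * w**2)) + c

        p0 = (float(np.ptp(ys)), float(xs[np.argmax(ys)]), float(np.ptp(xs)) / 4.0, float(np.min(ys)))
        try:
            popt, _ = optimize.curve_fit(gauss, xs, ys, p0=p0, maxfev=2000)
            if popt[2] != 0 and np.all(np.isfinite(popt)):
                gauss_r2 = _r_squared(ys, gauss(xs, *popt))
                gauss_params = tuple(float(v) for v in popt)
        except (RuntimeError, optimize.OptimizeWarning):
            pass

    return LinearTuningCurve(
        bin_width=bin_width,
        bin_centers=centers,
        occupancy_s=occ,
        rate=rate,
        linear_r2=float(lin_r2),
        gaussian_r2=float(gauss_r2),
        linear_slope=float(slope),
        gaussian_params=gauss_params,
    )


# ---------------------------------------------------------------- shuffling
def shuffle_spike_train(
    spikes: SpikeTrain,
    session_duration: float,
    min_shift: float = 30.0,
    seed: int | None = None,
    shift: float | None = None,
) -> SpikeTrain:
    """Circularly time-shift a spike train by a uniform random offset.

    The shift is drawn from ``[min_shift, duration - min_shift]``; times
    past the session end wrap to the beginning, preserving the train's
    temporal structure relative to itself while decoupling it from
    behavior. ``shift`` forces a specific offset (testing hook).
    """
    if session_duration <= 2 * min_shift:
        raise ValueError("session too short for the requested minimum shift")
    if shift is None:
        rng = np.random.default_rng(seed)
        shift = float(rng.uniform(min_shift, session_duration - min_shift))
    shifted = np.sort(np.mod(spikes.spike_times + shift, session_duration))
    return SpikeTrain(shifted)


def shuffle_threshold(
    statistic_fn: Callable[[SpikeTrain], float],
    spikes: SpikeTrain,
    session_duration: float,
    n_shuffles: int = 400,
    percentile: float = 99.0,
    min_shift: float = 30.0,
    seed: int | None = None,
) -> float:
    """Within-cell shuffle threshold: the given percentile of a statistic
    over circularly shifted spike trains (defaults: 400 shuffles, 99th)."""
    rng = np.random.default_rng(seed)
    values = np.empty(n_shuffles)
    for i in range(n_shuffles):
        sh = float(rng.uniform(min_shift, session_duration - min_shift))
        values[i] = statistic_fn(shuffle_spike_train(spikes, session_duration, min_shift, shift=sh))
    bad = ~np.isfinite(values)
    if bad.mean() > 0.10:
        raise ValueError(f"statistic undefined on {bad.sum()}/{n_shuffles} shuffles")
    return float(np.percentile(values[~bad], percentile))


# --------------------------------------------------------------- resampling
def resample_equal_occupancy(
    tracking: TrackingData,
    spikes: SpikeTrain,
    arena: ArenaGeometry | None = None,
    bin_size: float = 15.0,
    seed: int | None = None,
) -> tuple[TrackingData, SpikeTrain]:
    """Subsample frames so every visited spatial bin has equal occupancy.

    The arena is tiled with ``bin_size`` cm square bins (64 for the default
    geometry); the target occupancy is the minimum over *visited* bins
    (zero-occupancy bins are excluded, else the procedure degenerates);
    frames within each bin are subsampled without replacement and spikes
    are retained iff their frame is retained. Timestamps are preserved.
    """
    arena = arena or ArenaGeometry()
    side = arena.side_length
    n = int(round(side / bin_size))
    rng = np.random.default_rng(seed)

    ix = np.minimum((np.clip(tracking.x, 0, side) / bin_size).astype(int), n - 1)
    iy = np.minimum((np.clip(tracking.y, 0, side) / bin_size).astype(int), n - 1)
    flat = iy * n + ix
    counts = np.bincount(flat, minlength=n * n)
    target = int(counts[counts > 0].min())

    keep = np.zeros(len(tracking), dtype=bool)
    for b in np.flatnonzero(counts > 0):
        members = np.flatnonzero(flat == b)
        if members.size > target:
            members = rng.choice(members, size=target, replace=False)
        keep[members] = True

    kept_frames = np.flatnonzero(keep)
    sub_tracking = tracking.subset(kept_frames)

    spike_frames = tracking.frame_of(spikes.spike_times)
    retain = (spike_frames >= 0) & keep[np.clip(spike_frames, 0, None)]
    sub_spikes = SpikeTrain(spikes.spike_times[retain])
    return sub_tracking, sub_spikes
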