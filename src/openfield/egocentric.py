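"""Egocentric-bearing reference-point analysis.

For every cell, egocentric-bearing tuning curves are computed relative to a
20 x 20 array of candidate reference points spread evenly across the arena;
the mean vector length (MVL) of each curve gives a tuning-strength map whose
argmax ("MVL_max location") is the cell's preferred egocentric reference
point. Pure center-bearing cells peak at the arena center; conjunctive
CB x HD cells peak at offset locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ArenaGeometry, circdiff_deg, wrap_signed_deg, zone_membership
from .session import SpikeTrain, TrackingData

MIN_REFERENCE_DISTANCE = 1.0  # cm; bearing is ill-defined on top of the reference


def egocentric_bearing(x, y, hd, reference_point) -> np.ndarray:
    """Egocentric bearing (deg in [-180, 180)) of a reference point.

    0 = directly ahead, +90 = to the animal's left (counterclockwise-
    positive, matching the allocentric HD convention). NaN where the animal
    is within 1 cm of the reference point.
    """
    rx, ry = reference_point
    dx = rx - np.asarray(x, dtype=float)
    dy = ry - np.asarray(y, dtype=float)
    dist = np.hypot(dx, dy)
    bearing = wrap_signed_deg(np.rad2deg(np.arctan2(dy, dx)) - np.asarray(hd, dtype=float))
    return np.where(dist < MIN_REFERENCE_DISTANCE, np.nan, bearing)


def reference_grid(arena: ArenaGeometry | None = None, n: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Centers of an n x n partition of the arena (6 cm pitch, 3 cm inset
    from the walls for the default geometry)."""
    arena = arena or ArenaGeometry()
    pitch = arena.side_length / n
    coords = (np.arange(n) + 0.5) * pitch
    return coords, coords  # x-coords, y-coords


@dataclass(frozen=True)
class BearingBinCache:
    """Per-session precomputation shared across cells: for every reference
    point, the egocentric-bearing bin index of every frame (-1 = excluded)."""

    ref_x: np.ndarray
    ref_y: np.ndarray
    bin_idx: np.ndarray  # (n_refs, n_frames) int16
    n_bins: int
    dt: float


def precompute_bearing_bins(
    tracking: TrackingData,
    arena: ArenaGeometry | None = None,
    n_grid: int = 20,
    bin_width: float = 12.0,
) -> BearingBinCache:
    arena = arena or ArenaGeometry()
    xs, ys = reference_grid(arena, n_grid)
    n_bins = int(round(360.0 / bin_width))
    n_refs = n_grid * n_grid
    idx = np.empty((n_refs, len(tracking)), dtype=np.int16)
    k = 0
    for ry in ys:
        for rx in xs:
            b = egocentric_bearing(tracking.x, tracking.y, tracking.hd, (rx, ry))
            bi = np.floor(np.mod(b, 360.0) / bin_width)
            bi = np.where(np.isfinite(b), np.minimum(bi, n_bins - 1), -1)
            idx[k] = bi.astype(np.int16)
            k += 1
    return BearingBinCache(ref_x=xs, ref_y=ys, bin_idx=idx, n_bins=n_bins, dt=tracking.dt)


@dataclass(frozen=True)
class MVLMap:
    """Egocentric-bearing tuning strength over the reference-point grid.

    ``mvl[iy, ix]`` is the MVL of the bearing tuning curve for the reference
    point at ``(ref_x[ix], ref_y[iy])``; NaN where fewer than half the
    bearing bins were occupied. The MVL_max location is the argmax (ties
    broken toward the smallest row-major index).
    """

    ref_x: np.ndarray
    ref_y: np.ndarray
    mvl: np.ndarray              # (n, n), [iy, ix]
    preferred_bearing: np.ndarray

    @property
    def mvlmax_location(self) -> tuple[float, float]:
        flat = np.where(np.isfinite(self.mvl), self.mvl, -np.inf).ravel()
        k = int(np.argmax(flat))
        iy, ix = divmod(k, self.mvl.shape[1])
        return (float(self.ref_x[ix]), float(self.ref_y[iy]))

    @property
    def max_mvl(self) -> float:
        return float(np.nanmax(self.mvl))

    @property
    def normalized(self) -> np.ndarray:
        m = self.max_mvl
        return self.mvl / m if m > 0 else self.mvl


def mvl_map(
    tracking: TrackingData,
    spikes: SpikeTrain,
    arena: ArenaGeometry | None = None,
    n_grid: int = 20,
    bin_width: float = 12.0,
    min_bin_coverage: float = 0.5,
    cache: BearingBinCache | None = None,
) -> MVLMap:
    """MVL of the egocentric-bearing tuning curve at every grid reference point.

    Passing a precomputed ``cache`` (from :func:`precompute_bearing_bins`)
    amortizes the bearing computation across cells of one session.
    """
    arena = arena or ArenaGeometry()
    if cache is None:
        cache = precompute_bearing_bins(tracking, arena, n_grid, bin_width)
    counts = spikes.counts_per_frame(tracking)
    n_bins = cache.n_bins
    n = cache.ref_x.size
    centers = np.deg2rad((np.arange(n_bins) + 0.5) * bin_width)
    phasors = np.exp(1j * centers)

    mvl = np.full((n, n), np.nan)
    pref = np.full((n, n), np.nan)
    for k in range(n * n):
        bi = cache.bin_idx[k]
        ok = bi >= 0
        occ = np.bincount(bi[ok], minlength=n_bins) * cache.dt
        occupied = occ > 0
        if occupied.mean() < min_bin_coverage:
            continue
        spk = np.bincount(bi[ok], weights=counts[ok], minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(occupied, spk / occ, 0.0)
        total = rate.sum()
        if total <= 0:
            continue
        res = np.sum(rate * phasors) / total
        iy, ix = divmod(k, n)
        mvl[iy, ix] = np.abs(res)
        pref[iy, ix] = np.mod(np.rad2deg(np.angle(res)), 360.0)
    return MVLMap(ref_x=cache.ref_x, ref_y=cache.ref_y, mvl=mvl, preferred_bearing=pref)


def population_mvl_summary(maps: list[MVLMap], arena: ArenaGeometry | None = None) -> dict:
    """Histogram of MVL_max locations on the reference grid, element-wise
    mean of per-cell normalized MVL maps, and goal-vs-equivalent-zone mean
    MVL extraction."""
    if not maps:
        raise ValueError("need at least one MVL map")
    arena = arena or ArenaGeometry()
    ref_x, ref_y = maps[0].ref_x, maps[0].ref_y
    n = ref_x.size

    hist = np.zeros((n, n))
    for m in maps:
        x, y = m.mvlmax_location
        ix = int(np.argmin(np.abs(ref_x - x)))
        iy = int(np.argmin(np.abs(ref_y - y)))
        hist[iy, ix] += 1

    mean_map = np.nanmean(np.stack([m.normalized for m in maps]), axis=0)

    xx, yy = np.meshgrid(ref_x, ref_y)
    zone_means = {}
    from .behavior import ZONE_LABELS

    for label, center in zip(ZONE_LABELS, arena.equivalent_zone_centers()):
        inz = zone_membership(xx.ravel(), yy.ravel(), center, arena.goal_zone_side).reshape(n, n)
        zone_means[label] = float(np.nanmean(mean_map[inz]))
    return {"mvlmax_histogram": hist, "mean_normalized_map": mean_map, "zone_means": zone_means}


def mvlmax_rotation_about_center(loc_a, loc_b, center) -> float:
    """Signed rotation (deg, CCW-positive, in [-180, 180)) carrying the
    MVL_max location of session A onto that of session B about the arena
    center; NaN when either location coincides with the center."""
    a = np.asarray(loc_a, dtype=float) - np.asarray(center, dtype=float)
    b = np.asarray(loc_b, dtype=float) - np.asarray(center, dtype=float)
    if np.hypot(*a) == 0 or np.hypot(*b) == 0:
        return float("nan")
    ang_a = np.rad2deg(np.arctan2(a[1], a[0]))
    ang_b = np.rad2deg(np.arctan2(b[1], b[0]))
    return float(circdiff_deg(ang_b, ang_a))
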