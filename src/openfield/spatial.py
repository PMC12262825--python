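"""Allocentric map scores and cell classification.

Implements the standard open-field battery: spatial autocorrelogram and
grid score (hexagonality of the autocorrelogram annulus), border score
``(c - d)/(c + d)``, spatial information (bits/spike), firing-field
detection with rate-weighted centroids, normalized population maps, and the
combined classification rules that turn GLM variable selections plus scores
into cell-type flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .geometry import ArenaGeometry, zone_membership
from .tuning import RateMap2D, smoothed_occupancy

log = logging.getLogger(__name__)

GLM_LOCATION = "location"
GLM_HD = "hd"
GLM_CB = "center_bearing"
GLM_CD = "center_distance"

#: 4-connectivity structuring element for field labeling
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


# --------------------------------------------------------- autocorrelation
def spatial_autocorrelation(ratemap: RateMap2D, min_overlap: int = 20) -> np.ndarray:
    """2D spatial autocorrelogram: Pearson correlation of the smoothed map
    with itself at every integer bin shift, over overlapping visited bins.

    Shifts with fewer than ``min_overlap`` overlapping bins are NaN. For a
    constant map every correlation is undefined (all-NaN result).
    """
    rate = ratemap.rate_smoothed
    m = np.isfinite(rate).astype(float)
    if m.sum() < 2:
        raise ValueError("autocorrelation needs at least 2 visited bins")
    x = np.where(np.isfinite(rate), rate, 0.0)

    def xcorr(a, b):
        return fftconvolve(a, b[::-1, ::-1], mode="full")

    n = xcorr(m, m)
    sx = xcorr(x, m)
    sy = xcorr(m, x)
    sxy = xcorr(x, x)
    sxx = xcorr(x * x, m)
    syy = xcorr(m, x * x)

    n = np.round(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        var1 = n * sxx - sx * sx
        var2 = n * syy - sy * sy
        # a relative floor keeps FFT round-off from fabricating correlations
        # on (near-)constant overlaps
        floor = 1e-9 * np.maximum(n * np.abs(sxx), 1e-30)
        bad = (var1 < floor) | (var2 < floor)
        den = np.sqrt(np.clip(var1, 0, None) * np.clip(var2, 0, None))
        ac = num / den
    ac[(n < min_overlap) | bad | ~np.isfinite(ac)] = np.nan
    ac = np.clip(ac, -1.0, 1.0)
    center = (ac.shape[0] // 2, ac.shape[1] // 2)
    if np.isfinite(ac[center]):
        ac[center] = 1.0
    return ac


def _radial_profile(ac: np.ndarray) -> np.ndarray:
    """Mean autocorrelation in 1-bin-wide annuli about the center."""
    cy, cx = ac.shape[0] // 2, ac.shape[1] // 2
    yy, xx = np.indices(ac.shape)
    r = np.round(np.hypot(yy - cy, xx - cx)).astype(int)
    nmax = r.max() + 1
    prof = np.full(nmax, np.nan)
    for k in range(nmax):
        vals = ac[(r == k) & np.isfinite(ac)]
        if vals.size:
            prof[k] = vals.mean()
    return prof


def estimate_ring_radii(ac: np.ndarray) -> tuple[float, float]:
    """Inner/outer radius (bins) of the autocorrelogram's hexagonal ring.

    Heuristic: on the radial profile, the inner radius is the first local
    minimum after the central peak and the outer radius is 1.5x the radius
    of the next local maximum, capped at half the map extent. Falls back to
    ``[2, half extent]`` when no extrema are found.
    """
    prof = _radial_profile(ac)
    half_extent = min(ac.shape) / 2.0
    inner, outer = None, None
    for k in range(1, prof.size - 1):
        if not (np.isfinite(prof[k - 1]) and np.isfinite(prof[k]) and np.isfinite(prof[k + 1])):
            continue
        if inner is None and prof[k] < prof[k - 1] and prof[k] <= prof[k + 1]:
            inner = float(k)
        elif inner is not None and prof[k] > prof[k - 1] and prof[k] >= prof[k + 1]:
            outer = min(1.5 * k, half_extent)
            break
    if inner is None or outer is None or outer <= inner:
        return 2.0, half_extent
    return inner, outer


def annulus_rotation_correlations(
    ac: np.ndarray, inner: float, outer: float, step_deg: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of the autocorrelogram annulus with rotated copies
    of itself at ``step_deg`` offsets from 0 to 180 degrees (inclusive)."""
    cy, cx = ac.shape[0] // 2, ac.shape[1] // 2
    yy, xx = np.indices(ac.shape)
    rad = np.hypot(yy - cy, xx - cx)
    annulus = (rad >= inner) & (rad <= outer)

    finite = np.isfinite(ac)
    filled = np.where(finite, ac, 0.0)
    angles = np.arange(0.0, 180.0 + step_deg / 2, step_deg)
    corrs = np.full(angles.size, np.nan)
    for i, a in enumerate(angles):
        rot = ndimage.rotate(filled, a, reshape=False, order=1, mode="constant", cval=0.0)
        rot_mask = ndimage.rotate(finite.astype(float), a, reshape=False, order=1, mode="constant", cval=0.0)
        ok = annulus & finite & (rot_mask > 0.99)
        if ok.sum() < 20:
            continue
        u, v = ac[ok], rot[ok]
        su, sv = u.std(), v.std()
        if su > 0 and sv > 0:
            corrs[i] = float(np.mean((u - u.mean()) * (v - v.mean())) / (su * sv))
    return angles, corrs


def grid_score(ratemap: RateMap2D) -> float:
    """Grid score: min(corr at 60, 120 deg) - max(corr at 30, 90, 150 deg)
    of the autocorrelogram annulus rotated against itself.

    NaN when the autocorrelogram or the required rotation correlations are
    undefined (such a cell cannot be a grid cell).
    """
    try:
        ac = spatial_autocorrelation(ratemap)
    except ValueError:
        return float("nan")
    if not np.isfinite(ac).any():
        return float("nan")
    inner, outer = estimate_ring_radii(ac)
    angles, corrs = annulus_rotation_correlations(ac, inner, outer)

    def at(angle):
        return corrs[int(np.argmin(np.abs(angles - angle)))]

    on = [at(60.0), at(120.0)]
    off = [at(30.0), at(90.0), at(150.0)]
    if not (np.all(np.isfinite(on)) and np.all(np.isfinite(off))):
        return float("nan")
    return float(min(on) - max(off))


# -------------------------------------------------------------- border score
@dataclass(frozen=True)
class BorderScoreResult:
    """Border score ``(c - d)/(c + d)``: c is the maximum coverage of any
    single wall by a single field; d is the rate-weighted mean nearest-wall
    distance of field bins normalized by half the wall length (60 cm)."""

    c: float
    d: float
    score: float
    n_fields: int


def border_score(
    ratemap: RateMap2D,
    arena: ArenaGeometry | None = None,
    rate_threshold_pct: float = 20.0,
    min_area_cm2: float = 200.0,
) -> BorderScoreResult | None:
    """Border score of the smoothed map; None when no field qualifies."""
    arena = arena or ArenaGeometry()
    rate = ratemap.rate_smoothed
    if not np.isfinite(rate).any() or np.nanmax(rate) <= 0:
        return None
    thr = np.nanmax(rate) * rate_threshold_pct / 100.0
    mask = np.isfinite(rate) & (rate >= thr)
    labels, n_lab = ndimage.label(mask, structure=_STRUCT4)
    bin_area = ratemap.bin_size**2
    min_bins = int(np.ceil(min_area_cm2 / bin_area))
    keep = [k for k in range(1, n_lab + 1) if (labels == k).sum() >= min_bins]
    if not keep:
        return None

    n = rate.shape[0]
    side = arena.side_length
    # wall-adjacent bin rows: south = row 0, north = last row, west = col 0, east = last col
    walls = {
        "south": labels[0, :],
        "north": labels[-1, :],
        "west": labels[:, 0],
        "east": labels[:, -1],
    }
    c = 0.0
    for row in walls.values():
        for k in keep:
            c = max(c, float(np.mean(row == k)))

    yy, xx = np.indices(rate.shape)
    xc = (xx + 0.5) * ratemap.bin_size
    yc = (yy + 0.5) * ratemap.bin_size
    wall_dist = np.minimum.reduce([xc, side - xc, yc, side - yc])
    in_field = np.isin(labels, keep)
    w = rate[in_field]
    d = float(np.sum(w * wall_dist[in_field]) / np.sum(w)) / (side / 2.0)

    score = (c - d) / (c + d) if (c + d) > 0 else float("nan")
    return BorderScoreResult(c=c, d=d, score=float(score), n_fields=len(keep))


# ------------------------------------------------------- spatial information
def spatial_information(rate: np.ndarray, occupancy: np.ndarray) -> float:
    """Skaggs spatial information in bits/spike:
    ``SI = sum_i P_i (R_i/R) log2(R_i/R)`` over visited bins, with
    ``R = sum_i P_i R_i``; zero-rate terms contribute 0; NaN when the mean
    rate is zero."""
    rate = np.asarray(rate, dtype=float)
    occ = np.asarray(occupancy, dtype=float)
    ok = np.isfinite(rate) & np.isfinite(occ) & (occ > 0)
    if not ok.any():
        return float("nan")
    p = occ[ok] / occ[ok].sum()
    r = rate[ok]
    mean_rate = float(np.sum(p * r))
    if mean_rate <= 0:
        return float("nan")
    ratio = r / mean_rate
    terms = np.where(r > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return float(np.sum(terms))


def spatial_information_map(ratemap: RateMap2D, smooth_sigma: float = 3.75) -> float:
    """Spatial information of a rate map, using the smoothed rate map and an
    occupancy histogram smoothed with the same kernel."""
    occ = smoothed_occupancy(ratemap, smooth_sigma)
    return spatial_information(ratemap.rate_smoothed, occ)


# ------------------------------------------------------------------- fields
@dataclass(frozen=True)
class FieldSet:
    """Detected firing fields: connected supra-threshold components."""

    bin_lists: list  # list of (iy, ix) index arrays
    areas_cm2: np.ndarray
    centroids: np.ndarray  # (n_fields, 2) in cm, (x, y)
    threshold_pct: float
    min_area_cm2: float

    def __len__(self) -> int:
        return len(self.bin_lists)


def detect_fields(
    ratemap: RateMap2D, threshold_pct: float = 30.0, min_area_cm2: float = 150.0
) -> FieldSet:
    """Firing fields: 4-connected components of bins above ``threshold_pct``
    of the peak rate with area >= ``min_area_cm2``; centroids are
    rate-weighted mean bin-center positions."""
    rate = ratemap.rate_smoothed
    empty = FieldSet([], np.empty(0), np.empty((0, 2)), threshold_pct, min_area_cm2)
    if not np.isfinite(rate).any() or np.nanmax(rate) <= 0:
        return empty
    thr = np.nanmax(rate) * threshold_pct / 100.0
    mask = np.isfinite(rate) & (rate >= thr)
    labels, n_lab = ndimage.label(mask, structure=_STRUCT4)
    bin_area = ratemap.bin_size**2

    bin_lists, areas, centroids = [], [], []
    for k in range(1, n_lab + 1):
        iy, ix = np.nonzero(labels == k)
        area = iy.size * bin_area
        if area < min_area_cm2:
            continue
        w = rate[iy, ix]
        xc = (ix + 0.5) * ratemap.bin_size
        yc = (iy + 0.5) * ratemap.bin_size
        centroids.append((np.sum(w * xc) / w.sum(), np.sum(w * yc) / w.sum()))
        areas.append(area)
        bin_lists.append((iy, ix))
    if not bin_lists:
        return empty
    return FieldSet(bin_lists, np.asarray(areas), np.asarray(centroids), threshold_pct, min_area_cm2)


# -------------------------------------------------------- population maps
def population_normalized_map(
    maps: list[RateMap2D],
    arena: ArenaGeometry | None = None,
    invert: list[bool] | None = None,
) -> dict:
    """Min-max rescale each smoothed map to [0, 1], optionally invert
    (``1 - map``, for center-distance cells with negative slopes), and
    average element-wise; extract goal-zone vs equivalent-zone means.

    Constant maps cannot be rescaled and are excluded (logged).
    """
    if not maps:
        raise ValueError("need at least one map")
    arena = arena or ArenaGeometry()
    invert = invert or [False] * len(maps)

    rescaled = []
    for m, inv in zip(maps, invert):
        r = m.rate_smoothed
        lo, hi = np.nanmin(r), np.nanmax(r)
        if not np.isfinite(lo) or hi - lo == 0:
            log.info("population map: excluding constant map")
            continue
        s = (r - lo) / (hi - lo)
        rescaled.append(1.0 - s if inv else s)
    if not rescaled:
        raise ValueError("all maps constant; nothing to average")
    mean_map = np.nanmean(np.stack(rescaled), axis=0)

    bin_size = maps[0].bin_size
    n = mean_map.shape[0]
    yy, xx = np.indices(mean_map.shape)
    xc = (xx + 0.5) * bin_size
    yc = (yy + 0.5) * bin_size
    zone_means = {}
    from .behavior import ZONE_LABELS

    for label, center in zip(ZONE_LABELS, arena.equivalent_zone_centers()):
        inz = zone_membership(xc.ravel(), yc.ravel(), center, arena.goal_zone_side).reshape(n, n)
        zone_means[label] = float(np.nanmean(mean_map[inz]))
    return {"mean_map": mean_map, "zone_means": zone_means, "n_maps": len(rescaled)}


# ----------------------------------------------------------- classification
@dataclass(frozen=True)
class CellClassification:
    """Combined cell-type flags from GLM variable selection plus scores.

    Grid/border/non-grid are mutually exclusive with grid taking precedence
    over border, and non-grid requiring neither. In POR the head-direction
    flag is reported under the landmark-modulated label (``lm_hd``).
    """

    grid: bool
    border: bool
    nongrid_spatial: bool
    hd: bool
    cb: bool
    cd: bool
    region: str = "MEC_PaS"
    scores: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        out = []
        for name in ("grid", "border", "nongrid_spatial", "cb", "cd"):
            if getattr(self, name):
                out.append(name)
        if self.hd:
            out.append("lm_hd" if self.region == "POR" else "hd")
        return out

    @property
    def unclassified(self) -> bool:
        return not self.labels


def _passes(value, threshold) -> bool:
    return bool(np.isfinite(value) and np.isfinite(threshold) and value > threshold)


def classify_cell(
    selected_variables: set[str],
    scores: dict,
    shuffle_thresholds: dict,
    region: str = "MEC_PaS",
    grid_threshold: float = 0.4,
    border_threshold: float = 0.5,
    mvl_floor: float = 0.2,
    peak_rate_floor: float = 1.0,
) -> CellClassification:
    """Apply the combined classification rules.

    ``scores`` keys: grid_score, border_score, spatial_information, hd_mvl,
    hd_peak_rate, cb_mvl, cb_peak_rate, cd_linear_r2, cd_gaussian_r2,
    cd_peak_rate (missing/NaN scores simply fail their rule).
    ``shuffle_thresholds`` keys: spatial_information, hd_mvl, cb_mvl,
    cd_linear_r2, cd_gaussian_r2 — each fit type is compared against the
    shuffle distribution of the same fit type.
    """
    s = {k: scores.get(k, float("nan")) for k in (
        "grid_score", "border_score", "spatial_information",
        "hd_mvl", "hd_peak_rate", "cb_mvl", "cb_peak_rate",
        "cd_linear_r2", "cd_gaussian_r2", "cd_peak_rate",
    )}
    th = {k: shuffle_thresholds.get(k, float("nan")) for k in (
        "spatial_information", "hd_mvl", "cb_mvl", "cd_linear_r2", "cd_gaussian_r2",
    )}
    loc = GLM_LOCATION in selected_variables

    grid = loc and _passes(s["grid_score"], grid_threshold)
    border = loc and not grid and _passes(s["border_score"], border_threshold)
    nongrid = loc and not grid and not border and _passes(s["spatial_information"], th["spatial_information"])
    hd = (
        GLM_HD in selected_variables
        and _passes(s["hd_mvl"], th["hd_mvl"])
        and _passes(s["hd_mvl"], mvl_floor)
        and _passes(s["hd_peak_rate"], peak_rate_floor)
    )
    cb = (
        GLM_CB in selected_variables
        and _passes(s["cb_mvl"], th["cb_mvl"])
        and _passes(s["cb_mvl"], mvl_floor)
        and _passes(s["cb_peak_rate"], peak_rate_floor)
    )
    cd = (
        GLM_CD in selected_variables
        and (_passes(s["cd_linear_r2"], th["cd_linear_r2"]) or _passes(s["cd_gaussian_r2"], th["cd_gaussian_r2"]))
        and _passes(s["cd_peak_rate"], peak_rate_floor)
    )
    return CellClassification(
        grid=grid, border=border, nongrid_spatial=nongrid, hd=hd, cb=cb, cd=cd,
        region=region, scores=s, thresholds=th,
    )
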