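"""Responses to visual-cue manipulation: preferred-direction shifts,
bidirectionality under cue duplication, bidirectional von Mises fits with
per-cue modulation indices, and rotated-map correlations.

The bidirectionality index contrasts the mean vector length of the
head-direction tuning curve built from doubled angles (which collapses two
opposite lobes onto one) with the ordinary MVL:
``BI = (MVL_doubled - MVL_normal) / (MVL_doubled + MVL_normal)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .circstats import rayleigh_test, v_test  # noqa: F401  (re-exported: population tests)
from .geometry import circdiff_deg
from .session import SpikeTrain, TrackingData
from .tuning import CircularTuningCurve, RateMap2D, circular_tuning_curve


# ---------------------------------------------------------- bidirectionality
def bidirectionality_from_angles(
    angles_deg, spike_counts, dt: float, bin_width: float = 12.0
) -> dict:
    """MVL_normal, MVL_doubled and BI from per-frame head directions."""
    angles = np.asarray(angles_deg, dtype=float)
    normal = circular_tuning_curve(angles, spike_counts, dt, bin_width)
    doubled = circular_tuning_curve(np.mod(2.0 * angles, 360.0), spike_counts, dt, bin_width)
    m_n, m_d = normal.mvl, doubled.mvl
    if not (np.isfinite(m_n) and np.isfinite(m_d)) or (m_n + m_d) == 0:
        bi = float("nan")
    else:
        bi = (m_d - m_n) / (m_d + m_n)
    return {"mvl_normal": m_n, "mvl_doubled": m_d, "bi": float(bi)}


def bidirectionality_index(tracking: TrackingData, spikes: SpikeTrain, bin_width: float = 12.0) -> dict:
    """Bidirectionality of a cell's HD tuning in one session."""
    return bidirectionality_from_angles(
        tracking.hd, spikes.counts_per_frame(tracking), tracking.dt, bin_width
    )


# ------------------------------------------------------------ von Mises fits
@dataclass(frozen=True)
class VonMisesFit:
    """Bidirectional von Mises fit: two lobes exactly 180 degrees apart with
    shared concentration and separate amplitudes, plus an offset. ``mode``
    is "peak" (upright lobes) or "trough" (inverted lobes)."""

    mode: str
    mu: float            # first lobe direction, deg in [0, 360)
    amp1: float
    amp2: float
    kappa: float
    offset: float
    max_fit: float
    min_fit: float
    r2: float

    def predict(self, angles_deg) -> np.ndarray:
        a = np.deg2rad(np.asarray(angles_deg, dtype=float) - self.mu)
        g1 = np.exp(self.kappa * (np.cos(a) - 1.0))
        g2 = np.exp(self.kappa * (np.cos(a - np.pi) - 1.0))
        sign = 1.0 if self.mode == "peak" else -1.0
        return self.offset + sign * (self.amp1 * g1 + self.amp2 * g2)

    @property
    def lobe_directions(self) -> tuple[float, float]:
        return (self.mu, float(np.mod(self.mu + 180.0, 360.0)))


def fit_bidirectional_von_mises(curve: CircularTuningCurve, mode: str = "peak") -> VonMisesFit:
    """Least-squares bidirectional von Mises fit to a tuning curve.

    Multi-start over 12 initial lobe directions; the best-loss fit is
    returned. A flat curve yields near-zero amplitudes (low-quality fit is
    visible through r2 ~ 0).
    """
    if mode not in ("peak", "trough"):
        raise ValueError("mode must be 'peak' or 'trough'")
    ok = np.isfinite(curve.rate)
    if ok.sum() < 8:
        raise ValueError("too few occupied bins for a von Mises fit")
    theta = np.deg2rad(curve.bin_centers[ok])
    y = curve.rate[ok]
    sign = 1.0 if mode == "peak" else -1.0
    scale = max(float(np.ptp(y)), 1e-9)

    def model(params):
        mu, a1, a2, kappa, off = params
        g1 = np.exp(kappa * (np.cos(theta - mu) - 1.0))
        g2 = np.exp(kappa * (np.cos(theta - mu - np.pi) - 1.0))
        return off + sign * (a1 * g1 + a2 * g2)

    best = None
    lower = [-np.inf, 0.0, 0.0, 0.05, -np.inf]
    upper = [np.inf, np.inf, np.inf, 50.0, np.inf]
    for mu0 in np.deg2rad(np.arange(0.0, 360.0, 30.0)):
        p0 = [mu0, scale, scale / 2.0, 2.0, float(np.min(y)) if mode == "peak" else float(np.max(y))]
        try:
            res = optimize.least_squares(
                lambda p: model(p) - y, p0, bounds=(lower, upper), max_nfev=2000
            )
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("von Mises fit failed from every start")

    mu, a1, a2, kappa, off = best.x
    mu = float(np.mod(np.rad2deg(mu), 360.0))
    # canonical orientation: first lobe is the larger one
    if a2 > a1:
        a1, a2 = a2, a1
        mu = float(np.mod(mu + 180.0, 360.0))
    fine = np.linspace(0.0, 360.0, 721)
    fit = VonMisesFit(
        mode=mode, mu=mu, amp1=float(a1), amp2=float(a2), kappa=float(kappa), offset=float(off),
        max_fit=0.0, min_fit=0.0, r2=0.0,
    )
    pred_fine = fit.predict(fine)
    ss_res = float(np.sum((model(best.x) - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return VonMisesFit(
        mode=mode, mu=mu, amp1=float(a1), amp2=float(a2), kappa=float(kappa), offset=float(off),
        max_fit=float(pred_fine.max()), min_fit=float(pred_fine.min()), r2=float(r2),
    )


def cue_modulation_indices(fit: VonMisesFit, session1_preferred_deg: float) -> tuple[float, float]:
    """Per-cue modulation indices (MI_S, MI_N) from a bidirectional fit.

    The fitted lobe circularly nearest the session-1 preferred (or trough)
    direction is attributed to the south cue. For peak fits,
    ``MI = (P - Min_fit)/Max_fit`` with P the fitted rate at the lobe; for
    trough fits, ``MI = (Max_fit - T)/Max_fit``.
    """
    if fit.max_fit <= 0:
        return float("nan"), float("nan")
    d1, d2 = fit.lobe_directions
    if abs(circdiff_deg(d1, session1_preferred_deg)) <= abs(circdiff_deg(d2, session1_preferred_deg)):
        south, north = d1, d2
    else:
        south, north = d2, d1

    def mi(lobe_dir: float) -> float:
        v = float(fit.predict(lobe_dir))
        if fit.mode == "peak":
            return (v - fit.min_fit) / fit.max_fit
        return (fit.max_fit - v) / fit.max_fit

    return mi(south), mi(north)


# ------------------------------------------------------------------- shifts
def preferred_direction_shift(curve1: CircularTuningCurve, curve2: CircularTuningCurve) -> float:
    """Signed circular change in preferred firing direction (deg in
    [-180, 180), CCW-positive); NaN when either curve has no preferred
    direction."""
    p1, p2 = curve1.preferred_direction, curve2.preferred_direction
    if not (np.isfinite(p1) and np.isfinite(p2)):
        return float("nan")
    return float(circdiff_deg(p2, p1))


# ------------------------------------------------------- map correlations
def rotate_map_quarter_turns(arr: np.ndarray, k: int) -> np.ndarray:
    """Rotate a ``[iy, ix]``-indexed map by ``k`` quarter turns
    counterclockwise in world coordinates (about the arena center)."""
    return np.rot90(arr, -k)


def rotated_map_correlations(
    map1: RateMap2D, map2: RateMap2D, min_overlap: int = 20
) -> dict[int, float]:
    """Pearson correlation between map1 and map2 rotated by 0/90/180/270
    degrees about the arena center, over mutually visited bins."""
    a = map1.rate_smoothed
    out = {}
    for k, angle in enumerate((0, 90, 180, 270)):
        # rotate map2 *back* by the labeled angle: the correlation at 90 deg
        # is maximal when map2 is map1 rotated +90 deg in world coordinates
        b = rotate_map_quarter_turns(map2.rate_smoothed, -k)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < min_overlap:
            out[angle] = float("nan")
            continue
        u, v = a[ok], b[ok]
        su, sv = u.std(), v.std()
        if su == 0 or sv == 0:
            out[angle] = float("nan")
            continue
        out[angle] = float(np.mean((u - u.mean()) * (v - v.mean())) / (su * sv))
    return out
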