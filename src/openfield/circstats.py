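"""Circular statistics: mean vector length, Rayleigh test and V-test.

The mean vector length (MVL) of a tuning curve is the magnitude of the
rate-weighted mean resultant over bin-center angles; it measures tuning
strength on [0, 1]. The Rayleigh test rejects uniformity of a sample of
angles; the V-test additionally concentrates power at a pre-specified
direction.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def resultant(angles_deg, weights=None) -> complex:
    """Weighted mean resultant vector of angles (degrees) as a complex number."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if weights is None:
        weights = np.ones_like(a)
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total == 0:
        return complex(np.nan, np.nan)
    return complex(np.sum(w * np.exp(1j * a)) / total)


def mvl(angles_deg, weights=None) -> float:
    """Mean vector length in [0, 1]; NaN when total weight is zero."""
    r = resultant(angles_deg, weights)
    return float(np.abs(r))


def circmean_deg(angles_deg, weights=None) -> float:
    """Circular mean direction in [0, 360); NaN when resultant is undefined or zero."""
    r = resultant(angles_deg, weights)
    if not np.isfinite(r.real) or abs(r) == 0:
        return float("nan")
    mean = float(np.mod(np.rad2deg(np.angle(r)), 360.0))
    return 0.0 if mean >= 360.0 else mean


def rayleigh_test(angles_deg) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns ``(r, P)`` where r is the mean resultant length and P the
    large-sample approximation ``exp(-Z) * (1 + (2Z - Z^2) / 4n)`` with
    ``Z = n r^2`` (first-order small-n correction), clipped to [0, 1].
    """
    a = np.asarray(angles_deg, dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("Rayleigh test requires at least 2 angles")
    r = mvl(a)
    z = n * r * r
    p = np.exp(-z) * (1.0 + (2.0 * z - z * z) / (4.0 * n))
    return r, float(np.clip(p, 0.0, 1.0))


def v_test(angles_deg, mu_deg) -> tuple[float, float]:
    """V-test for concentration of angles around a pre-specified direction mu.

    Returns ``(u, P)`` where ``V = n r cos(mean - mu)``, ``u = V sqrt(2/n)``
    and P is the upper tail of the standard normal approximation.
    """
    a = np.asarray(angles_deg, dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("V-test requires at least 2 angles")
    r = mvl(a)
    mean = circmean_deg(a)
    v = n * r * np.cos(np.deg2rad(mean - mu_deg))
    u = v * np.sqrt(2.0 / n)
    p = float(norm.sf(u))
    return float(u), p
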