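"""Behavioral task metrics: goal-zone events, rewards, occupancy comparisons
against rotationally equivalent zones, and approach/departure directions."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .circstats import rayleigh_test
from .geometry import ArenaGeometry, zone_membership
from .session import TrackingData

log = logging.getLogger(__name__)

#: fixed reporting order of the goal zone's rotational images for the
#: default geometry (goal in the northwest quadrant)
ZONE_LABELS = ("NW", "SW", "SE", "NE")


@dataclass(frozen=True)
class ZoneEvents:
    """Entries, exits and rewards for one zone.

    A reward is an entry occurring at least ``timeout_s`` after the previous
    reward (the first entry is always rewarded), mirroring the task's
    reward-timeout rule.
    """

    entry_times: np.ndarray
    exit_times: np.ndarray
    reward_times: np.ndarray
    occupancy_s: float
    entries_per_min: float


def detect_zone_events(
    tracking: TrackingData,
    zone_center,
    zone_side: float,
    timeout_s: float = 10.0,
) -> ZoneEvents:
    """Detect zone entries/exits and timeout-honoring rewards.

    An entry is a frame inside the zone whose predecessor is outside
    (membership uses half-open square bounds). Occupancy counts all frames
    inside the zone.
    """
    if len(tracking) == 0:
        raise ValueError("tracking is empty")
    if timeout_s < 0:
        raise ValueError("timeout must be non-negative")
    inside = zone_membership(tracking.x, tracking.y, zone_center, zone_side)
    dt = tracking.dt

    trans = np.diff(inside.astype(int))
    entry_idx = np.flatnonzero(trans == 1) + 1
    exit_idx = np.flatnonzero(trans == -1) + 1
    if inside[0]:
        entry_idx = np.concatenate([[0], entry_idx])
    entry_times = tracking.time[entry_idx]
    exit_times = tracking.time[exit_idx]

    rewards = []
    last = -np.inf
    for t in entry_times:
        if t - last >= timeout_s:
            rewards.append(t)
            last = t
    duration = tracking.duration
    return ZoneEvents(
        entry_times=entry_times,
        exit_times=exit_times,
        reward_times=np.asarray(rewards),
        occupancy_s=float(inside.sum() * dt),
        entries_per_min=float(entry_times.size / (duration / 60.0)),
    )


def equivalent_zone_comparison(
    tracking: TrackingData,
    arena: ArenaGeometry,
    timeout_s: float = 10.0,
) -> dict[str, ZoneEvents]:
    """Zone statistics for the goal zone and its three 90-degree rotational
    images about the arena center, keyed NW/SW/SE/NE (default geometry)."""
    centers = arena.equivalent_zone_centers()
    return {
        label: detect_zone_events(tracking, center, arena.goal_zone_side, timeout_s)
        for label, center in zip(ZONE_LABELS, centers)
    }


def approach_departure_directions(
    tracking: TrackingData,
    zone_center,
    zone_side: float,
    window_s: float = 1.0,
) -> dict:
    """Head directions around zone entries and exits, with Rayleigh statistics.

    For each entry, the head direction at the start of the ``window_s``-long
    pre-entry segment; for each exit, the head direction at the end of the
    ``window_s``-long post-exit segment. Events whose window falls outside
    the session are skipped and logged.
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    events = detect_zone_events(tracking, zone_center, zone_side)
    t0, t1 = tracking.time[0], tracking.time[-1]

    approach, skipped = [], 0
    for t in events.entry_times:
        if t - window_s < t0:
            skipped += 1
            continue
        f = int(tracking.frame_of(t - window_s))
        approach.append(tracking.hd[f])
    departure = []
    for t in events.exit_times:
        if t + window_s > t1:
            skipped += 1
            continue
        f = int(tracking.frame_of(t + window_s))
        departure.append(tracking.hd[f])
    if skipped:
        log.info("approach/departure: skipped %d events with out-of-session windows", skipped)

    out = {
        "approach_hd": np.asarray(approach),
        "departure_hd": np.asarray(departure),
        "approach_r": float("nan"),
        "approach_p": float("nan"),
        "departure_r": float("nan"),
        "departure_p": float("nan"),
        "n_skipped": skipped,
    }
    if len(approach) >= 2:
        out["approach_r"], out["approach_p"] = rayleigh_test(approach)
    if len(departure) >= 2:
        out["departure_r"], out["departure_p"] = rayleigh_test(departure)
    return out


def behavior_table(tracking: TrackingData, arena: ArenaGeometry, timeout_s: float = 10.0, window_s: float = 1.0):
    """Tidy per-session behavior table (one row per zone)."""
    import pandas as pd

    zones = equivalent_zone_comparison(tracking, arena, timeout_s)
    dirs = approach_departure_directions(tracking, arena.goal_zone_center, arena.goal_zone_side, window_s)
    rows = []
    for label, ev in zones.items():
        rows.append(
            {
                "zone": label,
                "entries_per_min": ev.entries_per_min,
                "occupancy_s": ev.occupancy_s,
                "n_rewards": len(ev.reward_times),
                "approach_r": dirs["approach_r"] if label == "NW" else np.nan,
                "departure_r": dirs["departure_r"] if label == "NW" else np.nan,
            }
        )
    return pd.DataFrame(rows)
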