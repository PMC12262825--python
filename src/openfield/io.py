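"""Session serialization: tracking CSV, plain-text spike files and a YAML
session manifest.

Formats are deliberately plain text: tracking as CSV with header
``time_s,x_cm,y_cm,hd_deg``; spike trains as one timestamp (s) per line;
the manifest records arena geometry, cue configuration, per-cell region
tags and (for synthetic sessions) the ground-truth model parameters.

Vendor acquisition formats are out of scope: export tracking to the CSV
above (time in seconds, position in cm from the southwest corner, head
direction in degrees counterclockwise from east) and spike trains to one
timestamp per line with whatever converter your acquisition system
provides, then point a manifest at the files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import ArenaGeometry
from .session import SpikeTrain, TrackingData
from .synthetic import TuningModel

log = logging.getLogger(__name__)

TRACKING_COLUMNS = ["time_s", "x_cm", "y_cm", "hd_deg"]


@dataclass
class SessionRecord:
    """A loaded session: tracking, per-cell spikes, region tags, geometry."""

    session_id: str
    tracking: TrackingData
    spikes: dict[str, SpikeTrain]
    regions: dict[str, str]
    arena: ArenaGeometry
    cue_wall: str = "south"
    role: str = "standard1"
    ground_truth: dict | None = None
    n_clipped_samples: int = 0
    n_dropped_spikes: dict[str, int] = dataclasses.field(default_factory=dict)


def write_session(
    out_dir: str | Path,
    tracking: TrackingData,
    spikes: dict[str, SpikeTrain],
    arena: ArenaGeometry,
    regions: dict[str, str] | None = None,
    session_id: str = "session",
    cue_wall: str = "south",
    role: str = "standard1",
    scenario: str | None = None,
    models: dict[str, TuningModel] | None = None,
) -> Path:
    """Write one session to ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    regions = regions or {cid: "MEC_PaS" for cid in spikes}

    df = pd.DataFrame(
        {"time_s": tracking.time, "x_cm": tracking.x, "y_cm": tracking.y, "hd_deg": tracking.hd}
    )
    df.to_csv(out / "tracking.csv", index=False, float_format="%.5f")

    spike_dir = out / "spikes"
    spike_dir.mkdir(exist_ok=True)
    cells = {}
    for cid, train in spikes.items():
        path = spike_dir / f"{cid}.txt"
        np.savetxt(path, train.spike_times, fmt="%.6f")
        cells[cid] = {"spike_file": str(path.relative_to(out)), "region": regions.get(cid, "MEC_PaS")}

    manifest = {
        "session_id": session_id,
        "role": role,
        "cue_wall": cue_wall,
        "scenario": scenario,
        "arena": {
            "side_length": arena.side_length,
            "goal_zone_center": list(arena.goal_zone_center),
            "goal_zone_side": arena.goal_zone_side,
            "cue_wall": cue_wall,
        },
        "tracking": "tracking.csv",
        "cells": cells,
    }
    if models:
        manifest["ground_truth"] = {
            cid: {k: _plain(v) for k, v in dataclasses.asdict(m).items()} for cid, m in models.items()
        }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def _plain(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (list,)):
        return [_plain(x) for x in v]
    return v


def read_session(manifest_path: str | Path) -> SessionRecord:
    """Load and validate a session from its manifest.

    Out-of-arena tracking samples are clipped to the bounds (counted and
    logged); spikes outside the tracked span are dropped (counted per cell).
    Missing columns, unsorted time or empty files raise descriptive errors.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent

    a = manifest.get("arena", {})
    arena = ArenaGeometry(
        side_length=float(a.get("side_length", 120.0)),
        goal_zone_center=tuple(a["goal_zone_center"]) if "goal_zone_center" in a else None,
        goal_zone_side=float(a.get("goal_zone_side", 15.0)),
        cue_wall=a.get("cue_wall", manifest.get("cue_wall", "south")),
    )

    tracking_file = base / manifest["tracking"]
    df = pd.read_csv(tracking_file)
    missing = [c for c in TRACKING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{tracking_file}: missing tracking columns {missing}")
    if df.empty:
        raise ValueError(f"{tracking_file}: tracking file is empty")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValueError(f"{tracking_file}: time not strictly increasing at row {bad[0] + 1}")

    x = df["x_cm"].to_numpy(dtype=float)
    y = df["y_cm"].to_numpy(dtype=float)
    out_of_bounds = int(np.sum(~arena.contains(x, y)))
    if out_of_bounds:
        log.warning("%s: clipped %d out-of-arena samples", tracking_file, out_of_bounds)
        x = np.clip(x, 0.0, arena.side_length)
        y = np.clip(y, 0.0, arena.side_length)
    tracking = TrackingData(time=t, x=x, y=y, hd=np.mod(df["hd_deg"].to_numpy(dtype=float), 360.0))

    spikes: dict[str, SpikeTrain] = {}
    regions: dict[str, str] = {}
    dropped: dict[str, int] = {}
    span_end = tracking.time[-1] + tracking.dt
    for cid, info in manifest.get("cells", {}).items():
        path = base / info["spike_file"]
        if not path.exists():
            raise FileNotFoundError(f"spike file for cell {cid}: {path}")
        times = np.loadtxt(path, ndmin=1, dtype=float) if path.stat().st_size else np.empty(0)
        keep = (times >= tracking.time[0]) & (times < span_end)
        n_drop = int((~keep).sum())
        if n_drop:
            log.warning("cell %s: dropped %d spikes outside the tracked span", cid, n_drop)
        dropped[cid] = n_drop
        spikes[cid] = SpikeTrain(times[keep])
        regions[cid] = info.get("region", "MEC_PaS")

    return SessionRecord(
        session_id=str(manifest.get("session_id", manifest_path.parent.name)),
        tracking=tracking,
        spikes=spikes,
        regions=regions,
        arena=arena,
        cue_wall=manifest.get("cue_wall", "south"),
        role=manifest.get("role", "standard1"),
        ground_truth=manifest.get("ground_truth"),
        n_clipped_samples=out_of_bounds,
        n_dropped_spikes=dropped,
    )
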