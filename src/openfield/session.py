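"""Core in-memory containers: tracking trajectories and spike trains."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TrackingData:
    """Timestamped position and head-direction trajectory of one session.

    Attributes
    ----------
    time : array of float
        Frame start times in seconds, strictly increasing (nominally 30 Hz).
    x, y : array of float
        Position in cm; origin at the southwest corner.
    hd : array of float
        Head direction in degrees, counterclockwise from the positive
        x-axis, wrapped to [0, 360).
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hd: np.ndarray

    def __post_init__(self):
        for name in ("time", "x", "y", "hd"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.time.size
        if n == 0:
            raise ValueError("tracking data is empty")
        if any(getattr(self, k).size != n for k in ("x", "y", "hd")):
            raise ValueError("tracking fields must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("tracking time must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        """Median frame duration in seconds."""
        if len(self) == 1:
            return float("nan")
        return float(np.median(np.diff(self.time)))

    @property
    def duration(self) -> float:
        """Session duration: last frame start plus one frame."""
        return float(self.time[-1] - self.time[0] + self.dt)

    def frame_of(self, t) -> np.ndarray:
        """Index of the frame whose interval [t_f, t_f + dt) contains each time.

        Times before the first frame or at/after the end of the last frame
        map to -1.
        """
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.time, t, side="right") - 1
        idx = np.where(t < self.time[0], -1, idx)
        last_end = self.time[-1] + self.dt
        idx = np.where(t >= last_end, -1, idx)
        return idx

    def subset(self, frame_indices) -> "TrackingData":
        """Tracking restricted to the given (sorted, unique) frame indices."""
        i = np.asarray(frame_indices, dtype=int)
        return TrackingData(self.time[i], self.x[i], self.y[i], self.hd[i])


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike timestamps (seconds) of one unit in one session."""

    spike_times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.spike_times, dtype=float)
        if np.any(np.diff(t) < 0):
            t = np.sort(t)
        if t.size and t[0] < 0:
            raise ValueError("spike times must be non-negative")
        object.__setattr__(self, "spike_times", t)

    def __len__(self) -> int:
        return self.spike_times.size

    def counts_per_frame(self, tracking: TrackingData) -> np.ndarray:
        """Spike count in each tracking frame; spikes outside the span are dropped."""
        idx = tracking.frame_of(self.spike_times)
        idx = idx[idx >= 0]
        return np.bincount(idx, minlength=len(tracking)).astype(float)
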