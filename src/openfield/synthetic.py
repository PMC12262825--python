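"""Synthetic open-field sessions with known ground-truth tuning.

The generator emulates a rat foraging in a 120 x 120 cm arena during a
place-navigation task: 20-minute sessions sampled at 30 Hz, a goal-biased
correlated random walk (zone visits alternating with scattered-pellet
retrieval, 10 s reward timeout), and inhomogeneous-Poisson spike trains from
parametric tuning models for grid, border, non-grid spatial, head-direction
(HD), center-bearing (CB), center-distance (CD), conjunctive CB x HD, and
landmark-modulated HD (LM-HD) cells. Cue-manipulation days are simulated as
standard -> manipulated -> standard session triplets in which cue-following
(POR-like) models rotate or duplicate their directional tuning while
allocentric (MEC/PaS-like) models stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import ArenaGeometry, wrap_deg, wrap_signed_deg, rotate_about, zone_membership
from .session import SpikeTrain, TrackingData

CELL_KINDS = ("grid", "border", "nongrid", "hd", "cb", "cd", "cb_x_hd", "lm_hd")
SCENARIOS = ("ccw_rotation", "cw_rotation", "duplication")
#: cue-card wall in the manipulation session of each scenario
SCENARIO_CUE_WALL = {
    "ccw_rotation": "east",
    "cw_rotation": "west",
    "duplication": "south+north",
}
#: signed cue rotation (deg, CCW-positive) of each scenario
SCENARIO_ANGLE = {"ccw_rotation": 90.0, "cw_rotation": -90.0, "duplication": 0.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated foraging session.

    The defaults reproduce the study conditions: 20-minute sessions at
    30 Hz, a 10 s reward timeout, and 1-4 pellets scattered per reward.
    Trajectory statistics (speed, turning) are free parameters chosen to
    give rat-like smooth paths with full arena coverage.
    """

    duration: float = 1200.0
    frame_rate: float = 30.0
    mean_speed: float = 15.0        # cm/s, OU set point
    speed_sd: float = 6.0           # cm/s, stationary OU sd
    speed_tau: float = 1.0          # s, OU relaxation time
    turn_sd: float = 18.0           # deg per frame, wrapped-Gaussian turning noise
    steer_gain: float = 0.12        # fraction of bearing error corrected per frame at goal_bias=1
    hd_jitter_kappa: float = 100.0  # von Mises concentration of HD about heading
    goal_bias: float = 0.5
    reward_timeout: float = 10.0
    max_pellets: int = 4
    pellet_reach: float = 6.0       # cm, distance at which a pellet counts as retrieved
    forage_time: float = 40.0       # s, mean undirected foraging after pellet retrieval
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")
        n = self.duration * self.frame_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration x frame_rate must be integral")
        if not 0.0 <= self.goal_bias <= 1.0:
            raise ValueError("goal_bias must lie in [0, 1]")
        if not 1 <= self.max_pellets <= 4:
            raise ValueError("max_pellets must be in 1..4")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


@dataclass(frozen=True)
class TuningModel:
    """Parametric firing-rate model of one cell.

    The instantaneous rate is ``baseline_rate + (peak_rate - baseline_rate)
    * shape`` where ``shape`` is a kind-specific modulation in [0, 1], so
    rates are non-negative by construction.

    ``region`` tags whether the cell behaves like a postrhinal (POR,
    cue-following) or medial-entorhinal/parasubicular (MEC_PaS, globally
    anchored) neuron during cue manipulations.
    """

    kind: str
    baseline_rate: float = 0.5
    peak_rate: float = 10.0
    region: str = "MEC_PaS"
    # grid
    spacing: float = 40.0
    orientation: float = 0.0
    phase: tuple[float, float] = (0.0, 0.0)
    field_width: float = 12.0
    # border
    wall: str = "south"
    distance_decay: float = 8.0
    # nongrid: list of (center_xy, width_cm, amplitude<=1)
    fields: Sequence[tuple[tuple[float, float], float, float]] = ()
    # hd / lm_hd
    preferred_direction: float = 0.0
    kappa: float = 4.0
    cue_gain: float = 1.0
    duplication_weight: float = 0.5
    duplication_active: bool = False
    # cb / cb_x_hd
    preferred_bearing: float = 0.0
    bearing_kappa: float = 4.0
    reference_point: tuple[float, float] = (60.0, 60.0)
    # cd
    cd_profile: str = "linear"      # "linear" or "gaussian"
    cd_sign: int = 1                # +1: rate grows with center distance
    cd_mean: float = 30.0           # gaussian profile center, cm
    cd_width: float = 12.0          # gaussian profile sd, cm

    def __post_init__(self):
        if self.kind not in CELL_KINDS:
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if not 0.0 <= self.baseline_rate <= self.peak_rate:
            raise ValueError("rates must satisfy 0 <= baseline <= peak")
        if self.kappa < 0 or self.bearing_kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not (0.0 <= self.cue_gain <= 1.0 and 0.0 <= self.duplication_weight <= 1.0):
            raise ValueError("cue_gain and duplication_weight must lie in [0, 1]")

    # ------------------------------------------------------------------ rate
    def shape(self, tracking: TrackingData, arena: ArenaGeometry) -> np.ndarray:
        """Kind-specific modulation in [0, 1], one value per frame."""
        x, y, hd = tracking.x, tracking.y, tracking.hd
        if self.kind == "grid":
            return self._grid_shape(x, y)
        if self.kind == "border":
            return self._border_shape(x, y, arena)
        if self.kind == "nongrid":
            return self._nongrid_shape(x, y)
        if self.kind in ("hd", "lm_hd"):
            return self._hd_shape(hd)
        if self.kind == "cb":
            return self._bearing_shape(x, y, hd)
        if self.kind == "cd":
            return self._distance_shape(x, y, arena)
        if self.kind == "cb_x_hd":
            return self._bearing_shape(x, y, hd) * self._hd_shape(hd)
        raise AssertionError(self.kind)

    def rate(self, tracking: TrackingData, arena: ArenaGeometry | None = None) -> np.ndarray:
        """Instantaneous firing rate (Hz) at every tracking frame."""
        arena = arena or ArenaGeometry()
        lam = self.baseline_rate + (self.peak_rate - self.baseline_rate) * self.shape(tracking, arena)
        if np.any(lam < 0):
            raise AssertionError("negative rate: model construction violated")
        return lam

    def _grid_shape(self, x, y):
        # three plane waves 60 deg apart; normalized cosine sum in [0, 1],
        # sharpened so bump width tracks field_width
        angles = np.deg2rad(self.orientation + np.array([0.0, 60.0, 120.0]))
        k = 4.0 * np.pi / (np.sqrt(3.0) * self.spacing)
        dx = x - self.phase[0]
        dy = y - self.phase[1]
        z = sum(np.cos(k * (np.cos(a) * dx + np.sin(a) * dy)) for a in angles)
        s = (z + 1.5) / 4.5
        sharp = max(1.0, 0.5 * (self.spacing / self.field_width) ** 2)
        return s ** sharp

    def _border_shape(self, x, y, arena):
        side = arena.side_length
        d = {"south": y, "north": side - y, "west": x, "east": side - x}[self.wall]
        return np.exp(-np.maximum(d, 0.0) / self.distance_decay)

    def _nongrid_shape(self, x, y):
        if not self.fields:
            raise ValueError("nongrid model requires at least one Gaussian field")
        total = np.zeros_like(np.asarray(x, dtype=float))
        for (cx, cy), width, amp in self.fields:
            total += amp * np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * width**2)))
        return np.clip(total, 0.0, 1.0)

    def _von_mises(self, angle_deg, mu_deg, kappa):
        return np.exp(kappa * (np.cos(np.deg2rad(angle_deg - mu_deg)) - 1.0))

    def _hd_shape(self, hd):
        mu = self.preferred_direction
        if self.kind == "lm_hd" and self.duplication_active:
            w = self.duplication_weight

            def mix(angle):
                return (1.0 - w) * self._von_mises(angle, mu, self.kappa) + w * self._von_mises(
                    angle, mu + 180.0, self.kappa
                )

            # normalize by the analytic maximum of the mixture over angle so
            # the peak rate is preserved independent of the sampled headings
            peak = float(mix(np.linspace(0.0, 360.0, 3601)).max())
            return mix(hd) / max(peak, 1e-12)
        return self._von_mises(hd, mu, self.kappa)

    def _bearing_shape(self, x, y, hd):
        rx, ry = self.reference_point
        dx, dy = rx - x, ry - y
        dist = np.hypot(dx, dy)
        bearing = wrap_signed_deg(np.rad2deg(np.arctan2(dy, dx)) - hd)
        s = self._von_mises(bearing, self.preferred_bearing, self.bearing_kappa)
        # bearing is ill-defined on top of the reference point
        return np.where(dist < 1.0, 0.0, s)

    def _distance_shape(self, x, y, arena):
        cx, cy = arena.center
        d = np.hypot(x - cx, y - cy)
        if self.cd_profile == "gaussian":
            return np.exp(-((d - self.cd_mean) ** 2) / (2.0 * self.cd_width**2))
        dmax = arena.side_length / 2.0 * np.sqrt(2.0)
        t = np.clip(d / dmax, 0.0, 1.0)
        return t if self.cd_sign > 0 else 1.0 - t

    # ------------------------------------------------------- cue manipulation
    def follows_cue(self) -> bool:
        return self.region == "POR" and self.kind in ("lm_hd", "cb_x_hd")

    def under_cue_scenario(self, scenario: str, arena: ArenaGeometry) -> "TuningModel":
        """Model as expressed in the manipulation session of a cue triplet."""
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}")
        if not self.follows_cue():
            return self
        if scenario == "duplication":
            if self.kind == "lm_hd":
                return replace(self, duplication_active=True)
            # conjunctive cells pull their reference toward the now-bipolar
            # cue axis: modelled as a shift toward the arena center
            ref = tuple(
                np.asarray(arena.center)
                + (1.0 - self.duplication_weight) * (np.asarray(self.reference_point) - np.asarray(arena.center))
            )
            return replace(self, reference_point=ref)
        angle = self.cue_gain * SCENARIO_ANGLE[scenario]
        new = replace(self, preferred_direction=float(wrap_deg(self.preferred_direction + angle)))
        if self.kind == "cb_x_hd":
            ref = tuple(rotate_about(np.asarray(self.reference_point), arena.center, angle))
            new = replace(new, reference_point=ref)
        return new


# --------------------------------------------------------------- trajectory
def simulate_trajectory(
    arena: ArenaGeometry, config: SimulationConfig, seed: int | None = None
) -> TrackingData:
    """Goal-biased correlated random walk emulating place-navigation foraging.

    Heading persists with wrapped-Gaussian turning noise; with
    ``goal_bias > 0`` the walk steers toward the goal zone, and each
    rewarded entry (honoring the reward timeout) scatters 1-4 simulated
    pellets at uniform random locations which the walk then retrieves
    before returning to the goal. Head direction is the heading plus
    von Mises jitter. Boundaries reflect.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, dt = config.n_frames, config.dt
    side = arena.side_length

    x = np.empty(n)
    y = np.empty(n)
    heading = np.empty(n)

    pos = np.array([side / 2.0, 5.0])       # released at the middle of the south wall
    head = 90.0                             # facing north
    speed = config.mean_speed
    goal = np.asarray(arena.goal_zone_center)
    targets: list[np.ndarray] = [goal.copy()] if config.goal_bias > 0 else []
    last_reward = -np.inf
    seeking_goal = True
    wander_until = -np.inf          # undirected foraging window after pellet retrieval
    dwell_until = -np.inf           # post-reward pause inside the goal zone

    turn_noise = rng.normal(0.0, config.turn_sd, size=n)
    speed_noise = rng.normal(0.0, 1.0, size=n)
    hd_jitter = np.rad2deg(rng.vonmises(0.0, config.hd_jitter_kappa, size=n))

    a = dt / config.speed_tau
    for t in range(n):
        x[t], y[t] = pos
        heading[t] = head

        # reward / pellet bookkeeping
        if config.goal_bias > 0:
            in_goal = bool(
                zone_membership(pos[0], pos[1], arena.goal_zone_center, arena.goal_zone_side)
            )
            if seeking_goal and in_goal and (t * dt - last_reward) >= config.reward_timeout:
                last_reward = t * dt
                n_pellets = rng.integers(1, config.max_pellets + 1)
                targets = [rng.uniform(5.0, side - 5.0, size=2) for _ in range(n_pellets)]
                seeking_goal = False
                # brief pause at the dispenser trigger before chasing pellets
                dwell_until = t * dt + rng.exponential(2.0)
            elif not seeking_goal and targets and np.hypot(*(pos - targets[0])) < config.pellet_reach:
                targets.pop(0)
                if not targets:
                    targets = [goal.copy()]
                    seeking_goal = True
                    wander_until = t * dt + rng.exponential(config.forage_time)

        # steering (suspended while foraging undirected after pellet retrieval)
        turn = turn_noise[t]
        if config.goal_bias > 0 and targets and not (seeking_goal and t * dt < wander_until):
            desired = np.rad2deg(np.arctan2(*(targets[0] - pos)[::-1]))
            err = wrap_signed_deg(desired - head)
            turn += config.goal_bias * config.steer_gain * err
        head = float(wrap_deg(head + turn))

        # OU speed
        speed += (config.mean_speed - speed) * a + config.speed_sd * np.sqrt(2 * a) * speed_noise[t]
        speed = float(np.clip(speed, 0.0, 60.0))

        # rats decelerate when homing in on the remembered goal, which
        # biases occupancy (not just entries) toward the goal zone
        eff_speed = speed
        if config.goal_bias > 0:
            if t * dt < dwell_until:
                eff_speed = 0.0
            elif seeking_goal and t * dt >= wander_until and np.hypot(*(pos - goal)) < 20.0:
                eff_speed = speed * (1.0 - 0.6 * config.goal_bias)

        # step with reflecting boundaries
        step = eff_speed * dt
        nxt = pos + step * np.array([np.cos(np.deg2rad(head)), np.sin(np.deg2rad(head))])
        if nxt[0] < 0 or nxt[0] > side:
            head = float(wrap_deg(180.0 - head))
            nxt[0] = np.clip(nxt[0], 0.0, side)
        if nxt[1] < 0 or nxt[1] > side:
            head = float(wrap_deg(-head))
            nxt[1] = np.clip(nxt[1], 0.0, side)
        pos = nxt

    hd = wrap_deg(heading + hd_jitter)
    time = np.arange(n) * dt
    return TrackingData(time=time, x=x, y=y, hd=hd)


# ------------------------------------------------------------------- spikes
def generate_spikes(
    tracking: TrackingData,
    model: TuningModel,
    seed: int,
    arena: ArenaGeometry | None = None,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train from a tuning model along a trajectory.

    Per frame, a Poisson count with mean ``rate * dt`` is drawn and spike
    times are jittered uniformly within the frame. Bit-identical under a
    fixed seed.
    """
    if len(tracking) == 0:
        raise ValueError("tracking is empty")
    arena = arena or ArenaGeometry()
    rng = np.random.default_rng(seed)
    dt = tracking.dt
    lam = model.rate(tracking, arena)
    counts = rng.poisson(lam * dt)
    total = int(counts.sum())
    if total == 0:
        return SpikeTrain(np.empty(0))
    starts = np.repeat(tracking.time, counts)
    times = np.sort(starts + rng.uniform(0.0, dt, size=total))
    return SpikeTrain(times)


# -------------------------------------------------------------- cue triplet
@dataclass(frozen=True)
class CueTripletSession:
    """One session of a cue-manipulation day."""

    role: str                       # standard1 | manipulation | standard2
    cue_wall: str
    tracking: TrackingData
    spikes: dict[str, SpikeTrain]
    models: dict[str, TuningModel]  # models as expressed in this session


@dataclass(frozen=True)
class CueTriplet:
    scenario: str
    arena: ArenaGeometry
    sessions: tuple[CueTripletSession, CueTripletSession, CueTripletSession]


def simulate_cue_triplet(
    arena: ArenaGeometry,
    config: SimulationConfig,
    models: dict[str, TuningModel],
    scenario: str,
    seed: int = 0,
) -> CueTriplet:
    """Standard -> manipulated -> standard session triplet.

    Sessions 1 and 3 use the standard south cue; session 2 moves the cue
    (ccw -> east wall, cw -> west wall) or duplicates it on the north wall.
    POR-like LM-HD models rotate their preferred direction by
    ``cue_gain * (+-90 deg)`` (rotations) or become two-lobed mixtures
    (duplication); cue-following conjunctive CB x HD references rotate
    about the arena center by the same gained angle. MEC/PaS-like models
    are identical across the three sessions.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    ss = np.random.SeedSequence(seed)
    traj_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    spike_ss = ss.spawn(1)[0].spawn(3 * len(models))

    roles = ("standard1", "manipulation", "standard2")
    walls = ("south", SCENARIO_CUE_WALL[scenario], "south")
    sessions = []
    k = 0
    for i, (role, wall) in enumerate(zip(roles, walls)):
        session_models = {
            cid: (m.under_cue_scenario(scenario, arena) if role == "manipulation" else m)
            for cid, m in models.items()
        }
        tracking = simulate_trajectory(arena, config, seed=traj_seeds[i])
        spikes = {}
        for cid in models:
            sd = int(spike_ss[k].generate_state(1)[0] % (2**31))
            k += 1
            spikes[cid] = generate_spikes(tracking, session_models[cid], seed=sd, arena=arena)
        sessions.append(
            CueTripletSession(role=role, cue_wall=wall, tracking=tracking, spikes=spikes, models=session_models)
        )
    return CueTriplet(scenario=scenario, arena=arena, sessions=tuple(sessions))


# -------------------------------------------------------------- cell presets
def default_model(kind: str, rng: np.random.Generator | None = None, **overrides) -> TuningModel:
    """A realistic randomized model of the given kind (for population sims)."""
    rng = rng or np.random.default_rng(0)
    base: dict = {"kind": kind}
    if kind == "grid":
        base.update(
            region="MEC_PaS",
            spacing=40.0,
            orientation=float(rng.uniform(0, 60)),
            phase=tuple(rng.uniform(0, 40, 2)),
            peak_rate=15.0,
            baseline_rate=0.2,
        )
    elif kind == "border":
        base.update(
            region="MEC_PaS",
            wall=str(rng.choice(["south", "north", "east", "west"])),
            distance_decay=8.0,
            peak_rate=12.0,
            baseline_rate=0.2,
        )
    elif kind == "nongrid":
        n_fields = int(rng.integers(2, 4))
        centers = rng.uniform(15, 105, size=(n_fields, 2))
        base.update(
            region="MEC_PaS",
            fields=[(tuple(c), float(rng.uniform(8, 14)), 1.0) for c in centers],
            peak_rate=12.0,
            baseline_rate=0.2,
        )
    elif kind in ("hd", "lm_hd"):
        base.update(
            region="MEC_PaS" if kind == "hd" else "POR",
            preferred_direction=float(rng.uniform(0, 360)),
            kappa=4.0,
            peak_rate=10.0,
            baseline_rate=0.2,
        )
    elif kind == "cb":
        base.update(
            region="POR",
            preferred_bearing=float(rng.uniform(-180, 180)),
            bearing_kappa=4.0,
            reference_point=(60.0, 60.0),
            peak_rate=10.0,
            baseline_rate=0.5,
        )
    elif kind == "cb_x_hd":
        base.update(
            region="POR",
            preferred_bearing=float(rng.uniform(-180, 180)),
            bearing_kappa=4.0,
            reference_point=tuple(rng.uniform(25, 95, 2)),
            preferred_direction=float(rng.uniform(0, 360)),
            kappa=1.0,
            peak_rate=15.0,
            baseline_rate=0.5,
        )
    elif kind == "cd":
        base.update(
            region="POR",
            cd_profile=str(rng.choice(["linear", "gaussian"])),
            cd_sign=int(rng.choice([-1, 1])),
            cd_mean=float(rng.uniform(20, 50)),
            peak_rate=10.0,
            baseline_rate=0.5,
        )
    else:
        raise ValueError(f"unknown kind {kind!r}")
    base.update(overrides)
    return TuningModel(**base)
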