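"""Ground-truth recovery benchmarks on synthetic sessions.

Each routine generates sessions from the synthetic module, runs the
corresponding analysis exactly as the pipeline would, and reports recovery
statistics against the known generative parameters. They power both the
acceptance test-suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import cue as cue_mod
from .circstats import v_test
from .egocentric import mvl_map, precompute_bearing_bins
from .geometry import ArenaGeometry
from .pipeline import AnalysisConfig, analyze_cell, run_cue_analysis, session_views_from_triplet
from .spatial import border_score, spatial_information
from .synthetic import SimulationConfig, TuningModel, default_model, generate_spikes, simulate_cue_triplet, simulate_trajectory
from .tuning import RateMap2D, hd_tuning_curve, shuffle_threshold

RECOVERY_TYPES = ("hd", "cb", "cd", "grid", "border", "nongrid")
_FLAG_OF = {
    "hd": "hd", "cb": "cb", "cd": "cd",
    "grid": "grid", "border": "border", "nongrid": "nongrid_spatial",
}


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def _recovery_model(kind: str, rng: np.random.Generator) -> TuningModel:
    """Benchmark cell models: population defaults with the canonical
    head-direction parameterization (kappa 4, 10 Hz peak)."""
    if kind == "hd":
        return default_model("hd", rng, kappa=4.0, peak_rate=10.0)
    return default_model(kind, rng)


def classifier_recovery(
    n_per_type: int = 20,
    n_null: int = 20,
    seed: int = 0,
    config: AnalysisConfig | None = None,
    cells_per_session: int = 14,
) -> dict:
    """Classify synthetic cells of each type plus homogeneous-Poisson nulls.

    Cells are grouped onto shared 20-minute trajectories (as recorded
    populations are). Returns per-type recovery fractions and the fraction
    of null cells classified as anything.
    """
    config = config or AnalysisConfig(compute_mvl_maps=False)
    arena = ArenaGeometry()
    sim = SimulationConfig()
    rng = np.random.default_rng(seed)

    cells: list[tuple[str, TuningModel]] = []
    for kind in RECOVERY_TYPES:
        for _ in range(n_per_type):
            cells.append((kind, _recovery_model(kind, rng)))
    for _ in range(n_null):
        cells.append(("null", TuningModel(kind="hd", baseline_rate=2.0, peak_rate=2.0)))

    n_sessions = int(np.ceil(len(cells) / cells_per_session))
    traj_seeds = _seeds(seed + 1, n_sessions)
    spike_seeds = _seeds(seed + 2, len(cells))
    cell_seeds = _seeds(seed + 3, len(cells))

    hits = {k: 0 for k in RECOVERY_TYPES}
    null_fp = 0
    per_cell = []
    for s_idx in range(n_sessions):
        tracking = simulate_trajectory(arena, sim, seed=traj_seeds[s_idx])
        chunk = cells[s_idx * cells_per_session: (s_idx + 1) * cells_per_session]
        for j, (kind, model) in enumerate(chunk):
            i = s_idx * cells_per_session + j
            spikes = generate_spikes(tracking, model, seed=spike_seeds[i], arena=arena)
            report = analyze_cell(tracking, spikes, arena, model.region, config, seed=cell_seeds[i])
            cls = report["classification"]
            if kind == "null":
                null_fp += int(not cls.unclassified)
                recovered = None
            else:
                recovered = bool(getattr(cls, _FLAG_OF[kind]))
                hits[kind] += int(recovered)
            per_cell.append({"kind": kind, "labels": cls.labels, "recovered": recovered})

    return {
        "recovery": {k: hits[k] / n_per_type for k in RECOVERY_TYPES},
        "null_false_positive_rate": null_fp / n_null if n_null else float("nan"),
        "n_per_type": n_per_type,
        "n_null": n_null,
        "per_cell": per_cell,
    }


def closed_form_scores() -> dict:
    """The desk-scale closed-form checks: spatial information of the 4-bin
    worked example, the full-wall border strip, and the bidirectionality of
    symmetric-bimodal / unimodal von Mises curves."""
    si = spatial_information(np.array([8.0, 0.0, 0.0, 0.0]), np.ones(4))

    n = 48
    rate = np.zeros((n, n))
    rate[0, :] = 5.0
    strip_map = RateMap2D(2.5, np.ones((n, n)), rate.copy(), rate.copy(), rate.copy())
    bs = border_score(strip_map, ArenaGeometry())

    angles = np.arange(0.0, 360.0, 0.5)
    bimodal = np.exp(3.0 * (np.cos(np.deg2rad(angles - 45.0)) - 1.0)) + np.exp(
        3.0 * (np.cos(np.deg2rad(angles - 225.0)) - 1.0)
    )
    bi_bimodal = cue_mod.bidirectionality_from_angles(angles, bimodal, dt=1.0)["bi"]
    unimodal = np.exp(2.0 * (np.cos(np.deg2rad(angles - 77.0)) - 1.0))
    bi_unimodal = cue_mod.bidirectionality_from_angles(angles, unimodal, dt=1.0)["bi"]
    return {
        "spatial_information_4bin": si,
        "border_score_wall_strip": bs.score,
        "bi_symmetric_bimodal": bi_bimodal,
        "bi_unimodal_kappa2": bi_unimodal,
    }


def shuffle_calibration(
    n_cells: int = 100,
    seed: int = 0,
    n_shuffles: int = 400,
    percentile: float = 99.0,
    rate_hz: float = 2.0,
) -> dict:
    """False-positive rate of the MVL shuffle criterion on null cells.

    Homogeneous-Poisson cells have no HD tuning; with a 99th-percentile
    within-cell threshold the fraction whose true MVL exceeds their own
    threshold should be ~1%.
    """
    arena = ArenaGeometry()
    sim = SimulationConfig()
    traj_seeds = _seeds(seed + 10, max(1, n_cells // 10))
    spike_seeds = _seeds(seed + 11, n_cells)
    thr_seeds = _seeds(seed + 12, n_cells)

    trackings = [simulate_trajectory(arena, sim, seed=s) for s in traj_seeds]
    null = TuningModel(kind="hd", baseline_rate=rate_hz, peak_rate=rate_hz)
    fp = 0
    for i in range(n_cells):
        tracking = trackings[i % len(trackings)]
        spikes = generate_spikes(tracking, null, seed=spike_seeds[i], arena=arena)
        curve_mvl = hd_tuning_curve(tracking, spikes).mvl
        thr = shuffle_threshold(
            lambda s, tr=tracking: hd_tuning_curve(tr, s).mvl,
            spikes, tracking.duration,
            n_shuffles=n_shuffles, percentile=percentile, seed=thr_seeds[i],
        )
        fp += int(curve_mvl > thr)
    return {"false_positive_rate": fp / n_cells, "n_cells": n_cells, "expected": 1.0 - percentile / 100.0}


def cue_rotation_recovery(
    n_lmhd: int = 30,
    n_grid: int = 20,
    n_hd: int = 10,
    scenario: str = "ccw_rotation",
    cue_gain: float = 1.0,
    seed: int = 0,
) -> dict:
    """Rotation triplet: cue-following LM-HD cells should shift their
    preferred direction by the gained cue rotation. MEC-like controls
    should be unaffected: HD cells keep their preferred direction and grid
    cells' rate maps correlate best at 0 degrees."""
    arena = ArenaGeometry()
    sim = SimulationConfig()
    rng = np.random.default_rng(seed)
    models = {
        **{f"lmhd_{i}": default_model("lm_hd", rng, cue_gain=cue_gain) for i in range(n_lmhd)},
        **{f"grid_{i}": default_model("grid", rng) for i in range(n_grid)},
        **{f"hd_{i}": default_model("hd", rng, kappa=4.0) for i in range(n_hd)},
    }
    triplet = simulate_cue_triplet(arena, sim, models, scenario, seed=seed + 20)
    res = run_cue_analysis(session_views_from_triplet(triplet), scenario=scenario)
    table = res["table"]

    lm = table[table.cell.str.startswith("lmhd")]
    gr = table[table.cell.str.startswith("grid")]
    hd = table[table.cell.str.startswith("hd")]
    expected = cue_gain * (90.0 if scenario == "ccw_rotation" else -90.0)
    shifts = lm["shift_deg"].to_numpy()
    mean_shift = float(np.rad2deg(np.angle(np.mean(np.exp(1j * np.deg2rad(shifts))))))
    _, v_p = v_test(shifts, expected)

    corr_cols = [f"map_corr_{a}" for a in (0, 90, 180, 270)]
    best_at_zero = (gr[corr_cols].to_numpy().argmax(axis=1) == 0)
    return {
        "lmhd_mean_shift_deg": mean_shift,
        "lmhd_vtest_p": float(v_p),
        "expected_shift_deg": expected,
        "mec_hd_mean_abs_shift_deg": float(np.abs(hd["shift_deg"].to_numpy()).mean()) if len(hd) else float("nan"),
        "grid_frac_corr_max_at_0": float(best_at_zero.mean()) if len(gr) else float("nan"),
        "n_lmhd": n_lmhd,
        "n_grid": n_grid,
        "n_hd": n_hd,
    }


def duplication_recovery(
    n_por: int = 15, n_mec: int = 15, duplication_weight: float = 0.5, seed: int = 0
) -> dict:
    """Duplication triplet: POR LM-HD cells become bidirectional (large
    positive change in BI); MEC-like HD cells stay unidirectional."""
    arena = ArenaGeometry()
    sim = SimulationConfig()
    rng = np.random.default_rng(seed)
    models = {
        **{
            f"por_{i}": default_model("lm_hd", rng, duplication_weight=duplication_weight)
            for i in range(n_por)
        },
        **{f"mec_{i}": default_model("hd", rng) for i in range(n_mec)},
    }
    triplet = simulate_cue_triplet(arena, sim, models, "duplication", seed=seed + 30)
    res = run_cue_analysis(session_views_from_triplet(triplet), scenario="duplication")
    table = res["table"]
    por = table[table.cell.str.startswith("por")]
    mec = table[table.cell.str.startswith("mec")]
    return {
        "por_mean_delta_bi": float(por["delta_bi"].mean()),
        "mec_mean_delta_bi": float(mec["delta_bi"].mean()),
        "por_mean_mi_s": float(por["mi_s"].mean()),
        "por_mean_mi_n": float(por["mi_n"].mean()),
        "n_por": n_por,
        "n_mec": n_mec,
    }


def egocentric_recovery(n_cbxhd: int = 20, n_cb: int = 10, seed: int = 0) -> dict:
    """MVL_max recovery: conjunctive CB x HD cells with known reference
    points, and pure center-bearing cells whose reference is the arena
    center (recovered within one 6 cm grid step)."""
    arena = ArenaGeometry()
    sim = SimulationConfig()
    rng = np.random.default_rng(seed)
    tracking = simulate_trajectory(arena, sim, seed=seed + 40)
    cache = precompute_bearing_bins(tracking, arena)
    spike_seeds = _seeds(seed + 41, n_cbxhd + n_cb)

    errors = []
    for i in range(n_cbxhd):
        model = default_model("cb_x_hd", rng)
        spikes = generate_spikes(tracking, model, seed=spike_seeds[i], arena=arena)
        loc = mvl_map(tracking, spikes, arena, cache=cache).mvlmax_location
        errors.append(float(np.hypot(loc[0] - model.reference_point[0], loc[1] - model.reference_point[1])))

    grid_step = arena.side_length / 20.0
    center_errors = []
    for i in range(n_cb):
        model = default_model("cb", rng)
        spikes = generate_spikes(tracking, model, seed=spike_seeds[n_cbxhd + i], arena=arena)
        loc = mvl_map(tracking, spikes, arena, cache=cache).mvlmax_location
        center_errors.append(float(np.hypot(loc[0] - arena.center[0], loc[1] - arena.center[1])))

    return {
        "cbxhd_frac_within_10cm": float(np.mean(np.asarray(errors) <= 10.0)),
        "cbxhd_errors_cm": errors,
        "cb_frac_within_one_step": float(np.mean(np.asarray(center_errors) <= grid_step * np.sqrt(2) + 1e-9)),
        "cb_errors_cm": center_errors,
        "grid_step_cm": grid_step,
        "n_cbxhd": n_cbxhd,
        "n_cb": n_cb,
    }
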