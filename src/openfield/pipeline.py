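"""Orchestration: per-cell standard-session analysis and cue-triplet
analysis, with every numeric default exposed through one config object."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cue as cue_mod
from . import egocentric as ego
from .behavior import behavior_table
from .circstats import rayleigh_test, v_test
from .geometry import ArenaGeometry
from .glm import forward_select, build_design
from .io import SessionRecord
from .session import SpikeTrain, TrackingData
from .spatial import (
    CellClassification,
    border_score,
    classify_cell,
    detect_fields,
    grid_score,
    population_normalized_map,
    spatial_information_map,
)
from .tuning import (
    center_bearing_curve,
    compute_rate_map,
    distance_tuning_curve,
    hd_tuning_curve,
    resample_equal_occupancy,
    shuffle_spike_train,
    shuffle_threshold,
)

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Every numeric default of the pipeline in one place."""

    map_bin_size: float = 2.5
    map_smooth_sigma: float = 3.75
    circular_bin_width: float = 12.0
    distance_bin_width: float = 4.0
    grid_threshold: float = 0.4
    border_threshold: float = 0.5
    mvl_floor: float = 0.2
    peak_rate_floor: float = 1.0
    n_shuffles: int = 400
    shuffle_percentile: float = 99.0
    min_shift_s: float = 30.0
    glm_folds: int = 10
    glm_alpha: float = 0.05
    glm_smoothing_location: float = 2.0
    glm_smoothing_other: float = 20.0
    min_spikes: int = 100
    resample_bin_size: float = 15.0
    reward_timeout_s: float = 10.0
    approach_window_s: float = 1.0
    compute_mvl_maps: bool = True

    @property
    def glm_smoothing(self) -> dict[str, float]:
        s = {v: self.glm_smoothing_other for v in ("hd", "center_bearing", "center_distance", "speed")}
        s["location"] = self.glm_smoothing_location
        return s

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _derived_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2**31))


def compute_shuffle_thresholds(
    tracking: TrackingData,
    spikes: SpikeTrain,
    arena: ArenaGeometry,
    needed: set[str],
    config: AnalysisConfig,
    seed: int,
) -> dict[str, float]:
    """Within-cell shuffle thresholds, computed only for the statistics in
    ``needed`` (subset of {spatial_information, hd_mvl, cb_mvl, cd_r2}).

    The center-distance entry yields two thresholds (``cd_linear_r2`` and
    ``cd_gaussian_r2``) from the same shuffles: each fit type is compared
    against the shuffle distribution of the same fit type.
    """
    duration = tracking.duration
    out: dict[str, float] = {}
    ss = np.random.SeedSequence(seed)
    seeds = {name: _derived_seed(child) for name, child in zip(
        ("spatial_information", "hd_mvl", "cb_mvl", "cd_r2"), ss.spawn(4))}

    def run(name, stat):
        out[name] = shuffle_threshold(
            stat, spikes, duration,
            n_shuffles=config.n_shuffles, percentile=config.shuffle_percentile,
            min_shift=config.min_shift_s, seed=seeds[name],
        )

    if "spatial_information" in needed:
        run("spatial_information", lambda s: spatial_information_map(
            compute_rate_map(tracking, s, arena, config.map_bin_size, config.map_smooth_sigma),
            config.map_smooth_sigma))
    if "hd_mvl" in needed:
        run("hd_mvl", lambda s: hd_tuning_curve(tracking, s, config.circular_bin_width).mvl)
    if "cb_mvl" in needed:
        run("cb_mvl", lambda s: center_bearing_curve(tracking, s, arena, config.circular_bin_width).mvl)
    if "cd_r2" in needed:
        rng = np.random.default_rng(seeds["cd_r2"])
        lin = np.empty(config.n_shuffles)
        gau = np.empty(config.n_shuffles)
        for i in range(config.n_shuffles):
            shift = float(rng.uniform(config.min_shift_s, duration - config.min_shift_s))
            sh = shuffle_spike_train(spikes, duration, config.min_shift_s, shift=shift)
            curve = distance_tuning_curve(tracking, sh, arena, config.distance_bin_width)
            lin[i] = curve.linear_r2
            gau[i] = curve.gaussian_r2
        out["cd_linear_r2"] = float(np.nanpercentile(lin, config.shuffle_percentile))
        out["cd_gaussian_r2"] = float(np.nanpercentile(gau, config.shuffle_percentile))
    return out


def analyze_cell(
    tracking: TrackingData,
    spikes: SpikeTrain,
    arena: ArenaGeometry,
    region: str,
    config: AnalysisConfig | None = None,
    seed: int = 0,
    mvl_cache: ego.BearingBinCache | None = None,
) -> dict:
    """Full standard-session analysis of one cell.

    Returns a report dict: GLM selection, tuning curves and scores, shuffle
    thresholds (computed only where the classification rules consult them),
    the combined classification, firing fields, the egocentric MVL map and
    the bidirectionality index.
    """
    config = config or AnalysisConfig()
    sel = forward_select(
        build_design(tracking, spikes, arena),
        k=config.glm_folds, alpha=config.glm_alpha,
        smoothing=config.glm_smoothing, min_spikes=config.min_spikes,
    )
    selected = sel.selected_set

    ratemap = compute_rate_map(tracking, spikes, arena, config.map_bin_size, config.map_smooth_sigma)
    hd_curve = hd_tuning_curve(tracking, spikes, config.circular_bin_width)
    cb_curve = center_bearing_curve(tracking, spikes, arena, config.circular_bin_width)
    cd_curve = distance_tuning_curve(tracking, spikes, arena, config.distance_bin_width)

    gs = grid_score(ratemap) if "location" in selected else float("nan")
    bs = border_score(ratemap, arena) if "location" in selected else None
    scores = {
        "grid_score": gs,
        "border_score": bs.score if bs is not None else float("nan"),
        "spatial_information": spatial_information_map(ratemap, config.map_smooth_sigma),
        "hd_mvl": hd_curve.mvl,
        "hd_peak_rate": hd_curve.peak_rate,
        "cb_mvl": cb_curve.mvl,
        "cb_peak_rate": cb_curve.peak_rate,
        "cd_linear_r2": cd_curve.linear_r2,
        "cd_gaussian_r2": cd_curve.gaussian_r2,
        "cd_peak_rate": cd_curve.peak_rate,
    }

    needed = set()
    if "location" in selected and not (np.isfinite(gs) and gs > config.grid_threshold) and not (
        bs is not None and bs.score > config.border_threshold
    ):
        needed.add("spatial_information")
    if "hd" in selected:
        needed.add("hd_mvl")
    if "center_bearing" in selected:
        needed.add("cb_mvl")
    if "center_distance" in selected:
        needed.add("cd_r2")
    thresholds = compute_shuffle_thresholds(tracking, spikes, arena, needed, config, seed)

    classification = classify_cell(
        selected, scores, thresholds, region=region,
        grid_threshold=config.grid_threshold, border_threshold=config.border_threshold,
        mvl_floor=config.mvl_floor, peak_rate_floor=config.peak_rate_floor,
    )
    fields = detect_fields(ratemap)
    report = {
        "selection": sel,
        "selected_variables": sorted(selected),
        "ratemap": ratemap,
        "hd_curve": hd_curve,
        "cb_curve": cb_curve,
        "cd_curve": cd_curve,
        "scores": scores,
        "thresholds": thresholds,
        "classification": classification,
        "labels": classification.labels,
        "fields": fields,
        "bidirectionality": cue_mod.bidirectionality_index(tracking, spikes, config.circular_bin_width),
    }
    if config.compute_mvl_maps:
        report["mvl_map"] = ego.mvl_map(tracking, spikes, arena, cache=mvl_cache)
    return report


def run_standard_analysis(
    session: SessionRecord, config: AnalysisConfig | None = None, seed: int = 0
) -> dict:
    """Analyze every cell of one standard session; per-cell failures are
    isolated and logged rather than aborting the session."""
    config = config or AnalysisConfig()
    ss = np.random.SeedSequence(seed)
    cell_seeds = {cid: _derived_seed(child) for cid, child in zip(session.spikes, ss.spawn(len(session.spikes)))}
    resample_seed = _derived_seed(ss.spawn(1)[0])

    mvl_cache = (
        ego.precompute_bearing_bins(session.tracking, session.arena)
        if config.compute_mvl_maps and session.spikes
        else None
    )
    cells, failures = {}, {}
    for cid, spikes in session.spikes.items():
        try:
            cells[cid] = analyze_cell(
                session.tracking, spikes, session.arena, session.regions.get(cid, "MEC_PaS"),
                config, seed=cell_seeds[cid], mvl_cache=mvl_cache,
            )
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            log.exception("cell %s failed", cid)
            failures[cid] = str(exc)

    behavior = behavior_table(session.tracking, session.arena, config.reward_timeout_s, config.approach_window_s)

    summaries: dict = {"resampled": {}}
    maps = [r["ratemap"] for r in cells.values()]
    if maps:
        summaries["population_map"] = population_normalized_map(maps, session.arena)
    if config.compute_mvl_maps and cells:
        summaries["mvl_summary"] = ego.population_mvl_summary(
            [r["mvl_map"] for r in cells.values()], session.arena
        )
        resampled_maps = []
        for cid, spikes in session.spikes.items():
            if cid not in cells:
                continue
            rt, rs = resample_equal_occupancy(
                session.tracking, spikes, session.arena, config.resample_bin_size, seed=resample_seed
            )
            resampled_maps.append(ego.mvl_map(rt, rs, session.arena))
        summaries["resampled"] = {
            "metadata": {"occupancy_equalized": True, "bin_size_cm": config.resample_bin_size},
            "mvl_summary": ego.population_mvl_summary(resampled_maps, session.arena),
        }

    table = pd.DataFrame(
        [
            {
                "cell": cid,
                "region": session.regions.get(cid, "MEC_PaS"),
                "labels": "+".join(r["labels"]) or "unclassified",
                "selected": "+".join(r["selected_variables"]),
                **{k: r["scores"][k] for k in r["scores"]},
            }
            for cid, r in cells.items()
        ]
    )
    return {
        "cells": cells,
        "failures": failures,
        "behavior": behavior,
        "summaries": summaries,
        "table": table,
        "seed": seed,
    }


@dataclass
class SessionView:
    """Minimal per-session view used by the cue-triplet analysis."""

    role: str
    tracking: TrackingData
    spikes: dict[str, SpikeTrain]
    regions: dict[str, str]
    arena: ArenaGeometry


def session_views_from_triplet(triplet) -> list[SessionView]:
    """Adapt a synthetic :class:`~openfield.synthetic.CueTriplet`."""
    return [
        SessionView(
            role=s.role,
            tracking=s.tracking,
            spikes=s.spikes,
            regions={cid: m.region for cid, m in s.models.items()},
            arena=triplet.arena,
        )
        for s in triplet.sessions
    ]


def session_views_from_records(records: list[SessionRecord]) -> list[SessionView]:
    return [
        SessionView(role=r.role, tracking=r.tracking, spikes=r.spikes, regions=r.regions, arena=r.arena)
        for r in records
    ]


def run_cue_analysis(
    sessions: list[SessionView],
    config: AnalysisConfig | None = None,
    scenario: str | None = None,
    cell_types: dict[str, str] | None = None,
) -> dict:
    """Per-cell cue-manipulation statistics across a session triplet.

    For every cell present in all three sessions: preferred-direction shift
    (standard1 -> manipulation), bidirectionality per session and its change,
    south/north modulation indices (duplication scenario), rotated-map
    correlations, and — for center-bearing-type cells per ``cell_types`` —
    the MVL_max rotation about the arena center. Population Rayleigh and
    V tests are run on the shift distributions per region.
    """
    config = config or AnalysisConfig()
    if len(sessions) != 3:
        raise ValueError("cue analysis requires exactly three sessions")
    s1, s2, s3 = sessions
    arena = s1.arena
    roster = [cid for cid in s1.spikes if cid in s2.spikes and cid in s3.spikes]
    skipped = sorted((set(s1.spikes) | set(s2.spikes) | set(s3.spikes)) - set(roster))
    for cid in skipped:
        log.warning("cell %s missing from one session; excluded", cid)

    bearing_types = {"cb", "cb_x_hd"}
    caches = None
    if cell_types and any(cell_types.get(c) in bearing_types for c in roster):
        caches = [ego.precompute_bearing_bins(s.tracking, arena) for s in sessions]

    rows = []
    for cid in roster:
        curves = [hd_tuning_curve(s.tracking, s.spikes[cid], config.circular_bin_width) for s in sessions]
        bis = [
            cue_mod.bidirectionality_index(s.tracking, s.spikes[cid], config.circular_bin_width)["bi"]
            for s in sessions
        ]
        maps = [
            compute_rate_map(s.tracking, s.spikes[cid], arena, config.map_bin_size, config.map_smooth_sigma)
            for s in sessions
        ]
        corr12 = cue_mod.rotated_map_correlations(maps[0], maps[1])
        row = {
            "cell": cid,
            "region": s1.regions.get(cid, "MEC_PaS"),
            "shift_deg": cue_mod.preferred_direction_shift(curves[0], curves[1]),
            "shift_recovery_deg": cue_mod.preferred_direction_shift(curves[0], curves[2]),
            "bi_standard1": bis[0],
            "bi_manipulation": bis[1],
            "bi_standard2": bis[2],
            "delta_bi": bis[1] - bis[0],
            **{f"map_corr_{a}": corr12[a] for a in (0, 90, 180, 270)},
            "mi_s": float("nan"),
            "mi_n": float("nan"),
            "mvlmax_rotation_deg": float("nan"),
        }
        if scenario == "duplication" and np.isfinite(curves[1].preferred_direction):
            fit = cue_mod.fit_bidirectional_von_mises(curves[1], mode="peak")
            row["mi_s"], row["mi_n"] = cue_mod.cue_modulation_indices(fit, curves[0].preferred_direction)
        if caches is not None and cell_types and cell_types.get(cid) in bearing_types:
            m1 = ego.mvl_map(s1.tracking, s1.spikes[cid], arena, cache=caches[0])
            m2 = ego.mvl_map(s2.tracking, s2.spikes[cid], arena, cache=caches[1])
            row["mvlmax_rotation_deg"] = ego.mvlmax_rotation_about_center(
                m1.mvlmax_location, m2.mvlmax_location, arena.center
            )
        rows.append(row)

    table = pd.DataFrame(rows)
    population: dict[str, dict] = {}
    if len(table):
        for region, grp in table.groupby("region"):
            shifts = grp["shift_deg"].dropna().to_numpy()
            stats: dict[str, float] = {"n": int(shifts.size)}
            if shifts.size >= 2:
                stats["rayleigh_r"], stats["rayleigh_p"] = rayleigh_test(shifts)
                if scenario in ("ccw_rotation", "cw_rotation"):
                    expected = 90.0 if scenario == "ccw_rotation" else -90.0
                    stats["v_u"], stats["v_p"] = v_test(shifts, expected)
            population[region] = stats
    return {"table": table, "population": population, "scenario": scenario, "skipped": skipped}
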