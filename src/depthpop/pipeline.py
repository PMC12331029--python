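"""End-to-end orchestration of the three analyses and reporting.

Every run is driven by an :class:`AnalysisConfig` (loadable from YAML) and
is fully deterministic given its seed: rerunning a config writes
byte-identical report JSON and CSV tables.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import decoding, depth_tuning, information, preprocess, simulate
from .core import Recording, SimConfig, scores_to_frame

__all__ = ["AnalysisConfig", "run_cliff", "run_vslm",
           "run_overlap_and_track", "run_all"]


@dataclass
class AnalysisConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    out_dir: Optional[str] = None

    # depth tuning
    map_bin_cm: float = 2.5
    min_occupancy_s: float = 0.2
    xbin_cm: float = 5.0

    # information
    n_shuffles: int = 1000
    min_shift_s: float = 1.0
    null_mode: str = "pooled"
    mi_neighbors: int = 3
    ridge_threshold: float = 0.75

    # decoding
    pos_bin_cm: float = 2.0
    n_iter: int = 10
    knn_k: int = 5
    roster: bool = False

    # trial alignment
    rel_window_s: tuple[float, float] = (-3.0, 3.0)
    rate_bin_s: float = 1.0
    rate_step_s: float = 0.2

    # multi-session stability
    n_vslm_sessions: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("arm_lengths_cm", "avoid_bias", "dwell_s"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        for key in ("rel_window_s",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=SimConfig(**sim_raw), **raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # where results land is not provenance
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# small helpers
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_report(report: dict, out_dir: Optional[str], name: str) -> dict:
    if out_dir is not None:
        path = Path(out_dir)
        path.mkdir(parents=True, exist_ok=True)
        (path / name).write_text(
            json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
    return report


def _write_csv(df: pd.DataFrame, out_dir: Optional[str], name: str) -> None:
    if out_dir is not None:
        path = Path(out_dir)
        path.mkdir(parents=True, exist_ok=True)
        df.to_csv(path / name, index=False, float_format="%.10g")


def _rate_windows(rec: Recording, cfg: AnalysisConfig):
    """Event-rate feature windows and the 1-D X position at window centers."""
    n = rec.neural
    rs = preprocess.event_rate(n.events, n.timestamps[0], n.timestamps[-1],
                               bin_s=cfg.rate_bin_s, step_s=cfg.rate_step_s)
    x = np.interp(rs.t, rec.behavior.timestamps, rec.behavior.position[:, 0])
    return rs, x


def _group_indices(scores, truth=None):
    sel = np.array([s.selected for s in scores])
    return {"selected": np.flatnonzero(sel),
            "rejected": np.flatnonzero(~sel)}


def _recovery(scores, truth, planted_class: str) -> dict:
    planted = truth.cells_of(planted_class)
    others = np.setdiff1d(truth.cells_of("noise"),
                          np.array([], dtype=int))
    sel = np.array([s.selected for s in scores])
    sens = float(sel[planted].mean()) if planted.size else np.nan
    fpr = float(sel[others].mean()) if others.size else np.nan
    return {"sensitivity": sens, "noise_false_positive_rate": fpr,
            "n_planted": int(planted.size), "n_selected": int(sel.sum())}


# ---------------------------------------------------------------------------
# cliff pipeline
# ---------------------------------------------------------------------------

def run_cliff(cfg: AnalysisConfig,
              sessions: Optional[tuple[Recording, Recording]] = None,
              truth=None) -> dict:
    """Cliff-pair analysis: behavior metrics, rate maps, area scores,
    depth-sensitive cell selection, cross-session R^2, per-X-bin depth
    decoding, and (optionally) the classifier-roster calibration."""
    sim = cfg.sim
    if sessions is None:
        rec30, rec90, truth = simulate.make_cliff_pair(sim, cfg.seed)
    else:
        rec30, rec90 = sessions

    report: dict = {"stage": "cliff", "seed": cfg.seed,
                    "config_hash": cfg.config_hash()}

    # --- behavior metrics at each minute
    checkpoints = np.arange(60.0, sim.duration_s + 1e-9, 60.0)
    behav = {}
    for name, rec in (("cliff30", rec30), ("cliff90", rec90)):
        m = preprocess.cliff_metrics(rec.behavior, checkpoints,
                                     arena_cm=sim.arena_cm,
                                     center_cm=sim.center_cm)
        behav[name] = {k: v.tolist() for k, v in m.items()}
    report["behavior"] = behav
    report["checkpoints_s"] = checkpoints.tolist()

    # --- cross-registration
    pairs, _, _ = preprocess.cross_register(rec30.neural.centroids,
                                            rec90.neural.centroids)
    report["n_matched_cells"] = int(pairs.shape[0])
    idx30, idx90 = pairs[:, 0], pairs[:, 1]

    # --- rate maps along X and area scores
    edges = np.arange(0.0, sim.arena_cm + cfg.map_bin_cm / 2, cfg.map_bin_cm)
    scores_raw = np.empty(pairs.shape[0])
    for row, (c30, c90) in enumerate(pairs):
        maps = []
        for rec, c in ((rec30, c30), (rec90, c90)):
            t_img = rec.neural.timestamps
            x_img = np.interp(t_img, rec.behavior.timestamps,
                              rec.behavior.position[:, 0])
            dt = float(np.median(np.diff(t_img)))
            maps.append(depth_tuning.ratemap(
                rec.neural.traces[c], x_img, edges, dt,
                min_occupancy=cfg.min_occupancy_s))
        scores_raw[row] = depth_tuning.area_score(maps[0], maps[1])
    cell_scores = depth_tuning.classify_dsvc(scores_raw)
    _write_csv(scores_to_frame(cell_scores), cfg.out_dir, "cliff_area_scores.csv")
    groups = _group_indices(cell_scores)
    n_sel = int(len(groups["selected"]))
    report["dsvc"] = {
        "n_cells": int(pairs.shape[0]),
        "n_selected": n_sel,
        "selected_fraction": n_sel / pairs.shape[0],
    }
    if truth is not None:
        matched_truth_class = truth.cell_class[idx30]
        sel = np.array([s.selected for s in cell_scores])
        planted = matched_truth_class == "depth_tuned"
        untuned = matched_truth_class == "noise"
        report["dsvc"]["sensitivity"] = (
            float(sel[planted].mean()) if planted.any() else None)
        report["dsvc"]["noise_false_positive_rate"] = (
            float(sel[untuned].mean()) if untuned.any() else None)

    # --- cross-session mean-rate R^2 per group
    dur30 = rec30.neural.timestamps[-1] - rec30.neural.timestamps[0]
    dur90 = rec90.neural.timestamps[-1] - rec90.neural.timestamps[0]
    mean30 = np.array([rec30.neural.events[c].size / dur30 for c in idx30])
    mean90 = np.array([rec90.neural.events[c].size / dur90 for c in idx90])
    labels = np.where([s.selected for s in cell_scores], "dsvc", "rejected")
    report["r2"] = depth_tuning.session_rate_r2(mean30, mean90, labels)

    # --- per-X-bin depth decoding for each group
    rs30, x30 = _rate_windows(rec30, cfg)
    rs90, x90 = _rate_windows(rec90, cfg)
    xedges = np.arange(0.0, sim.arena_cm + cfg.xbin_cm / 2, cfg.xbin_cm)
    decode = {}
    for gname, gidx in groups.items():
        if gidx.size < 1:
            warnings.warn(f"no cells in group {gname}; decoding skipped")
            continue
        fa = rs30.rates[idx30[gidx]].T
        fb = rs90.rates[idx90[gidx]].T
        table = decoding.decode_depth_by_xbin(fa, x30, fb, x90, xedges,
                                              seed=cfg.seed)
        _write_csv(table, cfg.out_dir, f"cliff_xbin_accuracy_{gname}.csv")
        decode[gname] = {
            "mean_accuracy": float(np.nanmean(table["accuracy"])),
            "per_bin": table["accuracy"].tolist(),
        }
    report["depth_decoding"] = decode

    # --- optional classifier roster calibration (all matched cells)
    if cfg.roster:
        X = np.vstack([rs30.rates[idx30].T, rs90.rates[idx90].T])
        y = np.concatenate([np.zeros(rs30.t.size, int),
                            np.ones(rs90.t.size, int)])
        comp = decoding.compare_classifiers(X, y, seed=cfg.seed)
        report["roster"] = {k: {"accuracy": v["accuracy"]}
                            for k, v in comp.items()}

    return _write_report(report, cfg.out_dir, "cliff_report.json")


# ---------------------------------------------------------------------------
# maze (VSLM) pipeline
# ---------------------------------------------------------------------------

def _pre_t0_series(neural, trials):
    """Concatenate imaging frames inside each trial's pre-entry dwell with
    the binary orientation resampled onto the imaging clock."""
    t_img = neural.timestamps
    mask = np.zeros(t_img.size, bool)
    ori_img = np.zeros(t_img.size, int)
    for tr in trials:
        if tr.t0 is None or tr.ori_t.size == 0:
            continue
        m = (t_img >= tr.ori_t[0]) & (t_img <= tr.ori_t[-1])
        if not m.any():
            continue
        idx = np.clip(np.searchsorted(tr.ori_t, t_img[m], side="right") - 1,
                      0, tr.ori_t.size - 1)
        ori_img[m] = tr.ori[idx]
        mask[m] = True
    return mask, ori_img


def _analyze_vslm_session(neural, behavior, trials, cfg: AnalysisConfig,
                          seed: int) -> dict:
    out: dict = {}
    mask, ori_img = _pre_t0_series(neural, trials)
    traces_pre = neural.traces[:, mask]
    y_pre = ori_img[mask]
    fps_img = 1.0 / float(np.median(np.diff(neural.timestamps)))
    min_shift = max(int(round(cfg.min_shift_s * fps_img)), 1)
    observed, null = information.mi_scores_with_null(
        traces_pre, y_pre, k=cfg.mi_neighbors, n_shuffles=cfg.n_shuffles,
        min_shift=min_shift, seed=seed, null_mode=cfg.null_mode)
    scores = information.classify_dsva(observed, null)
    sel = np.array([s.selected for s in scores])
    out["dsva"] = {"n_cells": int(sel.size), "n_selected": int(sel.sum()),
                   "selected_fraction": float(sel.mean())}
    out["mi_observed"] = observed.tolist()
    out["selected"] = sel.tolist()

    # --- trial-aligned z-scored event rates, ridge fits per group
    rs = preprocess.event_rate(neural.events, neural.timestamps[0],
                               neural.timestamps[-1],
                               bin_s=cfg.rate_bin_s, step_s=cfg.rate_step_s)
    preprocess.zscore(rs)
    order = np.argsort(-observed)
    ridge = {}
    for group_name, gmask in (("dsva", sel), ("rejected", ~sel)):
        gorder = order[gmask[order]]
        for trial_group in ("correct", "incorrect"):
            try:
                rel_t, aligned = preprocess.trial_aligned_mean(
                    rs, trials, trial_group, rel_window=cfg.rel_window_s)
            except ValueError:
                ridge[f"{group_name}_{trial_group}"] = None
                continue
            fit = information.ridge_fit(aligned[gorder], rel_t,
                                        threshold=cfg.ridge_threshold)
            ridge[f"{group_name}_{trial_group}"] = {
                half: (None if f is None else dataclasses.asdict(f))
                for half, f in fit.items()}
    out["ridge_fits"] = ridge

    # --- choice decoding time course per group
    rel_t = np.arange(cfg.rel_window_s[0],
                      cfg.rel_window_s[1] + cfg.rate_step_s / 2,
                      cfg.rate_step_s)
    complete = [t for t in trials if t.t0 is not None]
    choices = np.array([int(t.correct) for t in complete])
    if np.unique(choices).size < 2 or len(complete) < 10:
        warnings.warn("only one trial type or too few trials; "
                      "choice decoding skipped")
        out["choice_decoding"] = None
    else:
        aligned = np.stack([
            np.vstack([np.interp(t.t0 + rel_t, rs.t, rs.z[c])
                       for c in range(neural.n_cells)])
            for t in complete])
        dec = {}
        for group_name, gmask in (("dsva", sel), ("rejected", ~sel)):
            if gmask.sum() < 1:
                continue
            acc, peak = decoding.decode_choice_timecourse(
                aligned[:, gmask, :], choices, k=cfg.knn_k,
                n_iter=cfg.n_iter, seed=seed)
            dec[group_name] = {"accuracy": acc.tolist(), "peak": peak}
        dec["rel_t"] = rel_t.tolist()
        out["choice_decoding"] = dec
    return out


def run_vslm(cfg: AnalysisConfig, n_sessions: Optional[int] = None) -> dict:
    """Maze analysis: per-cell MI vs shuffle null, cell selection, ridge
    fits, choice decoding; with 3+ sessions adds cross-registration and the
    joint-MI stability test of the selected populations."""
    sim = cfg.sim
    n_sessions = cfg.n_vslm_sessions if n_sessions is None else n_sessions
    base_fp = simulate.base_footprints(sim, cfg.seed)
    report: dict = {"stage": "vslm", "seed": cfg.seed,
                    "config_hash": cfg.config_hash(),
                    "n_sessions": n_sessions}

    sessions = []
    for s in range(n_sessions):
        neural, behavior, trials, truth = simulate.make_vslm_session(
            sim, cfg.seed + 1000 * s, base_centroids=base_fp)
        sessions.append((neural, behavior, trials, truth))

    per_session = []
    for s, (neural, behavior, trials, truth) in enumerate(sessions):
        out = _analyze_vslm_session(neural, behavior, trials, cfg,
                                    seed=cfg.seed + 1000 * s)
        sel = np.array(out["selected"])
        planted = truth.cell_class == "choice_tuned"
        untuned = truth.cell_class == "noise"
        out["dsva"]["sensitivity"] = (
            float(sel[planted].mean()) if planted.any() else None)
        out["dsva"]["noise_false_positive_rate"] = (
            float(sel[untuned].mean()) if untuned.any() else None)
        per_session.append(out)
    report["sessions"] = per_session

    # --- cross-session stability of the selected population
    if n_sessions >= 3:
        matched = preprocess.cross_register_many(
            [s[0].centroids for s in sessions[:3]])
        members = [np.array(per_session[k]["selected"])[matched[:, k]].astype(int)
                   for k in range(3)]
        obs = information.joint_mi(*members)
        rng = np.random.default_rng(cfg.seed)
        n = members[0].size
        vals = np.array([
            information.joint_mi(members[0][rng.permutation(n)],
                                 members[1], members[2])
            for _ in range(cfg.n_shuffles)])
        from .core import NullDistribution
        null = NullDistribution(values=vals, seed=cfg.seed)
        report["stability"] = {
            "n_matched": int(n),
            "joint_mi": float(obs),
            "null_lo": null.lo, "null_hi": null.hi,
            "above_null": bool(obs > null.hi),
        }
    return _write_report(report, cfg.out_dir, "vslm_report.json")


# ---------------------------------------------------------------------------
# overlap + track pipeline
# ---------------------------------------------------------------------------

def _arm_distance(behavior) -> np.ndarray:
    """Distance from the junction while on an arm (nan inside the box)."""
    pos = behavior.position
    d = np.hypot(pos[:, 0], pos[:, 1])
    d[pos[:, 1] < 0] = np.nan
    return d


def run_overlap_and_track(cfg: AnalysisConfig) -> dict:
    """Cross-task membership overlap (MI vs shuffle), position decoding on
    the maze arms per cell group, and actual-vs-relative position decoding
    with error-sign ratios on the linear track."""
    sim = cfg.sim
    base_fp = simulate.base_footprints(sim, cfg.seed)
    report: dict = {"stage": "overlap_track", "seed": cfg.seed,
                    "config_hash": cfg.config_hash()}

    rec30, rec90, cliff_truth = simulate.make_cliff_pair(
        sim, cfg.seed, base_centroids=base_fp)
    vslm_neural, vslm_behavior, vslm_trials, vslm_truth = \
        simulate.make_vslm_session(sim, cfg.seed + 1, base_centroids=base_fp)
    track_neural, track_behavior, track_truth = \
        simulate.make_linear_track_session(sim, cfg.seed + 2,
                                           base_centroids=base_fp)

    # --- DSVC membership from the cliff pair
    cliff_cfg = dataclasses.replace(cfg, out_dir=None, roster=False)
    cliff_report = run_cliff(cliff_cfg, sessions=(rec30, rec90),
                             truth=cliff_truth)
    report["cliff_dsvc"] = cliff_report["dsvc"]
    # recompute selection vector (run_cliff reports only counts)
    pairs, _, _ = preprocess.cross_register(rec30.neural.centroids,
                                            rec90.neural.centroids)

    edges = np.arange(0.0, sim.arena_cm + cfg.map_bin_cm / 2, cfg.map_bin_cm)
    area_scores = np.empty(pairs.shape[0])
    for row, (c30, c90) in enumerate(pairs):
        maps = []
        for rec, c in ((rec30, c30), (rec90, c90)):
            t_img = rec.neural.timestamps
            x_img = np.interp(t_img, rec.behavior.timestamps,
                              rec.behavior.position[:, 0])
            dt = float(np.median(np.diff(t_img)))
            maps.append(depth_tuning.ratemap(
                rec.neural.traces[c], x_img, edges, dt,
                min_occupancy=cfg.min_occupancy_s))
        area_scores[row] = depth_tuning.area_score(maps[0], maps[1])
    dsvc_scores = depth_tuning.classify_dsvc(area_scores)
    dsvc_sel_by_cell = np.zeros(sim.n_cells, bool)
    dsvc_sel_by_cell[pairs[:, 0]] = [s.selected for s in dsvc_scores]

    # --- DSVA membership from the maze session
    vslm_out = _analyze_vslm_session(vslm_neural, vslm_behavior, vslm_trials,
                                     cfg, seed=cfg.seed + 1)
    dsva_sel_by_cell = np.array(vslm_out["selected"], bool)

    # --- overlap MI vs rotation null (matched cells across tasks)
    xmatch, _, _ = preprocess.cross_register(rec30.neural.centroids,
                                             vslm_neural.centroids)
    mem_c = dsvc_sel_by_cell[xmatch[:, 0]].astype(int)
    mem_a = dsva_sel_by_cell[xmatch[:, 1]].astype(int)
    obs = information.mi_discrete(mem_c, mem_a)
    null = information.shuffle_null(information.mi_discrete, mem_c, mem_a,
                                    n_shuffles=cfg.n_shuffles, seed=cfg.seed,
                                    mode="permute")
    report["overlap"] = {
        "n_matched": int(xmatch.shape[0]),
        "n_dsvc": int(mem_c.sum()), "n_dsva": int(mem_a.sum()),
        "mi": float(obs), "null_lo": null.lo, "null_hi": null.hi,
        "outside_null": bool(null.outside(obs)),
    }

    # --- position decoding on the maze arms per group
    arm_d = _arm_distance(vslm_behavior)
    rs = preprocess.event_rate(vslm_neural.events, vslm_neural.timestamps[0],
                               vslm_neural.timestamps[-1],
                               bin_s=cfg.rate_bin_s, step_s=cfg.rate_step_s)
    d_at_win = np.interp(rs.t, vslm_behavior.timestamps,
                         np.nan_to_num(arm_d, nan=-1.0))
    on_arm = np.interp(rs.t, vslm_behavior.timestamps,
                       (~np.isnan(arm_d)).astype(float)) > 0.99
    valid = on_arm & (d_at_win >= 0)
    long_arm = max(sim.arm_lengths_cm)
    pedges = np.arange(0.0, long_arm + cfg.pos_bin_cm / 2, cfg.pos_bin_cm)
    arm_decode = {}
    for gname, members in (("dsvc", dsvc_sel_by_cell), ("dsva", dsva_sel_by_cell)):
        gidx = np.flatnonzero(members)
        if gidx.size < 5:
            warnings.warn(f"<5 matched cells in group {gname}; skipped")
            continue
        result, summary = decoding.decode_position(
            rs.rates[gidx][:, valid].T, d_at_win[valid], pedges,
            n_iter=cfg.n_iter, seed=cfg.seed)
        _write_csv(result, cfg.out_dir, f"vslm_position_{gname}.csv")
        arm_decode[gname] = summary
    report["arm_position_decoding"] = arm_decode

    # --- linear track: actual vs relative position decoding
    L = sim.track_length_cm
    rs_t = preprocess.event_rate(track_neural.events,
                                 track_neural.timestamps[0],
                                 track_neural.timestamps[-1],
                                 bin_s=cfg.rate_bin_s, step_s=cfg.rate_step_s)
    x_t = np.interp(rs_t.t, track_behavior.timestamps,
                    track_behavior.position[:, 0])
    rel, direction, valid_t = decoding.relative_positions(x_t, L)
    pedges_t = np.arange(0.0, L + cfg.pos_bin_cm / 2, cfg.pos_bin_cm)
    track = {}
    for gname, members in (("dsvc", dsvc_sel_by_cell), ("dsva", dsva_sel_by_cell)):
        gidx = np.flatnonzero(members)
        if gidx.size < 5:
            continue
        feats = rs_t.rates[gidx][:, valid_t].T
        res_a, sum_a = decoding.decode_position(
            feats, x_t[valid_t], pedges_t, n_iter=cfg.n_iter,
            seed=cfg.seed, direction=direction[valid_t])
        res_r, sum_r = decoding.decode_position(
            feats, rel[valid_t], pedges_t, n_iter=cfg.n_iter,
            seed=cfg.seed, relative=True)
        track[gname] = {
            "actual": {**sum_a, "sign":
                       decoding.error_sign_ratio(res_a["signed_error"])},
            "relative": {**sum_r, "sign":
                         decoding.error_sign_ratio(res_r["signed_error"])},
        }
        for key in track[gname].values():  # the long curves live in the CSVs
            key.pop("cumulative_error_cm", None)
            key.pop("cumulative_fraction", None)
        _write_csv(res_a, cfg.out_dir, f"track_actual_{gname}.csv")
        _write_csv(res_r, cfg.out_dir, f"track_relative_{gname}.csv")
    report["track_decoding"] = track
    return _write_report(report, cfg.out_dir, "overlap_track_report.json")


def run_all(cfg: AnalysisConfig) -> dict:
    return {
        "cliff": run_cliff(cfg),
        "vslm": run_vslm(cfg),
        "overlap_track": run_overlap_and_track(cfg),
    }
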