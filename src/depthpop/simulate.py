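"""Synthetic session generation with planted cell classes.

Generates complete behavior + imaging sessions for the three paradigms
(cliff arena pair, two-arm variable-length maze, linear track) with known
ground truth, so every downstream stage can be validated offline.

Trajectories are Ornstein-Uhlenbeck-style correlated walks with reflecting
walls; deep-side avoidance in the cliff arena is a multiplicative rejection
penalty on moves ending on the deep side. Spiking is inhomogeneous Poisson
from per-frame rate functions; traces are causal exponential kernels plus
Gaussian noise.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    BehaviorTrack,
    ConfigError,
    GroundTruth,
    NeuralSession,
    Recording,
    SimConfig,
    Trial,
    TrialTable,
)

__all__ = [
    "make_cliff_pair",
    "make_vslm_session",
    "make_linear_track_session",
    "spikes_to_trace",
    "poisson_events",
    "base_footprints",
]


def base_footprints(config: SimConfig, seed: int) -> np.ndarray:
    """Deterministic shared footprint centroids for a cohort of sessions."""
    return _footprints(config, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# calcium / spiking primitives
# ---------------------------------------------------------------------------

def spikes_to_trace(
    spike_times: np.ndarray,
    tau: float,
    sigma: float,
    frame_times: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render spike times into a fluorescence-like trace on a frame grid.

    Each spike contributes a causal kernel ``exp(-(t - ts)/tau)`` with unit
    amplitude. Spikes are binned to frames first, so the returned event list
    is the input spike times snapped onto the frame grid. Gaussian noise of
    scale ``sigma`` is added when ``sigma > 0``.

    Returns
    -------
    trace, binned_event_times
    """
    if tau <= 0:
        raise ConfigError("tau must be > 0")
    if sigma < 0:
        raise ConfigError("sigma must be >= 0")
    frame_times = np.asarray(frame_times, float)
    n = frame_times.size
    dt = float(frame_times[1] - frame_times[0]) if n > 1 else 1.0
    spike_times = np.sort(np.asarray(spike_times, float))
    idx = np.searchsorted(frame_times, spike_times, side="right") - 1
    idx = idx[(idx >= 0) & (idx < n)]
    counts = np.bincount(idx, minlength=n).astype(float)

    # recursive exponential filter == exact kernel sum for frame-aligned spikes
    trace = np.empty(n)
    decay = np.exp(-dt / tau)
    acc = 0.0
    for i in range(n):
        acc = acc * decay + counts[i]
        trace[i] = acc
    if sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        trace = trace + rng.normal(0.0, sigma, size=n)
    return trace, frame_times[np.repeat(np.arange(n), counts.astype(int))]


def poisson_events(
    rate_hz: np.ndarray, frame_times: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw inhomogeneous Poisson event times from a per-frame rate series."""
    frame_times = np.asarray(frame_times, float)
    dt = float(frame_times[1] - frame_times[0])
    counts = rng.poisson(np.maximum(rate_hz, 0.0) * dt)
    reps = np.repeat(np.arange(frame_times.size), counts)
    jitter = rng.uniform(0.0, dt, size=reps.size)
    return np.sort(frame_times[reps] + jitter)


def _render_cells(
    rates: np.ndarray,  # (cells, frames) Hz on the imaging clock
    frame_times: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[np.ndarray]]:
    traces = np.empty_like(rates)
    events: list[np.ndarray] = []
    for c in range(rates.shape[0]):
        ev = poisson_events(rates[c], frame_times, rng)
        tr, ev_binned = spikes_to_trace(ev, cfg.tau_s, cfg.trace_noise,
                                        frame_times, rng)
        traces[c] = tr
        events.append(ev_binned)
    return traces, events


def _footprints(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    pad = 30.0
    return rng.uniform(pad, cfg.fov_px - pad, size=(cfg.n_cells, 2))


def _jitter_footprints(base: np.ndarray, rng: np.random.Generator,
                       scale: float = 1.5) -> np.ndarray:
    return base + rng.normal(0.0, scale, size=base.shape)


def _keypoints(body: np.ndarray, rng: np.random.Generator,
               offset_cm: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Head/tail keypoints offset from the body along the travel direction."""
    vel = np.gradient(body, axis=0)
    norm = np.linalg.norm(vel, axis=1, keepdims=True)
    unit = np.divide(vel, norm, out=np.zeros_like(vel), where=norm > 1e-12)
    noise = rng.normal(0.0, 0.2, size=body.shape)
    head = body + offset_cm * unit + noise
    tail = body - offset_cm * unit + noise
    return head, tail


# ---------------------------------------------------------------------------
# cliff arena pair
# ---------------------------------------------------------------------------

def _cliff_walk(cfg: SimConfig, bias: float,
                rng: np.random.Generator) -> np.ndarray:
    """Bounded OU walk; moves ending on the deep half (x > arena/2) are
    rejected with probability ``bias``."""
    n = int(round(cfg.duration_s * cfg.behavior_hz))
    dt = 1.0 / cfg.behavior_hz
    theta = 1.0
    sig = cfg.run_speed_cms * np.sqrt(2.0 * theta)
    half = cfg.arena_cm / 2.0
    pos = np.empty((n, 2))
    p = np.array([half, half])
    v = np.zeros(2)
    xi = rng.normal(size=(n, 2))
    rej = rng.random(n)
    for i in range(n):
        v = v + (-theta * v) * dt + sig * np.sqrt(dt) * xi[i]
        cand = p + v * dt
        for d in range(2):  # reflecting walls
            if cand[d] < 0:
                cand[d] = -cand[d]
                v[d] = -v[d]
            elif cand[d] > cfg.arena_cm:
                cand[d] = 2 * cfg.arena_cm - cand[d]
                v[d] = -v[d]
        if cand[0] > half and rej[i] < bias:
            v = -v  # deep-side move rejected: bounce back
        else:
            p = cand
        pos[i] = p
    return pos


def _cliff_rates(cfg: SimConfig, pos_img: np.ndarray, session_gain: np.ndarray,
                 field_centers: np.ndarray) -> np.ndarray:
    """Per-frame rates on the imaging clock for one cliff session."""
    n_frames = pos_img.shape[0]
    rates = np.empty((cfg.n_cells, n_frames))
    w2 = 2.0 * cfg.place_field_width_cm ** 2
    classes = cfg.cell_classes()
    for c in range(cfg.n_cells):
        cls = classes[c]
        if cls == "depth_tuned":
            rates[c] = cfg.baseline_rate_hz * session_gain[c]
        elif cls == "place":
            d2 = np.sum((pos_img - field_centers[c]) ** 2, axis=1)
            rates[c] = cfg.place_peak_hz * np.exp(-d2 / w2) + 0.05
        else:  # choice_tuned behaves as untuned outside the maze; noise flat
            rates[c] = cfg.baseline_rate_hz
    return rates


def make_cliff_pair(
    config: SimConfig, seed: int,
    base_centroids: np.ndarray | None = None,
) -> tuple[Recording, Recording, GroundTruth]:
    """Two cliff-arena sessions (shallow 30 cm / deep 90 cm illusion depth)
    sharing cell identities.

    Depth-tuned cells change mean rate between sessions by ``depth_gain``
    (direction random per cell); place cells fire by position identically in
    both; everything else is homogeneous Poisson at baseline.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    classes = cfg.cell_classes()
    centers = rng.uniform(5.0, cfg.arena_cm - 5.0, size=(cfg.n_cells, 2))
    depth_dir = np.where(rng.random(cfg.n_cells) < 0.5, 1, -1)
    # session gains: gain applied in session 90 (dir=+1) or session 30 (dir=-1)
    gain30 = np.where((classes == "depth_tuned") & (depth_dir < 0),
                      cfg.depth_gain, 1.0)
    gain90 = np.where((classes == "depth_tuned") & (depth_dir > 0),
                      cfg.depth_gain, 1.0)
    base_fp = _footprints(cfg, rng) if base_centroids is None else base_centroids

    recs = []
    for kind, bias, gain in (("cliff30", cfg.avoid_bias[0], gain30),
                             ("cliff90", cfg.avoid_bias[1], gain90)):
        pos = _cliff_walk(cfg, bias, rng)
        t_beh = np.arange(pos.shape[0]) / cfg.behavior_hz
        t_img = np.arange(int(round(cfg.duration_s * cfg.imaging_hz))) / cfg.imaging_hz
        pos_img = np.column_stack([np.interp(t_img, t_beh, pos[:, d])
                                   for d in range(2)])
        rates = _cliff_rates(cfg, pos_img, gain, centers)
        traces, events = _render_cells(rates, t_img, cfg, rng)
        head, tail = _keypoints(pos, rng)
        lik = np.full((pos.shape[0], 3), 0.99)
        neural = NeuralSession(
            session_id=f"{kind}-seed{seed}", kind=kind, timestamps=t_img,
            traces=traces, events=events,
            centroids=_jitter_footprints(base_fp, rng),
        )
        behavior = BehaviorTrack(timestamps=t_beh, head=head, body=pos,
                                 tail=tail, likelihood=lik)
        recs.append(Recording(neural=neural, behavior=behavior))

    truth = GroundTruth(
        cell_class=classes,
        cell_params=pd.DataFrame({
            "depth_dir": depth_dir,
            "field_x": centers[:, 0],
            "field_y": centers[:, 1],
        }),
        extra={"avoid_bias": cfg.avoid_bias, "depth_gain": cfg.depth_gain},
    )
    return recs[0], recs[1], truth


# ---------------------------------------------------------------------------
# two-arm variable-length maze
# ---------------------------------------------------------------------------

def _arm_direction(side: str, cfg: SimConfig) -> np.ndarray:
    a = np.deg2rad(cfg.arm_angle_deg)
    s = np.sin(a) if side == "right" else -np.sin(a)
    return np.array([s, np.cos(a)])


def make_vslm_session(
    config: SimConfig, seed: int,
    base_centroids: np.ndarray | None = None,
) -> tuple[NeuralSession, BehaviorTrack, TrialTable, GroundTruth]:
    """One maze session: per-trial start-box dwell with a binary head
    orientation series, junction crossing at t0, and an arm run to reward.

    Arm lengths are drawn per trial from a seeded random sequence; the longer
    arm is always the rewarded (correct) one. ``choice_accuracy`` controls
    the fraction of trials in which the planted choice is correct.
    Choice-tuned cells fire above baseline during the pre-t0 dwell whenever
    the orientation matches the cell's preferred direction.
    """
    cfg = config
    if cfg.n_trials < 1:
        raise ConfigError("need at least one trial")
    rng = np.random.default_rng(seed)
    classes = cfg.cell_classes()
    dt = 1.0 / cfg.behavior_hz
    short, long = sorted(cfg.arm_lengths_cm)

    choice_pref = np.where(rng.random(cfg.n_cells) < 0.5, 1, 0)
    arm_centers = rng.uniform(2.0, long - 2.0, size=cfg.n_cells)

    pos_parts: list[np.ndarray] = []
    ori_full_parts: list[np.ndarray] = []   # -1 outside dwell
    arm_dist_parts: list[np.ndarray] = []   # nan outside arm
    trials: list[Trial] = []
    t_cursor = 0.0
    box_center = np.array([0.0, -cfg.startbox_cm / 2.0])

    for k in range(cfg.n_trials):
        long_side = "right" if rng.random() < 0.5 else "left"
        arm_len = {long_side: long,
                   ("left" if long_side == "right" else "right"): short}
        correct = bool(rng.random() < cfg.choice_accuracy)
        chosen = long_side if correct else (
            "left" if long_side == "right" else "right")

        # --- start-box dwell with block-switching binary orientation
        dwell = rng.uniform(*cfg.dwell_s)
        n_dwell = max(int(round(dwell / dt)), 2)
        block = max(int(round(cfg.ori_block_s / dt)), 1)
        n_blocks = n_dwell // block + 1
        toward_correct = rng.integers(0, 2, size=n_blocks)
        toward_correct[-1] = 1 if chosen == long_side else 0  # final glance
        ori = np.repeat(toward_correct, block)[:n_dwell]
        jig = rng.normal(0.0, 0.3, size=(n_dwell, 2))
        dwell_pos = box_center + np.cumsum(jig, axis=0) * 0.1
        dwell_pos[:, 1] = np.clip(dwell_pos[:, 1], -cfg.startbox_cm + 0.5, -0.5)
        dwell_pos[:, 0] = np.clip(dwell_pos[:, 0], -3.0, 3.0)

        # --- run out along the chosen arm, pause at reward, run back
        direction = _arm_direction(chosen, cfg)
        run_len = arm_len[chosen]
        n_run = max(int(round(run_len / cfg.run_speed_cms / dt)), 2)
        d_out = np.linspace(0.0, run_len, n_run)
        n_pause = max(int(round(cfg.end_dwell_s / dt)), 1)
        d_pause = np.full(n_pause, run_len)
        d_back = np.linspace(run_len, 0.0, n_run)
        d_all = np.concatenate([d_out, d_pause, d_back])
        arm_pos = d_all[:, None] * direction[None, :]

        trial_pos = np.vstack([dwell_pos, arm_pos])
        n_trial = trial_pos.shape[0]
        ori_full = np.full(n_trial, -1, dtype=int)
        ori_full[:n_dwell] = ori
        arm_dist = np.full(n_trial, np.nan)
        arm_dist[n_dwell:] = d_all

        t_start = t_cursor
        t0 = t_cursor + n_dwell * dt
        t_end = t_cursor + n_trial * dt
        trials.append(Trial(
            index=k,
            arm_lengths=(arm_len["left"], arm_len["right"]),
            correct_side=long_side, chosen_side=chosen, correct=correct,
            t_start=t_start, t0=t0, t_end=t_end,
            ori_t=t_start + np.arange(n_dwell) * dt, ori=ori.astype(int),
        ))
        pos_parts.append(trial_pos)
        ori_full_parts.append(ori_full)
        arm_dist_parts.append(arm_dist)
        t_cursor = t_end

    pos = np.vstack(pos_parts)
    ori_series = np.concatenate(ori_full_parts)
    arm_dist = np.concatenate(arm_dist_parts)
    t_beh = np.arange(pos.shape[0]) * dt
    total_s = pos.shape[0] * dt

    # --- rates on the imaging clock
    t_img = np.arange(int(round(total_s * cfg.imaging_hz))) / cfg.imaging_hz
    idx_beh = np.clip(np.searchsorted(t_beh, t_img, side="right") - 1,
                      0, t_beh.size - 1)
    ori_img = ori_series[idx_beh]
    arm_img = arm_dist[idx_beh]
    rates = np.empty((cfg.n_cells, t_img.size))
    w2 = 2.0 * cfg.place_field_width_cm ** 2
    for c in range(cfg.n_cells):
        cls = classes[c]
        if cls == "choice_tuned":
            r = np.full(t_img.size, cfg.baseline_rate_hz)
            hot = ori_img == choice_pref[c]
            r[hot] = cfg.baseline_rate_hz * cfg.choice_gain
            rates[c] = r
        elif cls == "place":
            r = np.full(t_img.size, 0.05)
            on_arm = ~np.isnan(arm_img)
            r[on_arm] += cfg.place_peak_hz * np.exp(
                -(arm_img[on_arm] - arm_centers[c]) ** 2 / w2)
            rates[c] = r
        else:
            rates[c] = cfg.baseline_rate_hz
    traces, events = _render_cells(rates, t_img, cfg, rng)

    head, tail = _keypoints(pos, rng)
    behavior = BehaviorTrack(timestamps=t_beh, head=head, body=pos, tail=tail,
                             likelihood=np.full((pos.shape[0], 3), 0.99))
    base_fp = _footprints(cfg, rng) if base_centroids is None else base_centroids
    neural = NeuralSession(
        session_id=f"vslm-seed{seed}", kind="vslm", timestamps=t_img,
        traces=traces, events=events,
        centroids=_jitter_footprints(base_fp, rng),
    )
    truth = GroundTruth(
        cell_class=classes,
        cell_params=pd.DataFrame({
            "choice_pref": choice_pref,
            "arm_field_cm": arm_centers,
        }),
        trial_info=TrialTable(trials).to_frame(),
    )
    return neural, behavior, TrialTable(trials), truth


# ---------------------------------------------------------------------------
# linear track
# ---------------------------------------------------------------------------

def _track_run(L: float, speed: float, dt: float, decel_zone: float,
               min_frac: float, going_right: bool) -> np.ndarray:
    """One end-to-end run, slowing smoothly inside the goal's approach zone
    (if ``decel_zone`` is 0 the speed is constant)."""
    xs = []
    x = 0.0 if going_right else L
    goal = L if going_right else 0.0
    step_sign = 1.0 if going_right else -1.0
    guard = int(10 * L / (speed * min_frac * dt)) + 10
    for _ in range(guard):
        remaining = abs(goal - x)
        if remaining < 1e-6:
            break
        frac = 1.0 if decel_zone <= 0 else \
            min_frac + (1.0 - min_frac) * min(remaining / decel_zone, 1.0)
        x = x + step_sign * min(speed * frac * dt, remaining)
        xs.append(x)
    return np.asarray(xs) if xs else np.array([goal])


def make_linear_track_session(
    config: SimConfig, seed: int,
    base_centroids: np.ndarray | None = None,
) -> tuple[NeuralSession, BehaviorTrack, GroundTruth]:
    """Back-and-forth runs on a linear track, slowing into each reward end.

    Place cells come in two codings (alternating): direction-selective
    allocentric fields shifted forward along the running direction by
    ``prospective_lag_cm``, and goal-distance (egocentric) fields that
    anticipate by a per-run exponential lag with the same mean. Lag 0 gives
    pure position coding with fields covering the whole track.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    classes = cfg.cell_classes()
    L = cfg.track_length_cm
    dt = 1.0 / cfg.behavior_hz
    n_total = int(round(cfg.duration_s * cfg.behavior_hz))

    x_parts: list[np.ndarray] = []
    going_right = True
    n_acc = 0
    n_pause = max(int(round(cfg.end_dwell_s / dt)), 1)
    while n_acc < n_total:
        speed = cfg.run_speed_cms * rng.uniform(0.9, 1.1)
        run = _track_run(L, speed, dt, cfg.decel_zone_cm,
                         cfg.min_speed_frac, going_right)
        pause = np.full(n_pause, run[-1])
        x_parts.extend([run, pause])
        n_acc += run.size + n_pause
        going_right = not going_right
    x = np.concatenate(x_parts)[:n_total]
    t_beh = np.arange(n_total) * dt

    dx = np.gradient(x)
    direction = np.sign(dx)
    # carry direction through pauses so the shifted field stays defined
    nz = np.flatnonzero(direction != 0)
    if nz.size:
        filled = np.interp(np.arange(n_total), nz, direction[nz])
        direction = np.sign(filled)
        direction[direction == 0] = 1.0

    t_img = np.arange(int(round(cfg.duration_s * cfg.imaging_hz))) / cfg.imaging_hz
    x_img = np.interp(t_img, t_beh, x)
    dir_img = np.sign(np.interp(t_img, t_beh, direction))
    dir_img[dir_img == 0] = 1.0

    r_img = np.where(dir_img > 0, L - x_img, x_img)  # distance to goal

    # fields tile the whole track so that, at lag 0, no quiet zone exists
    centers = rng.uniform(0.0, L, size=cfg.n_cells)
    prefs = (rng.choice([-1, 1], size=cfg.n_cells)
             if cfg.direction_selective_fields
             else np.zeros(cfg.n_cells, int))
    place_idx = np.flatnonzero(classes == "place")
    coding = np.array(["none"] * cfg.n_cells, dtype=object)
    # alternate allocentric fields and goal-distance (egocentric) fields
    coding[place_idx[0::2]] = "allo"
    coding[place_idx[1::2]] = "goal"
    w2 = 2.0 * cfg.place_field_width_cm ** 2
    rates = np.empty((cfg.n_cells, t_img.size))
    for c in range(cfg.n_cells):
        if coding[c] == "allo":
            # fires for the position `lag` cm ahead, in its preferred direction
            anticipated = x_img + cfg.prospective_lag_cm * dir_img
            bump = cfg.place_peak_hz * np.exp(
                -(anticipated - centers[c]) ** 2 / w2)
            if prefs[c] != 0:
                bump = np.where(dir_img == prefs[c], bump, 0.0)
            rates[c] = bump + 0.01
        elif coding[c] == "goal":
            # tuned to remaining distance, anticipating by the planted lag
            rates[c] = cfg.place_peak_hz * np.exp(
                -((r_img - cfg.prospective_lag_cm) - centers[c]) ** 2 / w2) \
                + 0.01
        else:
            rates[c] = cfg.baseline_rate_hz
    traces, events = _render_cells(rates, t_img, cfg, rng)

    pos = np.column_stack([x, np.zeros_like(x)])
    head, tail = _keypoints(pos, rng)
    behavior = BehaviorTrack(timestamps=t_beh, head=head, body=pos, tail=tail,
                             likelihood=np.full((n_total, 3), 0.99))
    base_fp = _footprints(cfg, rng) if base_centroids is None else base_centroids
    neural = NeuralSession(
        session_id=f"linear-seed{seed}", kind="linear", timestamps=t_img,
        traces=traces, events=events,
        centroids=_jitter_footprints(base_fp, rng),
    )
    truth = GroundTruth(
        cell_class=classes,
        cell_params=pd.DataFrame({
            "track_field_cm": centers,
            "dir_pref": prefs,
            "coding": coding,
            "lag_cm": np.full(cfg.n_cells, cfg.prospective_lag_cm),
        }),
        extra={"track_length_cm": L},
    )
    return neural, behavior, truth
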