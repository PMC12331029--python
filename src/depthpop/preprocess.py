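"""Derived series: event rates, speed, zone metrics, trial alignment, and
cross-session cell matching."""
from __future__ import annotations

import warnings

import numpy as np

from .core import BehaviorTrack, NeuralSession, RateSeries, TrialTable

__all__ = [
    "event_rate",
    "zscore",
    "trial_aligned_mean",
    "speed_from_track",
    "cliff_metrics",
    "align_to_junction",
    "cross_register",
    "cross_register_many",
    "resample_to",
]


def event_rate(
    events: list[np.ndarray],
    t_start: float,
    t_stop: float,
    bin_s: float = 1.0,
    step_s: float = 0.2,
) -> RateSeries:
    """Sliding-window firing rate: a ``bin_s`` window stepped by ``step_s``.

    Window centers start at ``t_start + bin_s/2`` and advance by ``step_s``
    while the window fits inside ``[t_start, t_stop]``; each rate is the
    event count in the half-open window ``[c - bin/2, c + bin/2)`` divided
    by ``bin_s``. With ``step_s == bin_s`` the windows tile the span, so
    summed counts are conserved.
    """
    if bin_s <= 0 or step_s <= 0:
        raise ValueError("bin and step must be > 0")
    n_win = int(np.floor((t_stop - t_start - bin_s) / step_s + 1e-9)) + 1
    if n_win < 1:
        raise ValueError("time grid too short for a single window")
    centers = t_start + bin_s / 2.0 + step_s * np.arange(n_win)
    lo = centers - bin_s / 2.0
    hi = centers + bin_s / 2.0
    rates = np.empty((len(events), n_win))
    for c, ev in enumerate(events):
        ev = np.asarray(ev, float)
        rates[c] = (np.searchsorted(ev, hi, side="left")
                    - np.searchsorted(ev, lo, side="left")) / bin_s
    return RateSeries(t=centers, rates=rates, bin_s=bin_s, step_s=step_s)


def zscore(rates: RateSeries) -> RateSeries:
    """Per-cell z-score over the session; zero-SD cells are set to 0."""
    mu = rates.rates.mean(axis=1, keepdims=True)
    sd = rates.rates.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant-rate cells z-scored to 0")
    z = np.divide(rates.rates - mu, sd, out=np.zeros_like(rates.rates),
                  where=sd > 0)
    rates.z = z
    return rates


def trial_aligned_mean(
    rates: RateSeries,
    trials: TrialTable,
    group: str,
    rel_window: tuple[float, float] = (-3.0, 3.0),
    use_z: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Average rates across trials of one group on a t0-aligned grid.

    ``group`` is ``"correct"`` or ``"incorrect"``. The mean over trials is
    the per-trial-count normalization that makes groups with different trial
    numbers comparable.

    Returns
    -------
    rel_t : (T,) time relative to t0
    aligned : (cells, T) trial-averaged rates
    """
    wanted = [t for t in trials
              if t.t0 is not None and t.correct == (group == "correct")]
    if not wanted:
        raise ValueError(f"no complete trials in group {group!r}")
    rel_t = np.arange(rel_window[0], rel_window[1] + rates.step_s / 2,
                      rates.step_s)
    values = rates.z if (use_z and rates.z is not None) else rates.rates
    acc = np.zeros((values.shape[0], rel_t.size))
    for tr in wanted:
        grid = tr.t0 + rel_t
        for c in range(values.shape[0]):
            acc[c] += np.interp(grid, rates.t, values[c])
    return rel_t, acc / len(wanted)


def speed_from_track(track: BehaviorTrack, window: int = 5) -> np.ndarray:
    """Speed (cm/s) from the body keypoint: per-frame Euclidean step lengths
    averaged over a sliding ``window`` of frames, divided by the frame
    interval. Returned per frame (edges padded with the nearest estimate)."""
    pos = track.position
    n = pos.shape[0]
    if n < window + 1:
        raise ValueError("track shorter than the smoothing window")
    dt = float(np.median(np.diff(track.timestamps)))
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)  # (n-1,)
    kernel = np.ones(window) / window
    smooth = np.convolve(steps, kernel, mode="valid")     # (n-window,)
    speed_mid = smooth / dt
    out = np.empty(n)
    half = window // 2
    out[half + 1: half + 1 + speed_mid.size] = speed_mid
    out[: half + 1] = speed_mid[0]
    out[half + 1 + speed_mid.size:] = speed_mid[-1]
    return out


def cliff_zones(track: BehaviorTrack, arena_cm: float,
                center_cm: float) -> dict[str, np.ndarray]:
    """Boolean frame masks: deep half (x > arena/2) and the concentric
    center square."""
    pos = track.position
    half = arena_cm / 2.0
    lo = (arena_cm - center_cm) / 2.0
    hi = arena_cm - lo
    deep = pos[:, 0] > half
    center = ((pos[:, 0] >= lo) & (pos[:, 0] <= hi)
              & (pos[:, 1] >= lo) & (pos[:, 1] <= hi))
    return {"deep": deep, "center": center}


def cliff_metrics(
    track: BehaviorTrack,
    checkpoints_s: np.ndarray,
    arena_cm: float = 60.0,
    center_cm: float = 30.0,
    speed_window: int = 5,
) -> dict[str, np.ndarray]:
    """Accumulated open-field metrics at each checkpoint time.

    Per checkpoint T: the deep-side fraction of the path length in [0, T];
    the deep fraction of path length restricted to the center square; and
    the median of per-frame speeds on the deep side up to T. Ratios with a
    zero denominator are returned as nan. Each step is attributed to the
    zone of its starting frame.
    """
    zones = cliff_zones(track, arena_cm, center_cm)
    steps = np.linalg.norm(np.diff(track.position, axis=0), axis=1)
    speed = speed_from_track(track, window=speed_window)
    t_step = track.timestamps[:-1]
    deep = zones["deep"][:-1]
    center = zones["center"][:-1]

    out = {k: np.empty(len(checkpoints_s)) for k in
           ("deep_distance_ratio", "center_deep_ratio", "deep_median_speed")}
    for i, T in enumerate(checkpoints_s):
        m = t_step <= T
        total = steps[m].sum()
        out["deep_distance_ratio"][i] = (
            steps[m & deep].sum() / total if total > 0 else np.nan)
        ctr = steps[m & center].sum()
        out["center_deep_ratio"][i] = (
            steps[m & center & deep].sum() / ctr if ctr > 0 else np.nan)
        frame_mask = (track.timestamps <= T) & zones["deep"]
        out["deep_median_speed"][i] = (
            float(np.median(speed[frame_mask])) if frame_mask.any() else np.nan)
    return out


def align_to_junction(
    track: BehaviorTrack,
    trial_windows: list[tuple[float, float]],
    junction_y: float = 0.0,
) -> np.ndarray:
    """First crossing of the start-box/arm junction per trial window.

    The junction is the line ``y == junction_y``; the start box lies below
    it. t0 is the time of the first frame whose body keypoint reaches the
    arm side after being on the box side. Trials without a crossing get nan
    (incomplete).
    """
    y = track.position[:, 1]
    t = track.timestamps
    above = y >= junction_y
    crossing = np.flatnonzero(~above[:-1] & above[1:]) + 1
    t_cross = t[crossing]
    t0 = np.full(len(trial_windows), np.nan)
    for i, (a, b) in enumerate(trial_windows):
        hits = t_cross[(t_cross >= a) & (t_cross < b)]
        if hits.size:
            t0[i] = hits[0]
    return t0


def cross_register(
    centroids_a: np.ndarray,
    centroids_b: np.ndarray,
    max_dist: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Greedy one-to-one matching of footprint centroids.

    Pairs are accepted in order of increasing Euclidean distance while both
    members are unmatched and the distance is strictly below ``max_dist``
    (cells moving within the threshold are considered identical).

    Returns
    -------
    pairs : (m, 2) int array of (index_a, index_b)
    unmatched_a, unmatched_b : int arrays
    """
    a = np.asarray(centroids_a, float)
    b = np.asarray(centroids_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("centroid arrays must be nonempty")
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    order = np.argsort(d, axis=None, kind="stable")
    used_a = np.zeros(a.shape[0], bool)
    used_b = np.zeros(b.shape[0], bool)
    pairs = []
    for flat in order:
        i, j = divmod(int(flat), b.shape[0])
        if d[i, j] >= max_dist:
            break
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            pairs.append((i, j))
    pairs_arr = (np.array(pairs, dtype=int) if pairs
                 else np.empty((0, 2), dtype=int))
    return pairs_arr, np.flatnonzero(~used_a), np.flatnonzero(~used_b)


def cross_register_many(
    centroid_sets: list[np.ndarray], max_dist: float = 10.0
) -> np.ndarray:
    """Chain pairwise matching across 3+ sessions; keep cells present in all.

    Returns an (m, n_sessions) index array, one row per matched cell.
    """
    if len(centroid_sets) < 2:
        raise ValueError("need at least two sessions")
    pairs, _, _ = cross_register(centroid_sets[0], centroid_sets[1], max_dist)
    chains = [[int(i), int(j)] for i, j in pairs]
    for s in range(2, len(centroid_sets)):
        prev = np.array([c[-1] for c in chains], dtype=int)
        sub_pairs, _, _ = cross_register(
            centroid_sets[s - 1][prev], centroid_sets[s], max_dist)
        keep = []
        for pi, j in sub_pairs:
            keep.append(chains[int(pi)] + [int(j)])
        chains = keep
    return (np.array(chains, dtype=int) if chains
            else np.empty((0, len(centroid_sets)), dtype=int))


def resample_to(values: np.ndarray, t_src: np.ndarray,
                t_dst: np.ndarray) -> np.ndarray:
    """Linear interpolation of a (n,) or (k, n) series onto a new clock."""
    values = np.asarray(values, float)
    if values.ndim == 1:
        return np.interp(t_dst, t_src, values)
    return np.vstack([np.interp(t_dst, t_src, row) for row in values])
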