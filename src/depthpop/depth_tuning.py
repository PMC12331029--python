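"""Rate maps, the area-score contrast, and depth-sensitive cell selection.

The area score contrasts a cell's occupancy-normalized rate maps between two
sessions: with ``A_k`` the total of map ``k`` over the bins both maps trust,
``score = (A1 - A2) / (|A1| + |A2|)``. Cells whose score falls beyond the
mean +/- SD of all scores in the animal are selected as depth sensitive.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .core import CellScore, RateMap

__all__ = ["ratemap", "area_score", "classify_dsvc", "session_rate_r2"]

DEFAULT_BIN_CM = 2.5          # matches the arena's checkerboard module
DEFAULT_MIN_OCCUPANCY_S = 0.2


def ratemap(
    activity: np.ndarray,
    positions: np.ndarray,
    bin_edges,
    dt: float,
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY_S,
) -> RateMap:
    """Occupancy-normalized activity map.

    ``activity`` and ``positions`` must share a time grid with frame
    interval ``dt`` (resample beforehand if needed). Each bin accumulates
    ``activity * dt`` and occupancy ``dt``; the normalized map is their
    ratio, with bins under ``min_occupancy`` masked to nan.
    """
    activity = np.asarray(activity, float)
    positions = np.asarray(positions, float)
    if positions.ndim == 1:
        positions = positions[:, None]
    if isinstance(bin_edges, np.ndarray):
        bin_edges = (bin_edges,)
    bin_edges = tuple(np.asarray(e, float) for e in bin_edges)
    if any(e.size < 3 for e in bin_edges):
        raise ValueError("need at least 2 bins per dimension")
    if activity.shape[0] != positions.shape[0]:
        raise ValueError("activity and positions must share a time grid")
    occ, _ = np.histogramdd(positions, bins=bin_edges)
    occ *= dt
    act, _ = np.histogramdd(positions, bins=bin_edges, weights=activity)
    act *= dt
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(occ >= min_occupancy, act / occ, np.nan)
    if np.all(np.isnan(norm)):
        raise ValueError("all bins below the occupancy threshold")
    return RateMap(bin_edges=bin_edges, activity=act, occupancy=occ,
                   normalized=norm, min_occupancy=min_occupancy)


def area_score(rm1: RateMap, rm2: RateMap, per_bin: bool = False):
    """Signed contrast of two rate maps in [-1, 1].

    Aggregates each map over the bins unmasked in both (the "area"), then
    returns ``(A1 - A2) / (|A1| + |A2|)``; 0 when both areas are 0. With
    ``per_bin=True`` the contrast is returned bin-wise instead.
    """
    if len(rm1.bin_edges) != len(rm2.bin_edges) or any(
            e1.size != e2.size or not np.allclose(e1, e2)
            for e1, e2 in zip(rm1.bin_edges, rm2.bin_edges)):
        raise ValueError("rate maps must share binning")
    shared = rm1.mask & rm2.mask
    if not shared.any():
        raise ValueError("no shared unmasked bins")
    if per_bin:
        a, b = rm1.normalized, rm2.normalized
        denom = np.abs(a) + np.abs(b)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, (a - b) / denom, 0.0)
        out[~shared] = np.nan
        return out
    a1 = float(np.nansum(np.where(shared, rm1.normalized, 0.0)))
    a2 = float(np.nansum(np.where(shared, rm2.normalized, 0.0)))
    denom = abs(a1) + abs(a2)
    return 0.0 if denom == 0 else (a1 - a2) / denom


def classify_dsvc(scores: np.ndarray) -> list[CellScore]:
    """Select cells whose area score lies beyond mean +/- SD of all scores.

    The threshold is two-sided and computed over every cell in the animal
    (sample SD). Zero spread rejects everything with a warning.
    """
    scores = np.asarray(scores, float)
    if scores.size < 2:
        raise ValueError("need at least 2 cells")
    mu = float(scores.mean())
    sd = float(scores.std(ddof=1))
    out = []
    if sd == 0:
        warnings.warn("zero SD of area scores: no cells selected")
    for i, s in enumerate(scores):
        selected = sd > 0 and (s < mu - sd or s > mu + sd)
        out.append(CellScore(cell=i, value=float(s), null_mean=mu, null_sd=sd,
                             null_lo=mu - sd, null_hi=mu + sd,
                             label="selected" if selected else "rejected"))
    return out


def session_rate_r2(
    mean_rates_a: np.ndarray,
    mean_rates_b: np.ndarray,
    group_labels: np.ndarray,
) -> dict[str, float]:
    """Per-group R^2 of the least-squares line of session-B mean rates on
    session-A mean rates. Groups with fewer than 3 cells are reported nan."""
    a = np.asarray(mean_rates_a, float)
    b = np.asarray(mean_rates_b, float)
    labels = np.asarray(group_labels)
    out: dict[str, float] = {}
    for g in np.unique(labels):
        m = labels == g
        if m.sum() < 3 or np.ptp(a[m]) == 0:
            out[str(g)] = np.nan
            continue
        res = stats.linregress(a[m], b[m])
        out[str(g)] = float(res.rvalue ** 2)
    return out
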