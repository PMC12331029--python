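"""Mutual-information machinery.

Continuous-vs-discrete MI uses a k-nearest-neighbor entropy estimator
(3 neighbors by default); discrete, conditional, and three-way interaction
information come straight from empirical joint tables. Nulls are built by
circularly rotating the neural series against the behavior series, which
breaks the alignment while preserving each series' autocorrelation. All
values are in nats.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma
from scipy import stats

from .core import CellScore, NullDistribution

__all__ = [
    "mi_knn",
    "mi_discrete",
    "mi_table",
    "cmi_discrete",
    "cmi_table",
    "joint_mi",
    "joint_mi_table",
    "shuffle_null",
    "classify_dsva",
    "mi_scores_with_null",
    "ridge_fit",
    "RidgeFit",
]


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def mi_knn(x: np.ndarray, y: np.ndarray, k: int = 3) -> float:
    """MI (nats) between a continuous series and a discrete one, via the
    k-nearest-neighbor entropy estimator, clipped below at 0.

    For each sample, the radius is the distance to its k-th neighbor within
    its own class; the estimate combines digammas of the class size and the
    number of points of any class inside that radius.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y).ravel()
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 20:
        raise ValueError("need at least 20 samples")
    if np.ptp(x) == 0:
        warnings.warn("constant continuous series: MI set to 0")
        return 0.0
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        return 0.0

    xx = x[:, None]
    radius = np.zeros(n)
    label_counts = np.zeros(n)
    k_all = np.zeros(n)
    for cls, cnt in zip(classes, counts):
        mask = y == cls
        label_counts[mask] = cnt
        if cnt > 1:
            kc = min(k, cnt - 1)
            tree = cKDTree(xx[mask])
            dist, _ = tree.query(xx[mask], k=kc + 1)
            radius[mask] = np.nextafter(dist[:, -1], 0)
            k_all[mask] = kc
    valid = label_counts > 1
    nv = int(valid.sum())
    if nv < 2:
        return 0.0
    tree = cKDTree(xx[valid])
    m_all = tree.query_ball_point(xx[valid], radius[valid], return_length=True)
    mi = (digamma(nv) + np.mean(digamma(k_all[valid]))
          - np.mean(digamma(label_counts[valid]))
          - np.mean(digamma(m_all)))
    return max(float(mi), 0.0)


def _joint_table(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xi = np.unique(x, return_inverse=True)[1]
    yi = np.unique(y, return_inverse=True)[1]
    table = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(table, (xi, yi), 1.0)
    return table / table.sum()


def mi_table(p_xy: np.ndarray) -> float:
    """I(X;Y) in nats from a joint probability table; 0*log 0 := 0."""
    p = np.asarray(p_xy, float)
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = p * np.log(p / (px * py))
    return float(np.nansum(np.where(p > 0, terms, 0.0)))


def mi_discrete(x: Sequence, y: Sequence) -> float:
    """Empirical I(X;Y) in nats from two discrete sample series."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    return mi_table(_joint_table(x, y))


def _joint_table3(x, y, z) -> np.ndarray:
    xi = np.unique(x, return_inverse=True)[1]
    yi = np.unique(y, return_inverse=True)[1]
    zi = np.unique(z, return_inverse=True)[1]
    table = np.zeros((xi.max() + 1, yi.max() + 1, zi.max() + 1))
    np.add.at(table, (xi, yi, zi), 1.0)
    return table / table.sum()


def cmi_table(p_xyz: np.ndarray) -> float:
    """I(X;Y|Z) in nats from a joint table p(x, y, z)."""
    p = np.asarray(p_xyz, float)
    pz = p.sum(axis=(0, 1))                    # p(z)
    pxz = p.sum(axis=1)                        # p(x, z)
    pyz = p.sum(axis=0)                        # p(y, z)
    total = 0.0
    for zi in range(p.shape[2]):
        if pz[zi] == 0:
            continue
        pj = p[:, :, zi] / pz[zi]              # p(x, y | z)
        px = pxz[:, zi] / pz[zi]
        py = pyz[:, zi] / pz[zi]
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = pj * np.log(pj / (px[:, None] * py[None, :]))
        total += pz[zi] * float(np.nansum(np.where(pj > 0, terms, 0.0)))
    return total


def cmi_discrete(x: Sequence, y: Sequence, z: Sequence) -> float:
    """Empirical I(X;Y|Z) in nats from discrete sample series."""
    x, y, z = (np.asarray(a).ravel() for a in (x, y, z))
    if not (x.size == y.size == z.size):
        raise ValueError("series must have equal length")
    return cmi_table(_joint_table3(x, y, z))


def joint_mi(x: Sequence, y: Sequence, z: Sequence) -> float:
    """Interaction information I(X;Y;Z) = I(X;Y) - I(X;Y|Z); may be
    negative (synergy) or positive (redundancy)."""
    return mi_discrete(x, y) - cmi_discrete(x, y, z)


def joint_mi_table(p_xyz: np.ndarray) -> float:
    p = np.asarray(p_xyz, float)
    return mi_table(p.sum(axis=2)) - cmi_table(p)


# ---------------------------------------------------------------------------
# shuffle null and cell selection
# ---------------------------------------------------------------------------

def shuffle_null(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    x: np.ndarray,
    y: np.ndarray,
    n_shuffles: int = 1000,
    min_shift: int = 1,
    seed: int = 0,
    mode: str = "rotate",
) -> NullDistribution:
    """Null distribution of ``statistic(x, y)`` under reordering of ``x``.

    ``mode="rotate"`` (for time series) rolls ``x`` by a random offset of at
    least ``min_shift`` samples (and at most ``n - min_shift``), preserving
    the series' autocorrelation while destroying its alignment with ``y``.
    ``mode="permute"`` (for unordered vectors such as cell memberships)
    draws a full random permutation instead, preserving only the counts.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)
    rng = np.random.default_rng(seed)
    if mode == "rotate":
        if n < 2 * min_shift:
            raise ValueError("series shorter than twice the minimum shift")
        offsets = rng.integers(min_shift, n - min_shift + 1, size=n_shuffles)
        vals = np.array([statistic(np.roll(x, int(o)), y) for o in offsets])
    elif mode == "permute":
        vals = np.array([statistic(x[rng.permutation(n)], y)
                         for _ in range(n_shuffles)])
    else:
        raise ValueError("mode must be 'rotate' or 'permute'")
    return NullDistribution(values=vals, seed=seed)


def classify_dsva(
    observed: np.ndarray,
    null: NullDistribution | list[NullDistribution],
) -> list[CellScore]:
    """Select cells whose observed MI falls outside the 95% interval of the
    shuffle null (two-sided). ``null`` is either one pooled distribution for
    all cells or a per-cell list."""
    observed = np.asarray(observed, float)
    if isinstance(null, NullDistribution):
        nulls = [null] * observed.size
    else:
        nulls = list(null)
        if len(nulls) != observed.size:
            raise ValueError("need one null per cell")
    out = []
    for i, (v, nd) in enumerate(zip(observed, nulls)):
        out.append(CellScore(
            cell=i, value=float(v),
            null_mean=float(nd.values.mean()), null_sd=float(nd.values.std()),
            null_lo=nd.lo, null_hi=nd.hi,
            label="selected" if nd.outside(v) else "rejected"))
    return out


def mi_scores_with_null(
    traces: np.ndarray,
    y: np.ndarray,
    k: int = 3,
    n_shuffles: int = 1000,
    min_shift: int = 1,
    seed: int = 0,
    null_mode: str = "pooled",
) -> tuple[np.ndarray, NullDistribution | list[NullDistribution]]:
    """Observed per-cell MI (kNN, trace vs binary series) plus its rotation
    null.

    With ``null_mode="pooled"`` (the default, one histogram per subject) the
    shuffle budget ``n_shuffles`` is spread evenly across cells and the
    rotated values of all cells are pooled into a single distribution; with
    ``"per_cell"`` every cell gets its own ``n_shuffles``-sized null.
    """
    traces = np.atleast_2d(np.asarray(traces, float))
    n_cells = traces.shape[0]
    observed = np.array([mi_knn(traces[c], y, k=k) for c in range(n_cells)])
    stat = lambda xs, ys: mi_knn(xs, ys, k=k)  # noqa: E731
    n = traces.shape[1]
    if n < 2 * min_shift:
        raise ValueError("series shorter than twice the minimum shift")
    if null_mode == "pooled":
        per_cell = max(int(np.ceil(n_shuffles / n_cells)), 1)
        chunks = []
        for c in range(n_cells):
            rng = np.random.default_rng(seed + c)
            offsets = rng.integers(min_shift, n - min_shift + 1,
                                   size=per_cell)
            chunks.append([stat(np.roll(traces[c], int(o)), y)
                           for o in offsets])
        pooled = NullDistribution(values=np.concatenate(chunks), seed=seed)
        return observed, pooled
    if null_mode == "per_cell":
        nulls = [shuffle_null(stat, traces[c], y, n_shuffles=n_shuffles,
                              min_shift=min_shift, seed=seed + c)
                 for c in range(n_cells)]
        return observed, nulls
    raise ValueError("null_mode must be 'pooled' or 'per_cell'")


# ---------------------------------------------------------------------------
# ridge-line fits of MI-sorted heatmaps
# ---------------------------------------------------------------------------

@dataclass
class RidgeFit:
    slope: float
    intercept: float
    r2: float
    n_cells: int


def ridge_fit(
    aligned: np.ndarray,
    rel_t: np.ndarray,
    threshold: float = 0.75,
) -> dict[str, RidgeFit | None]:
    """Line fits of threshold-crossing times against MI rank.

    ``aligned`` is (cells, T) of trial-averaged z-scored rates with rows
    already sorted by descending MI; ``rel_t`` is time relative to t0. For
    each cell and each half-window (pre: t < 0; post: t >= 0) the crossing
    time is the first time the rate reaches ``threshold`` x the cell's own
    window maximum (cells whose window maximum is not positive are
    excluded). Each half gets a least-squares line of crossing time on cell
    rank; halves with fewer than 3 contributing cells are reported None.
    """
    aligned = np.asarray(aligned, float)
    rel_t = np.asarray(rel_t, float)
    out: dict[str, RidgeFit | None] = {}
    for name, mask in (("pre", rel_t < 0), ("post", rel_t >= 0)):
        ranks, times = [], []
        sub_t = rel_t[mask]
        for rank in range(aligned.shape[0]):
            row = aligned[rank, mask]
            if row.size == 0:
                continue
            peak = row.max()
            if peak <= 0:
                continue
            hits = np.flatnonzero(row >= threshold * peak)
            if hits.size == 0:
                continue
            ranks.append(rank)
            times.append(sub_t[hits[0]])
        if len(ranks) < 3 or np.ptp(ranks) == 0:
            out[name] = None
            continue
        res = stats.linregress(ranks, times)
        out[name] = RidgeFit(slope=float(res.slope),
                             intercept=float(res.intercept),
                             r2=float(res.rvalue ** 2), n_cells=len(ranks))
    return out
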