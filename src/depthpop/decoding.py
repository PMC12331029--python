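"""Decoders and their evaluation.

The Gaussian naive Bayes classifier is implemented here from the Gaussian
likelihood formula (maximum-likelihood class means/variances, argmax of
prior x product of likelihoods in log space); the k-nearest-neighbor and
random-forest backends come from scikit-learn with pinned settings (k=5
uniform weights; 100 trees grown to purity).

Sign convention for position errors: positive = predicted position closer
to the goal / ahead of the animal.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "GaussianNBModel",
    "gnb_fit",
    "gnb_predict",
    "gnb_log_posterior",
    "decode_depth_by_xbin",
    "calibration_curve",
    "decode_choice_timecourse",
    "decode_position",
    "relative_positions",
    "error_sign_ratio",
    "compare_classifiers",
]


# ---------------------------------------------------------------------------
# Gaussian naive Bayes from the likelihood formula
# ---------------------------------------------------------------------------

@dataclass
class GaussianNBModel:
    classes_: np.ndarray
    priors_: np.ndarray      # P(y), sums to 1
    theta_: np.ndarray       # (classes, features) means
    var_: np.ndarray         # (classes, features) variances, floored


def gnb_fit(X: np.ndarray, y: np.ndarray,
            var_smoothing: float = 1e-9) -> GaussianNBModel:
    """Maximum-likelihood fit: per-class feature means and (biased)
    variances, priors from class counts. Variances are floored by
    ``var_smoothing`` times the largest overall feature variance so that
    zero-variance features stay usable."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    eps = var_smoothing * float(X.var(axis=0).max())
    theta = np.vstack([X[y == c].mean(axis=0) for c in classes])
    var = np.vstack([X[y == c].var(axis=0) for c in classes]) + eps
    return GaussianNBModel(classes_=classes, priors_=counts / y.size,
                           theta_=theta, var_=var)


def gnb_log_posterior(model: GaussianNBModel, X: np.ndarray) -> np.ndarray:
    """Normalized log posteriors, (samples, classes)."""
    X = np.atleast_2d(np.asarray(X, float))
    jll = np.empty((X.shape[0], model.classes_.size))
    for i in range(model.classes_.size):
        ll = -0.5 * np.sum(
            np.log(2.0 * np.pi * model.var_[i])
            + (X - model.theta_[i]) ** 2 / model.var_[i], axis=1)
        jll[:, i] = np.log(model.priors_[i]) + ll
    return jll - logsumexp(jll, axis=1, keepdims=True)


def gnb_predict(model: GaussianNBModel,
                X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and normalized class probabilities."""
    logp = gnb_log_posterior(model, X)
    return model.classes_[np.argmax(logp, axis=1)], np.exp(logp)


class GNBClassifier:
    """Minimal sklearn-style wrapper around the in-repo implementation."""

    def __init__(self, var_smoothing: float = 1e-9):
        self.var_smoothing = var_smoothing

    def fit(self, X, y):
        self.model_ = gnb_fit(X, y, self.var_smoothing)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X):
        return gnb_predict(self.model_, X)[0]

    def predict_proba(self, X):
        return gnb_predict(self.model_, X)[1]


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def _split(n: int, rng: np.random.Generator,
           test_frac: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Sample-wise random 80/20 split."""
    perm = rng.permutation(n)
    n_test = max(int(round(n * test_frac)), 1)
    return perm[n_test:], perm[:n_test]


def _block_split(n: int, rng: np.random.Generator, test_frac: float = 0.2,
                 n_blocks: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous-block 80/20 split: controls temporal leakage between
    overlapping feature windows by assigning whole blocks to one side."""
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    blocks = [np.arange(edges[i], edges[i + 1]) for i in range(n_blocks)]
    order = rng.permutation(n_blocks)
    n_test_blocks = max(int(round(n_blocks * test_frac)), 1)
    te = np.concatenate([blocks[b] for b in order[:n_test_blocks]])
    tr = np.concatenate([blocks[b] for b in order[n_test_blocks:]])
    return np.sort(tr), np.sort(te)


# ---------------------------------------------------------------------------
# depth decoding per X-bin
# ---------------------------------------------------------------------------

def decode_depth_by_xbin(
    features_a: np.ndarray,
    x_a: np.ndarray,
    features_b: np.ndarray,
    x_b: np.ndarray,
    xbin_edges: np.ndarray,
    seed: int = 0,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Per-X-bin GNB accuracy at telling the two sessions (depths) apart.

    ``features_*`` are (samples, cells) rate windows from each session;
    ``x_*`` the animal's X position at each window. Samples are pooled,
    labeled by session, stratified by X bin; each bin gets its own 80/20
    split and accuracy. Bins visited at only one depth (or with too few
    samples) come back nan.
    """
    X = np.vstack([features_a, features_b])
    labels = np.concatenate([np.zeros(len(x_a), int), np.ones(len(x_b), int)])
    xs = np.concatenate([x_a, x_b])
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(xbin_edges) - 1):
        m = (xs >= xbin_edges[i]) & (xs < xbin_edges[i + 1])
        acc = np.nan
        if m.sum() >= min_samples and np.unique(labels[m]).size == 2:
            Xi, yi = X[m], labels[m]
            for _ in range(10):  # redraw if a class misses the train split
                tr, te = _split(len(yi), rng)
                if np.unique(yi[tr]).size == 2 and 1 < np.bincount(yi[tr]).min():
                    break
            else:
                rows.append({"x_lo": xbin_edges[i], "x_hi": xbin_edges[i + 1],
                             "n": int(m.sum()), "accuracy": np.nan})
                continue
            model = gnb_fit(Xi[tr], yi[tr])
            pred, _ = gnb_predict(model, Xi[te])
            acc = float(np.mean(pred == yi[te]))
        rows.append({"x_lo": float(xbin_edges[i]),
                     "x_hi": float(xbin_edges[i + 1]),
                     "n": int(m.sum()), "accuracy": acc})
    return pd.DataFrame(rows)


def calibration_curve(probs: np.ndarray, labels: np.ndarray,
                      n_bins: int = 10) -> pd.DataFrame:
    """Reliability curve: bin positive-class probabilities, return each
    bin's mean predicted probability and observed positive fraction (empty
    bins omitted)."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(probs, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        if not m.any():
            continue
        rows.append({"mean_predicted": float(probs[m].mean()),
                     "observed_fraction": float(np.mean(labels[m] == 1)),
                     "n": int(m.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# choice decoding over trial time
# ---------------------------------------------------------------------------

def decode_choice_timecourse(
    aligned: np.ndarray,
    choices: np.ndarray,
    k: int = 5,
    n_iter: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """kNN (k=5, uniform weights, Euclidean) accuracy of correct-vs-incorrect
    at each trial-aligned time bin, averaged over ``n_iter`` random 80/20
    splits; also returns the peak of the mean accuracy curve."""
    from sklearn.neighbors import KNeighborsClassifier

    aligned = np.asarray(aligned, float)          # (trials, cells, T)
    choices = np.asarray(choices).astype(int)
    n_trials, _, n_t = aligned.shape
    if n_trials < 10:
        raise ValueError("need at least 10 trials")
    counts = np.bincount(choices, minlength=2)
    if counts.min() * 9 < counts.max():
        warnings.warn(
            f"severe class imbalance; chance level {counts.max() / n_trials:.2f}")
    rng = np.random.default_rng(seed)
    acc = np.zeros(n_t)
    for t in range(n_t):
        Xt = aligned[:, :, t]
        vals = []
        for _ in range(n_iter):
            tr, te = _split(n_trials, rng)
            if np.unique(choices[tr]).size < 2:
                continue
            clf = KNeighborsClassifier(
                n_neighbors=min(k, len(tr)), weights="uniform",
                metric="euclidean")
            clf.fit(Xt[tr], choices[tr])
            vals.append(np.mean(clf.predict(Xt[te]) == choices[te]))
        acc[t] = np.mean(vals) if vals else np.nan
    return acc, float(np.nanmax(acc))


# ---------------------------------------------------------------------------
# position decoding
# ---------------------------------------------------------------------------

def _bin_positions(positions: np.ndarray,
                   bin_edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    idx = np.clip(np.digitize(positions, bin_edges) - 1, 0, centers.size - 1)
    return idx, centers


def decode_position(
    features: np.ndarray,
    positions: np.ndarray,
    bin_edges: np.ndarray,
    n_iter: int = 10,
    seed: int = 0,
    direction: np.ndarray | None = None,
    relative: bool = False,
    min_bin_samples: int = 5,
    split: str = "samples",
) -> tuple[pd.DataFrame, dict]:
    """Random-forest position decoding over discretized bins.

    Per iteration ``i`` a fresh sample-wise 80/20 split is drawn and a
    100-tree forest (nodes expanded until pure, >=1 sample per leaf, equal
    sample weights) is fit with ``random_state = seed + i``. The signed
    error is the bin-center difference with positive pointing at the goal:
    for relative (distance-to-goal) positions, ``actual - predicted``; for
    actual positions, ``(predicted - actual) * direction`` when a running
    direction is supplied, else the raw difference.

    Returns a tidy per-test-sample table and a summary with the median
    absolute error and the cumulative |error| fraction curve.
    """
    from sklearn.ensemble import RandomForestClassifier

    features = np.asarray(features, float)
    positions = np.asarray(positions, float)
    cls, centers = _bin_positions(positions, bin_edges)
    counts = np.bincount(cls, minlength=centers.size)
    visited = counts > 0
    if visited.sum() > 1 and counts[visited].min() < min_bin_samples:
        warnings.warn("some visited position bins have very few samples")
    if split not in ("samples", "blocks"):
        raise ValueError("split must be 'samples' or 'blocks'")
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iter):
        if split == "blocks":
            tr, te = _block_split(features.shape[0], rng)
        else:
            tr, te = _split(features.shape[0], rng)
        clf = RandomForestClassifier(
            n_estimators=100, random_state=seed + it, n_jobs=1)
        clf.fit(features[tr], cls[tr])
        proba = clf.predict_proba(features[te])
        pred_cls = clf.classes_[np.argmax(proba, axis=1)]
        pred = centers[pred_cls]
        actual = centers[cls[te]]
        if relative:
            signed = actual - pred
        elif direction is not None:
            signed = (pred - actual) * np.asarray(direction)[te]
        else:
            signed = pred - actual
        rows.append(pd.DataFrame({
            "iteration": it,
            "sample": te,
            "actual": actual,
            "predicted": pred,
            "signed_error": signed,
            "probability": proba.max(axis=1),
        }))
    result = pd.concat(rows, ignore_index=True)
    abs_err = np.abs(result["signed_error"].to_numpy())
    err_grid = np.unique(abs_err)
    cum = np.searchsorted(np.sort(abs_err), err_grid, side="right") / abs_err.size
    summary = {
        "median_abs_error_cm": float(np.median(abs_err)),
        "mean_abs_error_cm": float(np.mean(abs_err)),
        "cumulative_error_cm": err_grid.tolist(),
        "cumulative_fraction": cum.tolist(),
    }
    return result, summary


def relative_positions(
    x: np.ndarray,
    track_length: float,
    speed_eps: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert 1-D track coordinates to distance-remaining-to-goal.

    The goal is the track end the animal is currently heading to (assuming
    constant forward movement within a run); the relative position is 0 at
    the goal regardless of direction. Frames whose direction cannot be
    segmented (dwell at the ends) are flagged invalid.

    Returns
    -------
    rel : distance to goal, cm
    direction : +1 toward ``track_length``, -1 toward 0
    valid : False on unsegmentable dwell frames
    """
    x = np.asarray(x, float)
    dx = np.gradient(x)
    direction = np.sign(dx)
    moving = np.abs(dx) > speed_eps / 50.0  # cm/frame at 50 fps equivalent
    valid = np.ones(x.size, bool)
    nz = np.flatnonzero(direction != 0)
    if nz.size == 0:
        return np.full_like(x, np.nan), np.zeros_like(x), np.zeros(x.size, bool)
    filled = np.interp(np.arange(x.size), nz, direction[nz])
    direction = np.where(filled >= 0, 1.0, -1.0)
    at_end = (x < 1.0) | (x > track_length - 1.0)
    valid = moving | ~at_end
    goal = np.where(direction > 0, track_length, 0.0)
    rel = np.abs(goal - x)
    return rel, direction, valid


def error_sign_ratio(signed_errors: np.ndarray) -> dict:
    """Positive / negative fractions over the nonzero signed errors (zeros
    counted separately); nan fractions when every error is zero."""
    e = np.asarray(signed_errors, float)
    nz = e[e != 0]
    n_zero = int(np.sum(e == 0))
    if nz.size == 0:
        warnings.warn("all decoding errors are zero; sign ratio undefined")
        return {"positive_fraction": np.nan, "negative_fraction": np.nan,
                "n_nonzero": 0, "n_zero": n_zero}
    pos = float(np.mean(nz > 0))
    return {"positive_fraction": pos, "negative_fraction": 1.0 - pos,
            "n_nonzero": int(nz.size), "n_zero": n_zero}


# ---------------------------------------------------------------------------
# classifier roster comparison
# ---------------------------------------------------------------------------

def default_roster(seed: int = 0) -> dict:
    from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
    from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
    from sklearn.gaussian_process import GaussianProcessClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    return {
        "knn": KNeighborsClassifier(n_neighbors=5),
        "svc": SVC(probability=True, random_state=seed),
        "gpc": GaussianProcessClassifier(random_state=seed),
        "mlp": MLPClassifier(max_iter=500, random_state=seed),
        "rfc": RandomForestClassifier(n_estimators=100, random_state=seed),
        "abc": AdaBoostClassifier(random_state=seed),
        "gnb": GNBClassifier(),
        "qda": QuadraticDiscriminantAnalysis(),
    }


def compare_classifiers(
    X: np.ndarray,
    y: np.ndarray,
    roster: dict | None = None,
    seed: int = 0,
    n_prob_bins: int = 10,
) -> dict[str, dict]:
    """Fit every roster classifier on one shared 80/20 split; report test
    accuracy and the calibration curve of the positive class. A classifier
    that raises is recorded as missing and the run continues."""
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    if roster is None:
        roster = default_roster(seed)
    rng = np.random.default_rng(seed)
    tr, te = _split(len(y), rng)
    out: dict[str, dict] = {}
    for name, clf in roster.items():
        try:
            clf.fit(X[tr], y[tr])
            proba = clf.predict_proba(X[te])
            pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
            p1 = proba[:, pos_col]
            pred = clf.classes_[np.argmax(proba, axis=1)]
            out[name] = {
                "accuracy": float(np.mean(pred == y[te])),
                "calibration": calibration_curve(p1, y[te], n_prob_bins),
            }
        except Exception as exc:  # roster member failure is not fatal
            warnings.warn(f"classifier {name} failed: {exc}")
            out[name] = {"accuracy": np.nan, "calibration": None}
    return out
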