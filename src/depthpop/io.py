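"""Readers and writers for the external interchange formats.

Behavior goes to a DeepLabCut-dialect CSV (three header rows:
scorer / bodyparts / coords), neural data to an HDF5 container with
``traces``, ragged ``events``, ``centroids`` and ``timestamps`` datasets,
and metadata / ground truth to JSON sidecars.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import BehaviorTrack, GroundTruth, NeuralSession

BODYPARTS = ("head", "body", "tail")


def write_dlc_csv(track: BehaviorTrack, path: str | Path,
                  scorer: str = "depthpop-sim") -> None:
    n = track.timestamps.size
    lik = track.likelihood
    if lik is None:
        lik = np.ones((n, 3))
    cols = {}
    for j, (part, arr) in enumerate(zip(BODYPARTS,
                                        (track.head, track.body, track.tail))):
        cols[(scorer, part, "x")] = arr[:, 0]
        cols[(scorer, part, "y")] = arr[:, 1]
        cols[(scorer, part, "likelihood")] = lik[:, j]
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["scorer", "bodyparts", "coords"])
    df.to_csv(path, index_label="frame")


def read_dlc_csv(path: str | Path, fps: float = 50.0,
                 min_likelihood: float = 0.9) -> BehaviorTrack:
    """Read a DLC-dialect CSV; frames with keypoint likelihood below
    ``min_likelihood`` are linearly interpolated from their neighbors."""
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    scorer = df.columns.get_level_values(0)[0]
    n = len(df)
    t = np.arange(n) / fps
    parts = []
    lik = np.empty((n, 3))
    for j, part in enumerate(BODYPARTS):
        x = df[(scorer, part, "x")].to_numpy(float)
        y = df[(scorer, part, "y")].to_numpy(float)
        p = df[(scorer, part, "likelihood")].to_numpy(float)
        good = p >= min_likelihood
        if good.any() and not good.all():
            idx = np.arange(n)
            x = np.interp(idx, idx[good], x[good])
            y = np.interp(idx, idx[good], y[good])
        parts.append(np.column_stack([x, y]))
        lik[:, j] = p
    return BehaviorTrack(timestamps=t, head=parts[0], body=parts[1],
                         tail=parts[2], likelihood=lik)


def write_neural_h5(session: NeuralSession, path: str | Path) -> None:
    flat = (np.concatenate(session.events)
            if any(e.size for e in session.events) else np.empty(0))
    offsets = np.cumsum([0] + [e.size for e in session.events])
    with h5py.File(path, "w") as f:
        f.attrs["session_id"] = session.session_id
        f.attrs["kind"] = session.kind
        f.create_dataset("timestamps", data=session.timestamps)
        f.create_dataset("traces", data=session.traces)
        f.create_dataset("events_flat", data=flat)
        f.create_dataset("events_offsets", data=offsets)
        f.create_dataset("footprint_centroids", data=session.centroids)


def read_neural_h5(path: str | Path) -> NeuralSession:
    with h5py.File(path, "r") as f:
        flat = f["events_flat"][()]
        off = f["events_offsets"][()]
        events = [flat[off[i]:off[i + 1]] for i in range(off.size - 1)]
        return NeuralSession(
            session_id=str(f.attrs["session_id"]),
            kind=str(f.attrs["kind"]),
            timestamps=f["timestamps"][()],
            traces=f["traces"][()],
            events=events,
            centroids=f["footprint_centroids"][()],
        )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "cell_class": truth.cell_class.tolist(),
        "cell_params": truth.cell_params.to_dict(orient="list"),
        "trial_info": (None if truth.trial_info is None
                       else truth.trial_info.to_dict(orient="list")),
        "extra": _jsonable(truth.extra),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        cell_class=np.array(payload["cell_class"]),
        cell_params=pd.DataFrame(payload["cell_params"]),
        trial_info=(None if payload["trial_info"] is None
                    else pd.DataFrame(payload["trial_info"])),
        extra=payload["extra"],
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
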