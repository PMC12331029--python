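"""Shared domain types for the depth-coding analysis pipeline.

Arrays are plain numpy; tabular summaries use pandas. All timestamps are in
seconds, positions in cm, footprint centroids in pixels.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

CELL_CLASSES = ("depth_tuned", "choice_tuned", "place", "noise")


class ConfigError(ValueError):
    """Raised when a simulation or analysis configuration is invalid."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters for synthetic session generation.

    Geometry defaults: 60x60 cm open field with a concentric 30 cm center
    square for the cliff arena; a start box plus two arms (20 / 40 cm, the
    long arm rewarded) for the maze; a plain linear track.
    """

    # arena / maze geometry (cm)
    arena_cm: float = 60.0
    center_cm: float = 30.0
    arm_lengths_cm: tuple[float, float] = (20.0, 40.0)
    startbox_cm: float = 10.0
    arm_angle_deg: float = 30.0
    track_length_cm: float = 60.0

    # clocks (Hz)
    behavior_hz: float = 50.0
    imaging_hz: float = 30.0
    duration_s: float = 900.0

    # planted cell counts
    n_depth: int = 10
    n_choice: int = 10
    n_place: int = 10
    n_noise: int = 10

    # tuning parameters
    depth_gain: float = 2.0
    choice_gain: float = 2.0
    place_field_width_cm: float = 6.0
    place_peak_hz: float = 4.0
    direction_selective_fields: bool = True  # linear-track fields per direction
    prospective_lag_cm: float = 0.0
    baseline_rate_hz: float = 2.0

    # calcium kernel
    tau_s: float = 0.5
    trace_noise: float = 0.05

    # behavior dynamics
    run_speed_cms: float = 15.0
    avoid_bias: tuple[float, float] = (0.0, 0.5)  # deep-move rejection (30, 90 cm)
    end_dwell_s: float = 0.5
    decel_zone_cm: float = 10.0   # slowing distance approaching a track goal
    min_speed_frac: float = 0.3   # speed floor inside the deceleration zone

    # maze trials
    n_trials: int = 30
    choice_accuracy: float = 0.8
    dwell_s: tuple[float, float] = (3.0, 6.0)
    ori_block_s: float = 1.0

    # imaging field of view (pixels)
    fov_px: int = 608

    def __post_init__(self) -> None:
        if min(self.arena_cm, self.center_cm, self.track_length_cm,
               self.startbox_cm, *self.arm_lengths_cm) <= 0:
            raise ConfigError("geometry lengths must be > 0")
        if self.center_cm > self.arena_cm:
            raise ConfigError("center square larger than arena")
        if self.duration_s <= 0 or self.behavior_hz <= 0 or self.imaging_hz <= 0:
            raise ConfigError("durations and rates must be > 0")
        if min(self.n_depth, self.n_choice, self.n_place, self.n_noise) < 0:
            raise ConfigError("cell counts must be >= 0")
        if (self.baseline_rate_hz < 0 or self.place_peak_hz < 0
                or self.depth_gain <= 0 or self.choice_gain <= 0):
            raise ConfigError("rates must be >= 0 and gains > 0")
        if self.place_field_width_cm <= 0:
            raise ConfigError("field width must be > 0")
        if self.prospective_lag_cm < 0:
            raise ConfigError("prospective lag must be >= 0")
        if self.tau_s <= 0 or self.trace_noise < 0:
            raise ConfigError("tau must be > 0 and noise >= 0")
        if not (0.0 <= self.choice_accuracy <= 1.0):
            raise ConfigError("choice accuracy must lie in [0, 1]")
        if not all(0.0 <= b <= 1.0 for b in self.avoid_bias):
            raise ConfigError("avoidance bias must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.n_depth + self.n_choice + self.n_place + self.n_noise

    def cell_classes(self) -> np.ndarray:
        return np.array(
            ["depth_tuned"] * self.n_depth + ["choice_tuned"] * self.n_choice
            + ["place"] * self.n_place + ["noise"] * self.n_noise
        )


@dataclass
class NeuralSession:
    """Traces, events, and footprints for one recording."""

    session_id: str
    kind: str  # cliff30 | cliff90 | vslm | linear
    timestamps: np.ndarray          # (frames,) s, strictly increasing
    traces: np.ndarray              # (cells, frames) arbitrary units
    events: list[np.ndarray]        # per-cell sorted event times, s
    centroids: np.ndarray           # (cells, 2) pixels

    def __post_init__(self) -> None:
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.traces.shape != (len(self.events), self.timestamps.size):
            raise ValueError("traces shape must be (cells, frames)")
        if self.centroids.shape[0] != len(self.events):
            raise ValueError("one centroid per cell required")
        lo, hi = self.timestamps[0], self.timestamps[-1]
        for ev in self.events:
            if ev.size and (ev[0] < lo - 1e-9 or ev[-1] > hi + 1e-9):
                raise ValueError("event timestamps outside session span")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]


@dataclass
class BehaviorTrack:
    """Keypoint trajectories on the behavior clock (default 50 Hz)."""

    timestamps: np.ndarray          # (frames,) s
    head: np.ndarray                # (frames, 2) cm
    body: np.ndarray                # (frames, 2) cm
    tail: np.ndarray                # (frames, 2) cm
    likelihood: Optional[np.ndarray] = None  # (frames, 3) DLC confidences

    def __post_init__(self) -> None:
        n = self.timestamps.size
        for arr in (self.head, self.body, self.tail):
            if arr.shape != (n, 2):
                raise ValueError("keypoints must be (frames, 2)")

    @property
    def position(self) -> np.ndarray:
        """Canonical animal position: the body-center keypoint."""
        return self.body

    @property
    def fps(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))


@dataclass
class RateSeries:
    """Sliding-window event rates on a regular grid of window centers."""

    t: np.ndarray                   # (windows,) window centers, s
    rates: np.ndarray               # (cells, windows) events / s
    bin_s: float = 1.0
    step_s: float = 0.2
    z: Optional[np.ndarray] = None  # z-scored rates, filled by zscore()

    def __post_init__(self) -> None:
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")


@dataclass
class Trial:
    index: int
    arm_lengths: tuple[float, float]    # (left, right) cm
    correct_side: str                   # "left" | "right"
    chosen_side: str
    correct: bool
    t_start: float
    t0: Optional[float]                 # junction crossing; None = incomplete
    t_end: float
    ori_t: np.ndarray                   # pre-entry orientation timestamps
    ori: np.ndarray                     # binary: 1 = toward correct arm


@dataclass
class TrialTable:
    trials: list[Trial]

    def __post_init__(self) -> None:
        sides = {"left", "right"}
        for tr in self.trials:
            if tr.correct_side not in sides or tr.chosen_side not in sides:
                raise ValueError("trial sides must be left/right")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "arm_left_cm": [t.arm_lengths[0] for t in self.trials],
                "arm_right_cm": [t.arm_lengths[1] for t in self.trials],
                "correct_side": [t.correct_side for t in self.trials],
                "chosen_side": [t.chosen_side for t in self.trials],
                "correct": [t.correct for t in self.trials],
                "t0": [np.nan if t.t0 is None else t.t0 for t in self.trials],
            }
        )


@dataclass
class RateMap:
    """Occupancy-normalized activity map over spatial bins."""

    bin_edges: tuple[np.ndarray, ...]   # one array per spatial dimension
    activity: np.ndarray                # summed activity * dt per bin
    occupancy: np.ndarray               # seconds per bin
    normalized: np.ndarray              # activity / occupancy, nan when masked
    min_occupancy: float

    @property
    def mask(self) -> np.ndarray:
        """True where the bin has enough occupancy to be trusted."""
        return self.occupancy >= self.min_occupancy


@dataclass
class CellScore:
    """Per-cell selection statistic and its verdict."""

    cell: int
    value: float
    null_mean: float = np.nan
    null_sd: float = np.nan
    null_lo: float = np.nan
    null_hi: float = np.nan
    label: str = "rejected"          # "selected" | "rejected"

    @property
    def selected(self) -> bool:
        return self.label == "selected"


def scores_to_frame(scores: list[CellScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell": [s.cell for s in scores],
            "value": [s.value for s in scores],
            "null_lo": [s.null_lo for s in scores],
            "null_hi": [s.null_hi for s in scores],
            "label": [s.label for s in scores],
        }
    )


@dataclass
class NullDistribution:
    """Shuffle distribution of a statistic with its 95% interval."""

    values: np.ndarray
    seed: int
    lo: float = field(init=False)
    hi: float = field(init=False)

    def __post_init__(self) -> None:
        if self.values.size < 100:
            raise ValueError("need at least 100 shuffles")
        self.lo = float(np.percentile(self.values, 2.5))
        self.hi = float(np.percentile(self.values, 97.5))

    @property
    def n_shuffles(self) -> int:
        return int(self.values.size)

    def outside(self, value: float) -> bool:
        return value < self.lo or value > self.hi


@dataclass
class GroundTruth:
    """Planted cell classes and tuning parameters of a synthetic session."""

    cell_class: np.ndarray          # (cells,) of CELL_CLASSES
    cell_params: pd.DataFrame       # per-cell tuning parameters
    trial_info: Optional[pd.DataFrame] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(np.unique(self.cell_class)) - set(CELL_CLASSES)
        if bad:
            raise ValueError(f"unknown cell classes: {bad}")
        if len(self.cell_params) != self.cell_class.size:
            raise ValueError("one parameter row per cell required")

    def cells_of(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.cell_class == cls)


@dataclass
class Recording:
    """A neural session paired with its behavior track."""

    neural: NeuralSession
    behavior: BehaviorTrack
    trials: Optional[TrialTable] = None
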