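"""Core data records shared across the analysis pipeline.

The containers here are deliberately thin: trials are frame-major numpy
arrays plus metadata, EMG channels are 1-D signals with a sampling rate,
and stimulation epochs are takeoff-referenced time windows. Anything
heavier (DataFrames, model objects) lives in the module that produces it.

Conventions
-----------
* frame indices are 0-based; time windows are half-open ``[start, end)``
* positions are in mm with y increasing upward
* times are in ms relative to takeoff wherever a takeoff frame is set
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: canonical 10-landmark skeleton, nose to tail
CANONICAL_LANDMARKS: tuple[str, ...] = (
    "nose", "ear", "shoulder", "elbow", "forepaw",
    "hip", "knee", "ankle", "hindpaw", "tail_base",
)

PHASES: tuple[str, ...] = ("preparation", "propulsion", "flight", "landing")


@dataclass
class TrialRecording:
    """A tracked-landmark trial: ``positions`` is (T, L, 2) in mm."""

    trial_id: str
    animal_id: str
    frame_rate: float
    landmarks: tuple[str, ...]
    positions: np.ndarray
    confidence: np.ndarray | None = None
    takeoff_frame: int | None = None
    gap_distance: float | None = None
    condition: str = "control"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (T, L, 2)")
        if self.positions.shape[1] != len(self.landmarks):
            raise ValueError("landmark count mismatch with positions")
        if self.confidence is None:
            self.confidence = np.ones(self.positions.shape[:2])
        else:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if np.nanmin(self.confidence) < 0 or np.nanmax(self.confidence) > 1:
                raise ValueError("confidence must lie in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.takeoff_frame is not None and not (
            0 <= self.takeoff_frame < self.n_frames
        ):
            raise ValueError("takeoff_frame out of range")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.positions.shape[1]

    def landmark_index(self, name: str) -> int:
        try:
            return self.landmarks.index(name)  # type: ignore[union-attr]
        except ValueError as err:
            raise KeyError(f"unknown landmark {name!r}") from err

    def landmark(self, name: str) -> np.ndarray:
        """(T, 2) trajectory of a single landmark."""
        return self.positions[:, self.landmark_index(name), :]

    @property
    def relative_time_ms(self) -> np.ndarray | None:
        """Frame times in ms relative to takeoff, if takeoff is set."""
        if self.takeoff_frame is None:
            return None
        frames = np.arange(self.n_frames)
        return (frames - self.takeoff_frame) * 1000.0 / self.frame_rate

    def gap_mask(self) -> np.ndarray:
        """(T, L) boolean mask of frames flagged as gaps (NaN position)."""
        return np.isnan(self.positions).any(axis=2)

    def copy(self, **changes) -> "TrialRecording":
        out = replace(self, **changes)
        if "positions" not in changes:
            out.positions = self.positions.copy()
        if "confidence" not in changes:
            out.confidence = None if self.confidence is None else self.confidence.copy()
        out.metadata = dict(self.metadata)
        return out


@dataclass
class EMGRecording:
    """One muscle channel of a trial, in mV-like units."""

    muscle: str
    role: str  # flexor | extensor | bi-articular
    signal: np.ndarray
    sampling_rate: float
    trial_id: str = ""
    time_offset_ms: float = 0.0  # time of sample 0 relative to takeoff

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("EMG signal must be finite")

    @property
    def time_ms(self) -> np.ndarray:
        """Sample times in ms relative to takeoff."""
        return self.time_offset_ms + np.arange(self.signal.size) * 1000.0 / self.sampling_rate


@dataclass
class StimEpoch:
    """A stimulation window in ms relative to takeoff."""

    onset_ms: float
    duration_ms: float = 50.0
    phase_label: str = "propulsion"

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass
class GroundTruth:
    """Generator-side ground truth attached to a synthetic trial."""

    phase_boundaries: tuple[int, int, int]
    phase_per_frame: np.ndarray
    joint_angles: dict[str, np.ndarray]
    root_path: np.ndarray  # (T, 2) hindpaw trajectory before noise
    control_angles: dict[str, np.ndarray] | None = None
    envelopes: dict[str, np.ndarray] | None = None
    state_sequence: np.ndarray | None = None
    beta: float | None = None
    animal_intercept: float = 0.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        b = tuple(int(x) for x in self.phase_boundaries)
        if not (b[0] < b[1] < b[2]):
            raise ValueError("phase boundaries must be strictly increasing")
        self.phase_boundaries = b  # type: ignore[assignment]
        self.phase_per_frame = np.asarray(self.phase_per_frame)

    def phase_slice(self, phase: str) -> slice:
        b1, b2, b3 = self.phase_boundaries
        t = len(self.phase_per_frame)
        return {
            "preparation": slice(0, b1),
            "propulsion": slice(b1, b2),
            "flight": slice(b2, b3),
            "landing": slice(b3, t),
        }[phase]


@dataclass
class CohortDataset:
    """A collection of synthetic trials with shared ground truth."""

    trials: list[TrialRecording]
    truths: list[GroundTruth]
    emg: list[list[EMGRecording]]
    beta: float
    animal_intercepts: dict[str, float]
    config: object = None

    def __len__(self) -> int:
        return len(self.trials)

    def manifest(self) -> "pd.DataFrame":  # noqa: F821 - imported lazily
        import pandas as pd

        rows = [
            {
                "trial_id": t.trial_id,
                "animal_id": t.animal_id,
                "gap_distance": t.gap_distance,
                "condition": t.condition,
                "n_frames": t.n_frames,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)


def as_xy(point: Sequence[float]) -> np.ndarray:
    return np.asarray(point, dtype=float).reshape(2)
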