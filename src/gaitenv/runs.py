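"""Core signal containers.

Frames
------
Sensor frame (as mounted on the lower back): x points right, y points up
(vertical), z points posterior.  The forward direction is therefore ``-z``.
Anatomical frame: columns ordered (VT, ML, AP) with VT up-positive, ML
right-positive and AP forward-positive.

Sample-index segment intervals are 0-based and half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .errors import SignalError

#: Permutation mapping anatomical (VT, ML, AP) coordinates to ideal sensor
#: (x, y, z) coordinates: x = ML, y = VT, z = -AP.  Proper rotation (det +1).
ANAT_TO_SENSOR = np.array(
    [[0.0, 1.0, 0.0],
     [1.0, 0.0, 0.0],
     [0.0, 0.0, -1.0]]
)

GRAVITY = 9.81  # m/s^2

AXES = ("vt", "ml", "ap")


def _check_segments(segments, n):
    prev_end = 0
    for lo, hi in segments:
        if not (0 <= lo < hi <= n):
            raise SignalError(f"segment ({lo}, {hi}) outside [0, {n})")
        if lo < prev_end:
            raise SignalError("segments overlap or are out of order")
        prev_end = hi


@dataclass
class RawRun:
    """One participant-run of tri-axial sensor-frame acceleration.

    ``samples`` is ``n x 3`` in m/s^2, columns (ax, ay, az) in the sensor
    frame.  ``segments`` lists half-open sample intervals (two legs for the
    out-and-back sidewalk protocol, one for treadmill).
    """

    samples: np.ndarray
    fs_hz: float
    segments: list[tuple[int, int]]
    condition: str
    participant: str
    speed_mps: float
    truth: dict[str, Any] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise SignalError("samples must be n x 3")
        if self.fs_hz <= 0:
            raise SignalError("fs_hz must be positive")
        n = self.samples.shape[0]
        if n < 2 * self.fs_hz:
            raise SignalError("run shorter than 2 s")
        _check_segments(self.segments, n)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def replace(self, **kw) -> "RawRun":
        return replace(self, **kw)


@dataclass
class AlignedSignal:
    """Acceleration in anatomical axes (VT, ML, AP), gravity removed from VT.

    ``rotation_applied`` maps raw sensor samples to the anatomical columns:
    ``aligned = sensor @ rotation_applied.T`` (before gravity subtraction).
    """

    samples: np.ndarray
    fs_hz: float
    segments: list[tuple[int, int]]
    rotation_applied: np.ndarray
    condition: str
    participant: str
    speed_mps: float
    tilt_deg: float = 0.0
    heading_deg: float = 0.0
    status: str = "ok"
    truth: dict[str, Any] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        R = np.asarray(self.rotation_applied, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise SignalError("rotation_applied is not orthonormal")
        _check_segments(self.segments, self.samples.shape[0])

    @property
    def vt(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def ml(self) -> np.ndarray:
        return self.samples[:, 1]

    @property
    def ap(self) -> np.ndarray:
        return self.samples[:, 2]

    def segment_arrays(self) -> list[np.ndarray]:
        return [self.samples[lo:hi] for lo, hi in self.segments]

    def replace(self, **kw) -> "AlignedSignal":
        return replace(self, **kw)


@dataclass
class StepSegmentation:
    """Initial contacts, step/stride durations and the 50-point step matrix.

    ``contacts`` holds one strictly increasing array of global sample indices
    per segment; no step spans a segment boundary.  ``step_matrix`` is
    ``n_steps x n_points x 3`` (anatomical axis order), one row per retained
    step, linearly time-normalized.
    """

    contacts: list[np.ndarray]
    step_durations_s: np.ndarray
    stride_durations_s: np.ndarray
    step_matrix: np.ndarray
    dominant_period_s: float
    fs_hz: float
    n_steps_excluded: int = 0

    @property
    def n_steps(self) -> int:
        return self.step_matrix.shape[0]

    @property
    def step_lag(self) -> int:
        """Mean step duration rounded to the nearest sample."""
        return int(round(float(np.mean(self.step_durations_s)) * self.fs_hz))

    @property
    def stride_lag(self) -> int:
        return int(round(float(np.mean(self.stride_durations_s)) * self.fs_hz))
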