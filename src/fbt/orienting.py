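"""Head-orienting response quantification from overhead marker tracking.

A reflective marker on the head (or on the jacket between the microphone
pockets) is tracked at 60 frames/s for 1 s after stimulus onset. The x-y
stream is reduced to an angle-versus-time series (the bearing of the
per-frame displacement vector relative to the pre-onset heading), from
which two behavioural measures are taken:

* movement latency - the third frame of three consecutive frames that each
  moved in the same direction by at least a threshold after stimulus onset;
* final bearing - the circular mean of the angles in the last three frames
  of the tracked second.

Positive angles are rightward, matching the acoustic sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Per-frame angular change that counts as "movement" for latency detection.
#: The tracking hardware's jitter is well below 1 degree/frame.
DEFAULT_MOVE_THRESHOLD_DEG: float = 1.0

#: Frames used to estimate the pre-onset heading.
HEADING_WINDOW_FRAMES: int = 5

_STATIONARY_EPS: float = 1e-12


@dataclass
class Trajectory:
    """Time-stamped marker coordinates with the stimulus-onset frame."""

    t_s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    onset_index: int
    fps: float = 60.0

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t_s.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have equal length")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        dt = np.diff(self.t_s)
        if np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.fps, rtol=1e-6, atol=1e-9):
            raise ValueError("timestamps must increase in 1/fps steps")
        if not (0 <= self.onset_index < self.t_s.size):
            raise ValueError("onset_index out of range")

    @property
    def n_frames(self) -> int:
        return int(self.t_s.size)


@dataclass(frozen=True)
class OrientingResult:
    """Latency (absent if no qualifying movement) and final bearing."""

    latency_ms: float | None
    final_bearing_deg: float
    direction: str  # "left" / "right" / "none"

    def __post_init__(self) -> None:
        if self.latency_ms is not None and self.latency_ms < 0:
            raise ValueError("latency must be non-negative")
        if abs(self.final_bearing_deg) > 180.0:
            raise ValueError("final bearing must be within +-180 degrees")


def _wrap_deg(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def angles_from_xy(
    traj: Trajectory,
    initial_heading_deg: float | None = None,
) -> np.ndarray:
    """Per-frame bearing of the displacement vector, relative to the initial heading.

    The heading of frame ``i`` is the direction of the displacement
    ``p_i - p_{i-1}``; frames with no displacement hold the previous angle
    (a stationary marker has not turned). Bearings are measured clockwise
    from the arena's 0 degree axis (+y), so positive is rightward.

    When ``initial_heading_deg`` is not given it is estimated as the bearing
    of the mean displacement over the last ``HEADING_WINDOW_FRAMES`` frames
    before onset; a marker that is stationary throughout that window (the
    expected case at the start spout) falls back to the arena's 0 degree axis.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    if initial_heading_deg is None:
        lo = max(0, traj.onset_index - HEADING_WINDOW_FRAMES)
        dx = traj.x[traj.onset_index] - traj.x[lo]
        dy = traj.y[traj.onset_index] - traj.y[lo]
        if np.hypot(dx, dy) <= _STATIONARY_EPS or lo == traj.onset_index:
            initial_heading_deg = 0.0
        else:
            initial_heading_deg = float(np.degrees(np.arctan2(dx, dy)))

    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    moved = np.hypot(dx, dy) > _STATIONARY_EPS
    bearing = np.degrees(np.arctan2(dx, dy))  # clockwise from +y

    angles = np.empty(traj.n_frames)
    angles[0] = 0.0
    prev = 0.0
    for i in range(1, traj.n_frames):
        if moved[i - 1]:
            prev = float(_wrap_deg(bearing[i - 1] - initial_heading_deg))
        angles[i] = prev
    return angles


def detect_latency(
    angles: Sequence[float],
    onset_index: int,
    fps: float = 60.0,
    move_threshold_deg: float = DEFAULT_MOVE_THRESHOLD_DEG,
) -> float | None:
    """Movement latency by the three-consecutive-frames rule, in ms.

    The latency is the third frame of the first run of three frames after
    stimulus onset that each changed by at least ``move_threshold_deg`` in
    the same direction; ``None`` (absent) if no such run exists. Absence is
    a value, not an error - trials without a detectable movement are real.
    """
    a = np.asarray(angles, dtype=float)
    if a.size - onset_index < 4:
        raise ValueError("series must extend at least 3 frames past onset")
    d = np.diff(a)  # d[j] = change into frame j+1
    for k in range(onset_index + 3, a.size):
        window = d[k - 3 : k]  # changes into frames k-2, k-1, k
        if np.all(window >= move_threshold_deg) or np.all(window <= -move_threshold_deg):
            return (k - onset_index) / fps * 1e3
    return None


def final_bearing(angles: Sequence[float]) -> float:
    """Circular (unit-vector) mean of the last three frame angles, degrees.

    The circular mean survives wraparound near +-180; for the modest
    bearings of a head-orienting response it coincides with the arithmetic
    mean.
    """
    a = np.asarray(angles, dtype=float)
    if a.size < 3:
        raise ValueError("need at least three frames")
    last = np.radians(a[-3:])
    return float(
        _wrap_deg(np.degrees(np.arctan2(np.mean(np.sin(last)), np.mean(np.cos(last)))))
    )


def analyze_trajectory(
    traj: Trajectory,
    move_threshold_deg: float = DEFAULT_MOVE_THRESHOLD_DEG,
    initial_heading_deg: float | None = None,
) -> OrientingResult:
    """Full single-trial analysis: angle series, latency, final bearing."""
    angles = angles_from_xy(traj, initial_heading_deg)
    lat = detect_latency(angles, traj.onset_index, traj.fps, move_threshold_deg)
    fb = final_bearing(angles)
    if abs(fb) < 1e-9:
        direction = "none"
    else:
        direction = "right" if fb > 0 else "left"
    return OrientingResult(latency_ms=lat, final_bearing_deg=fb, direction=direction)


def compare_conditions(
    results_a: Sequence[OrientingResult],
    results_b: Sequence[OrientingResult],
) -> tuple[float, float]:
    """Mean latency and bearing differences between two recording conditions.

    Returns ``(mean latency_a - mean latency_b in ms, mean bearing_a - mean
    bearing_b in degrees)``; trials with an absent latency are excluded from
    the latency means.
    """
    if not results_a or not results_b:
        raise ValueError("both condition lists must be non-empty")

    def _mean_latency(results: Sequence[OrientingResult]) -> float:
        lats = [r.latency_ms for r in results if r.latency_ms is not None]
        if not lats:
            raise ValueError("no trials with a detected latency in one condition")
        return float(np.mean(lats))

    def _mean_bearing(results: Sequence[OrientingResult]) -> float:
        return float(np.mean([r.final_bearing_deg for r in results]))

    return (
        _mean_latency(results_a) - _mean_latency(results_b),
        _mean_bearing(results_a) - _mean_bearing(results_b),
    )
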