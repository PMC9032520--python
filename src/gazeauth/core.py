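"""Core data containers for monocular gaze recordings.

Recordings hold gaze angles in degrees sampled at a fixed rate (1000 Hz for
EyeLink-class trackers); blink/track-loss samples are stored as NaN and
exposed through a validity mask.  Screen traces hold the same samples after
projection onto the display, plus per-sample angular speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TASKS = ("FXS", "HSS", "RAN", "TEX")

FIXATION = "fixation"
SACCADE = "saccade"
INVALID = "invalid"


class GazeAuthError(Exception):
    """Base class for gazeauth errors."""


class DegenerateAngleError(GazeAuthError):
    """A gaze angle at or beyond 90 degrees cannot be projected on a screen."""


class TooShortError(GazeAuthError):
    """Recording has too few valid samples for the requested operation."""


class EmptyEventError(GazeAuthError):
    """No classifiable samples in the recording."""


class EmptyWindowError(GazeAuthError):
    """A time window holds no valid samples."""


class FormatError(GazeAuthError):
    """Malformed recording file."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical viewing geometry linking gaze angles to screen pixels.

    Parameters
    ----------
    distance_mm : head-to-screen distance *l*.
    width_mm, height_mm : physical screen size *w*, *h*.
    width_px, height_px : screen resolution.
    """

    distance_mm: float = 550.0
    width_mm: float = 474.0
    height_mm: float = 297.0
    width_px: int = 1680
    height_px: int = 1050

    def __post_init__(self) -> None:
        for name in ("distance_mm", "width_mm", "height_mm", "width_px", "height_px"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ScreenGeometry.{name} must be strictly positive")

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)


@dataclass
class GazeRecording:
    """One subject/session gaze-angle trace.

    ``theta_x``/``theta_y`` are gaze angles in degrees; invalid samples
    (blinks, track loss) are NaN.  ``timestamps`` are milliseconds and must be
    strictly increasing.
    """

    subject_id: str
    task: str
    round: int
    session: int
    timestamps: np.ndarray
    theta_x: np.ndarray
    theta_y: np.ndarray
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.theta_x = np.asarray(self.theta_x, dtype=float)
        self.theta_y = np.asarray(self.theta_y, dtype=float)
        n = len(self.timestamps)
        if len(self.theta_x) != n or len(self.theta_y) != n:
            raise ValueError("timestamps, theta_x, theta_y must have equal length")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def valid(self) -> np.ndarray:
        return ~(np.isnan(self.theta_x) | np.isnan(self.theta_y))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def slice(self, start: int, end: int) -> "GazeRecording":
        """Sub-recording over the half-open sample range [start, end)."""
        return GazeRecording(
            subject_id=self.subject_id,
            task=self.task,
            round=self.round,
            session=self.session,
            timestamps=self.timestamps[start:end],
            theta_x=self.theta_x[start:end],
            theta_y=self.theta_y[start:end],
            sample_rate=self.sample_rate,
        )


@dataclass
class ScreenTrace:
    """Pixel-coordinate view of a recording (origin top-left, y down).

    ``velocity`` is angular speed in deg/s, NaN where undefined (at invalid
    samples or across invalid gaps).  Coordinates may lie off-screen; no
    clipping is applied so off-screen gaze still contributes to distances.
    """

    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    velocity: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.y) == len(self.valid)):
            raise ValueError("x, y, valid must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class EventSegment:
    """A classified eye-movement event over samples [start_idx, end_idx)."""

    kind: str
    start_idx: int
    end_idx: int
    duration_ms: float
    short: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (FIXATION, SACCADE, INVALID):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.start_idx < self.end_idx:
            raise ValueError("start_idx must be < end_idx")

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx


def check_partition(segments: list[EventSegment], n: int) -> None:
    """Assert that segments tile [0, n) without gaps or overlaps."""
    if not segments:
        raise AssertionError("empty segment list")
    if segments[0].start_idx != 0 or segments[-1].end_idx != n:
        raise AssertionError("segments do not span the recording")
    for a, b in zip(segments, segments[1:]):
        if a.end_idx != b.start_idx:
            raise AssertionError("segments are not contiguous")
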