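"""Motion-information (MI) feature: per-step distance and clockwise direction.

Between consecutive gaze points P(i-1) and P(i) the step vector
b = P(i) - P(i-1) is summarized by its length

    L = sqrt(dx^2 + dy^2)

and by the clockwise angle from the reference vector a = (0, 1) to b:

    theta = arccos(a.b / |a||b|)       if dx >= 0
          = 2*pi - arccos(a.b / |a||b|) if dx <  0

giving theta in [0, 2*pi).  The two 1x(n-1) sequences are stacked into a
2x(n-1) matrix, z-scored per channel over the valid entries, and
right-padded with zeros to a fixed length so the convolutional branch sees
a constant input size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FIXATION, EventSegment, ScreenTrace, TooShortError

__all__ = ["MIFeature", "step_distance", "step_direction", "build_mi"]


@dataclass
class MIFeature:
    """2 x (pad_length) channel matrix: row 0 = distance, row 1 = direction."""

    channels: np.ndarray
    valid_length: int

    @property
    def pad_length(self) -> int:
        return self.channels.shape[1]


def step_distance(p_prev, p_next) -> float:
    """Euclidean pixel distance between two gaze points."""
    p_prev = np.asarray(p_prev, dtype=float)
    p_next = np.asarray(p_next, dtype=float)
    return float(np.hypot(*(p_next - p_prev)))


def step_direction(p_prev, p_next) -> float:
    """Clockwise angle in [0, 2*pi) from the reference (0, 1) to the step vector.

    A zero-length step (coincident points) returns 0 by convention.
    """
    dx = float(p_next[0]) - float(p_prev[0])
    dy = float(p_next[1]) - float(p_prev[1])
    norm = np.hypot(dx, dy)
    if norm == 0.0:
        return 0.0
    base = float(np.arccos(np.clip(dy / norm, -1.0, 1.0)))
    theta = base if dx >= 0 else 2.0 * np.pi - base
    return theta % (2.0 * np.pi)


def _steps(x: np.ndarray, y: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (L, theta) over consecutive valid sample pairs.

    Pairs spanning an invalid gap are dropped (motion across a blink is not a
    gaze step).
    """
    ok = valid[:-1] & valid[1:]
    dx = np.diff(x)[ok]
    dy = np.diff(y)[ok]
    L = np.hypot(dx, dy)
    theta = np.zeros_like(L)
    nz = L > 0
    base = np.arccos(np.clip(dy[nz] / L[nz], -1.0, 1.0))
    theta[nz] = np.where(dx[nz] >= 0, base, 2.0 * np.pi - base) % (2.0 * np.pi)
    return L, theta


def zscore(x: np.ndarray) -> np.ndarray:
    """Z-score a channel; a (numerically) constant channel maps to zeros.

    The constancy check is relative: an sd below 1e-9 of the mean magnitude
    is rounding noise, and z-scoring it would blow float residue up to
    unit variance.
    """
    if x.size == 0:
        return np.zeros_like(x)
    sd = x.std()
    if sd <= 1e-9 * max(1.0, abs(float(x.mean()))):
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def build_mi(
    trace: ScreenTrace,
    target_len: int,
    decimate: int = 1,
    fixation_only: bool = False,
    events: list[EventSegment] | None = None,
) -> MIFeature:
    """Build the z-scored 2 x (target_len - 1) MI feature of a screen trace.

    Parameters
    ----------
    target_len
        Nominal sample count of the segment (``duration_s * sample_rate``,
        in decimated samples when ``decimate > 1``); channels are right-padded
        with zeros to ``target_len - 1`` columns.
    decimate
        Keep every ``decimate``-th sample before forming steps (1 = full rate).
    fixation_only
        If True, restrict to samples inside fixation events (``events``
        required); default uses all valid gaze points.
    """
    x, y, valid = trace.x, trace.y, trace.valid.copy()
    if fixation_only:
        if events is None:
            raise ValueError("fixation_only=True requires classified events")
        mask = np.zeros_like(valid)
        for ev in events:
            if ev.kind == FIXATION:
                mask[ev.start_idx : ev.end_idx] = True
        valid = valid & mask
    if decimate > 1:
        x, y, valid = x[::decimate], y[::decimate], valid[::decimate]
    if int(valid.sum()) < 2:
        raise TooShortError("need at least 2 valid samples to build MI")
    L, theta = _steps(x, y, valid)
    n_steps = len(L)
    width = target_len - 1
    if n_steps > width:
        raise ValueError(f"{n_steps} steps exceed target width {width}")
    channels = np.zeros((2, width), dtype=float)
    channels[0, :n_steps] = zscore(L)
    channels[1, :n_steps] = zscore(theta)
    return MIFeature(channels=channels, valid_length=n_steps)
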