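"""Gaze-angle to screen projection, angular velocity, and I-VT event classification.

The projection model places the eye on the screen-center normal at distance
*l*; a gaze angle theta maps to the screen offset l*tan(theta), converted to
pixels by the pixel pitch of each axis:

    x = (l * wpix / w) * tan(theta_x) + wpix / 2
    y = (l * hpix / h) * tan(theta_y) + hpix / 2

Velocity-threshold identification (I-VT) splits samples into fixations
(angular speed below ``fix_thresh``, default 100 deg/s) and saccades (runs of
fast samples whose peak reaches ``sac_peak_thresh``, default 300 deg/s).
Fast runs that never reach the peak threshold are folded back into the
surrounding fixation; invalid (blink) runs become their own segments.
"""

from __future__ import annotations

import numpy as np

from .core import (
    FIXATION,
    INVALID,
    SACCADE,
    DegenerateAngleError,
    EmptyEventError,
    EventSegment,
    GazeRecording,
    ScreenGeometry,
    ScreenTrace,
    TooShortError,
)

__all__ = [
    "angles_to_screen",
    "screen_to_angles",
    "compute_velocity",
    "classify_ivt",
    "extract_blinks",
    "preprocess_recording",
]


def angles_to_screen(rec: GazeRecording, geom: ScreenGeometry) -> ScreenTrace:
    """Project gaze angles (degrees) onto screen pixel coordinates.

    Invalid samples stay NaN.  Raises :class:`DegenerateAngleError` if any
    valid angle magnitude reaches 90 degrees.
    """
    valid = rec.valid
    for name, theta in (("theta_x", rec.theta_x), ("theta_y", rec.theta_y)):
        bad = valid & (np.abs(theta) >= 90.0)
        if np.any(bad):
            idx = int(np.argmax(bad))
            raise DegenerateAngleError(
                f"|{name}| >= 90 deg at sample index {idx} ({theta[idx]:.3f} deg)"
            )
    x = (geom.distance_mm * geom.width_px / geom.width_mm) * np.tan(
        np.radians(rec.theta_x)
    ) + geom.width_px / 2.0
    y = (geom.distance_mm * geom.height_px / geom.height_mm) * np.tan(
        np.radians(rec.theta_y)
    ) + geom.height_px / 2.0
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return ScreenTrace(x=x, y=y, valid=valid.copy())


def screen_to_angles(
    x: np.ndarray, y: np.ndarray, geom: ScreenGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse projection: pixel coordinates back to gaze angles in degrees."""
    tx = np.degrees(
        np.arctan(
            (np.asarray(x) - geom.width_px / 2.0)
            * geom.width_mm
            / (geom.distance_mm * geom.width_px)
        )
    )
    ty = np.degrees(
        np.arctan(
            (np.asarray(y) - geom.height_px / 2.0)
            * geom.height_mm
            / (geom.distance_mm * geom.height_px)
        )
    )
    return tx, ty


def compute_velocity(trace: ScreenTrace, rec: GazeRecording) -> ScreenTrace:
    """Per-sample angular speed (deg/s) from backward differences of gaze angles.

    v[i] combines the x and y angle increments over one sample interval:
    sqrt(dtheta_x^2 + dtheta_y^2) * sample_rate.  Undefined (NaN) where either
    endpoint of the difference is invalid.  The first sample copies the second
    sample's value (boundary convention).
    """
    if int(rec.valid.sum()) < 2:
        raise TooShortError("recording has fewer than 2 valid samples")
    dx = np.diff(rec.theta_x)
    dy = np.diff(rec.theta_y)
    v = np.empty(rec.n_samples, dtype=float)
    v[1:] = np.hypot(dx, dy) * rec.sample_rate
    v[0] = v[1] if rec.n_samples > 1 else np.nan
    return ScreenTrace(x=trace.x, y=trace.y, valid=trace.valid, velocity=v)


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode an integer label array into (label, start, end)."""
    n = len(labels)
    if n == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    return [(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def classify_ivt(
    trace: ScreenTrace,
    sample_rate: float = 1000.0,
    fix_thresh: float = 100.0,
    sac_peak_thresh: float = 300.0,
    min_fix_ms: float = 50.0,
    min_sac_ms: float = 10.0,
) -> list[EventSegment]:
    """I-VT classification into fixation / saccade / invalid segments.

    A contiguous run of samples with speed >= ``fix_thresh`` is a saccade
    candidate, confirmed only if its peak speed reaches ``sac_peak_thresh``;
    unconfirmed candidates merge into the surrounding fixation.  Fixations
    shorter than ``min_fix_ms`` and saccades shorter than ``min_sac_ms`` are
    merged into their longer non-invalid neighbor.  The returned segments
    tile the recording.
    """
    if trace.velocity is None:
        raise ValueError("trace has no velocity; run compute_velocity first")
    if fix_thresh >= sac_peak_thresh:
        raise ValueError("fix_thresh must be < sac_peak_thresh")
    n = trace.n_samples
    valid = trace.valid
    if not np.any(valid):
        raise EmptyEventError("recording contains no valid samples")
    v = trace.velocity

    # 0 = fixation, 1 = saccade candidate, 2 = invalid.  Valid samples with
    # undefined velocity (gap boundaries) default to fixation.
    labels = np.zeros(n, dtype=np.int8)
    fast = valid & np.isfinite(v) & (v >= fix_thresh)
    labels[fast] = 1
    labels[~valid] = 2

    kinds = {0: FIXATION, 1: SACCADE, 2: INVALID}
    raw = []
    for lab, s, e in _runs(labels):
        kind = kinds[lab]
        if kind == SACCADE:
            peak = np.nanmax(v[s:e]) if np.any(np.isfinite(v[s:e])) else 0.0
            if peak < sac_peak_thresh:
                kind = FIXATION  # unconfirmed candidate folds into fixation
        raw.append([kind, s, e])

    def coalesce(segs: list[list]) -> list[list]:
        out: list[list] = []
        for seg in segs:
            if out and out[-1][0] == seg[0]:
                out[-1][2] = seg[2]
            else:
                out.append(seg)
        return out

    segs = coalesce(raw)

    ms = 1000.0 / sample_rate
    min_samples = {FIXATION: min_fix_ms / ms, SACCADE: min_sac_ms / ms}
    # Iteratively relabel too-short movement segments into a non-invalid
    # neighbor (prefer the longer one); terminates because each merge removes
    # a segment.  Short segments walled in by invalid runs are kept.
    while True:
        candidates = [
            i
            for i, (kind, s, e) in enumerate(segs)
            if kind != INVALID and (e - s) < min_samples[kind]
        ]
        merged = False
        for i in sorted(candidates, key=lambda i: segs[i][2] - segs[i][1]):
            neighbors = [
                j for j in (i - 1, i + 1) if 0 <= j < len(segs) and segs[j][0] != INVALID
            ]
            if not neighbors:
                continue
            j = max(neighbors, key=lambda j: segs[j][2] - segs[j][1])
            segs[i][0] = segs[j][0]
            segs = coalesce(segs)
            merged = True
            break
        if not merged:
            break

    return [
        EventSegment(kind=k, start_idx=s, end_idx=e, duration_ms=(e - s) * ms)
        for k, s, e in segs
    ]


def extract_blinks(rec: GazeRecording, min_blink_ms: float = 0.0) -> list[EventSegment]:
    """Maximal runs of invalid (NaN) samples, reported as invalid segments.

    Runs shorter than ``min_blink_ms`` are still reported but flagged
    ``short``.  Default ``min_blink_ms = 0`` reports everything unflagged.
    """
    ms = 1000.0 / rec.sample_rate
    out = []
    for lab, s, e in _runs((~rec.valid).astype(np.int8)):
        if lab != 1:
            continue
        dur = (e - s) * ms
        out.append(
            EventSegment(
                kind=INVALID,
                start_idx=s,
                end_idx=e,
                duration_ms=dur,
                short=dur < min_blink_ms,
            )
        )
    return out


def preprocess_recording(
    rec: GazeRecording, geom: ScreenGeometry, **ivt_kwargs
) -> tuple[ScreenTrace, list[EventSegment]]:
    """Convenience pipeline: project, compute velocity, classify events."""
    trace = angles_to_screen(rec, geom)
    trace = compute_velocity(trace, rec)
    events = classify_ivt(trace, sample_rate=rec.sample_rate, **ivt_kwargs)
    return trace, events
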