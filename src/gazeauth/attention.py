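"""Recording-duration analysis from windowed attention statistics.

During a fixation task the gaze gradually wanders off the stimulus as
attention declines.  Three per-window statistics quantify this:

* distraction distance ``D`` — mean pixel distance between gaze samples and
  the stimulus point ``T``;
* blink fraction ``P`` — fraction of invalid (blink/NaN) samples in the
  window (a per-sample average; the blink-*event* count is also exposed);
* distraction angle ``gamma = arctan(D * h / (hpix * l))`` in degrees —
  ``D`` converted to visual angle via the screen geometry.

A quadratic fit of the across-recording mean gamma versus time gives the
moment the fitted angle reaches the fovea radius (1 degree): past that point
the stimulus leaves the fovea, so longer recordings add distracted, less
identity-rich data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import EmptyWindowError, GazeAuthError, GazeRecording, ScreenGeometry
from .preprocess import angles_to_screen

__all__ = [
    "AttentionWindow",
    "AttentionProfile",
    "distraction_distance",
    "blink_fraction",
    "blink_run_count",
    "distraction_angle",
    "attention_profile",
]

logger = logging.getLogger(__name__)

FOVEA_RADIUS_DEG = 1.0


@dataclass(frozen=True)
class AttentionWindow:
    """Statistics of one 0.5 s analysis window (possibly averaged over recordings)."""

    window_index: int
    t_start: float
    t_end: float
    D: float  # mean pixel distance to stimulus; NaN if no valid sample anywhere
    P: float  # invalid-sample fraction in [0, 1]
    gamma: float  # distraction angle, degrees
    n: int  # valid samples (or recordings contributing, in averaged profiles)


@dataclass
class AttentionProfile:
    """Windowed attention statistics with quadratic trend of gamma over time."""

    windows: list[AttentionWindow]
    fit_coeffs: tuple[float, float, float] | None  # a, b, c of a*t^2 + b*t + c
    crossing_time: float | None  # smallest t >= 0 with fitted gamma >= threshold
    fovea_deg: float = FOVEA_RADIUS_DEG

    def fitted_gamma(self, t: np.ndarray) -> np.ndarray:
        if self.fit_coeffs is None:
            raise GazeAuthError("profile has no quadratic fit (fewer than 3 windows)")
        a, b, c = self.fit_coeffs
        return a * np.asarray(t) ** 2 + b * np.asarray(t) + c


def distraction_distance(points: np.ndarray, target: np.ndarray) -> float:
    """Mean Euclidean pixel distance from each valid gaze point to the target."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    ok = ~np.isnan(pts).any(axis=1)
    if not np.any(ok):
        raise EmptyWindowError("no valid gaze points in window")
    d = np.hypot(*(pts[ok] - np.asarray(target, dtype=float)).T)
    return float(d.mean())


def blink_fraction(valid: np.ndarray) -> float:
    """Invalid-sample fraction of a window (per-sample blink measure)."""
    valid = np.asarray(valid, dtype=bool)
    if valid.size == 0:
        raise EmptyWindowError("empty window")
    return float((~valid).mean())


def blink_run_count(valid: np.ndarray) -> int:
    """Number of maximal invalid runs (blink events) in a window."""
    inv = ~np.asarray(valid, dtype=bool)
    if inv.size == 0:
        raise EmptyWindowError("empty window")
    return int(inv[0]) + int(np.sum(~inv[:-1] & inv[1:]))


def distraction_angle(D: float, geom: ScreenGeometry) -> float:
    """Distraction angle gamma (degrees) for a pixel distance D."""
    if D < 0:
        raise ValueError("D must be nonnegative")
    return float(
        np.degrees(
            np.arctan(D * geom.height_mm / (geom.height_px * geom.distance_mm))
        )
    )


def _crossing_time(coeffs: np.ndarray, level: float) -> float | None:
    """Smallest t >= 0 where the quadratic reaches `level`, or None."""
    a, b, c = (float(v) for v in coeffs)
    if c >= level:  # already at/above the level at t = 0
        return 0.0
    roots = np.roots([a, b, c - level]) if abs(a) > 1e-15 else (
        np.array([(level - c) / b]) if abs(b) > 1e-15 else np.array([])
    )
    real = sorted(float(r.real) for r in roots if abs(r.imag) < 1e-9 and r.real >= 0)
    eps = 1e-6
    for r in real:
        val = a * (r + eps) ** 2 + b * (r + eps) + c
        if val >= level - 1e-12:  # crosses upward (or touches) at r
            return r
    return None


def attention_profile(
    recs: list[GazeRecording],
    geom: ScreenGeometry,
    target: tuple[float, float] | None = None,
    window_s: float = 0.5,
    trim_head_s: float = 1.0,
    keep_s: float = 14.0,
    fovea_deg: float = FOVEA_RADIUS_DEG,
) -> AttentionProfile:
    """Windowed attention profile averaged across fixation-task recordings.

    Each recording drops its first ``trim_head_s`` seconds (orienting
    response), keeps the next ``keep_s`` seconds, and is split into
    non-overlapping ``window_s`` windows (14 s / 0.5 s = 28 windows).  D, P
    and gamma are computed per window, averaged per window index across
    recordings, and the mean gamma is fit with an unweighted least-squares
    quadratic against window-midpoint time (measured from recording start).
    Windows with zero valid samples are excluded from the D/gamma averages
    but contribute P = 1.

    Too-short recordings are skipped with a warning; an error is raised if
    none are usable.
    """
    if target is None:
        target = geom.center_px
    n_windows = int(round(keep_s / window_s))
    D_acc = [[] for _ in range(n_windows)]
    P_acc = [[] for _ in range(n_windows)]
    used = 0
    for rec in recs:
        need = trim_head_s + keep_s
        if rec.duration_s < need - 1e-9:
            logger.warning(
                "skipping recording %s: %.2f s < required %.2f s",
                rec.subject_id,
                rec.duration_s,
                need,
            )
            continue
        trace = angles_to_screen(rec, geom)
        pts = trace.points
        start = int(round(trim_head_s * rec.sample_rate))
        wlen = int(round(window_s * rec.sample_rate))
        for m in range(n_windows):
            w = slice(start + m * wlen, start + (m + 1) * wlen)
            valid = rec.valid[w]
            P_acc[m].append(blink_fraction(valid))
            if np.any(valid):
                D_acc[m].append(distraction_distance(pts[w], target))
        used += 1
    if used == 0:
        raise GazeAuthError("no usable recordings for attention profile")

    windows = []
    for m in range(n_windows):
        t0 = trim_head_s + m * window_s
        D = float(np.mean(D_acc[m])) if D_acc[m] else float("nan")
        gamma = distraction_angle(D, geom) if D_acc[m] else float("nan")
        windows.append(
            AttentionWindow(
                window_index=m,
                t_start=t0,
                t_end=t0 + window_s,
                D=D,
                P=float(np.mean(P_acc[m])),
                gamma=gamma,
                n=len(D_acc[m]),
            )
        )

    good = [w for w in windows if np.isfinite(w.gamma)]
    fit = crossing = None
    if len(good) >= 3:
        t_mid = np.array([(w.t_start + w.t_end) / 2.0 for w in good])
        g = np.array([w.gamma for w in good])
        coeffs = np.polyfit(t_mid, g, 2)
        fit = tuple(float(c) for c in coeffs)
        crossing = _crossing_time(coeffs, fovea_deg)
    return AttentionProfile(
        windows=windows, fit_coeffs=fit, crossing_time=crossing, fovea_deg=fovea_deg
    )
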