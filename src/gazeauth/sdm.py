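"""Saccade distribution map (SDM): where saccade trajectories land on screen.

Saccade trajectories whose bounding box is too small in both directions are
discarded; the remaining saccade samples are accumulated point-by-point onto
a screen-sized count canvas (1680 x 1050 by default), downscaled to 128 x 128
with an exact mass-preserving area resampling, and normalized to sum to 1 so
the map is a spatial probability image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SACCADE, EventSegment, ScreenTrace

__all__ = [
    "SDM",
    "filter_saccade",
    "rasterize_saccades",
    "area_resize",
    "finalize_sdm",
    "build_sdm",
]

SDM_SHAPE = (128, 128)
CANVAS_PX = (1680, 1050)  # width, height


@dataclass
class SDM:
    """Normalized saccade distribution map.

    ``grid`` is (128, 128), nonnegative, and sums to 1 unless no saccade
    survived filtering (then all-zero with ``n_saccades_used = 0``).
    """

    grid: np.ndarray
    n_saccades_used: int
    canvas_px: tuple[int, int] = CANVAS_PX


def filter_saccade(
    traj: np.ndarray, min_extent_px: float = 10.0, drop_if: str = "both_short"
) -> bool:
    """Keep/drop decision for a saccade trajectory by its spatial extent.

    ``drop_if="both_short"`` (default) drops only when both the maximum
    width and the maximum height fall below ``min_extent_px``;
    ``drop_if="either_short"`` drops when either does.  Returns True to keep.
    """
    pts = np.asarray(traj, dtype=float).reshape(-1, 2)
    ok = ~np.isnan(pts).any(axis=1)
    if not np.any(ok):
        return False
    pts = pts[ok]
    width = pts[:, 0].max() - pts[:, 0].min()
    height = pts[:, 1].max() - pts[:, 1].min()
    if drop_if == "both_short":
        return not (width < min_extent_px and height < min_extent_px)
    if drop_if == "either_short":
        return not (width < min_extent_px or height < min_extent_px)
    raise ValueError(f"unknown drop_if mode {drop_if!r}")


def rasterize_saccades(
    events: list[EventSegment],
    trace: ScreenTrace,
    canvas_px: tuple[int, int] = CANVAS_PX,
    min_extent_px: float = 10.0,
    drop_if: str = "both_short",
) -> tuple[np.ndarray, int]:
    """Accumulate kept saccade samples onto one (height, width) count grid.

    Every valid sample of every kept saccade increments its nearest pixel;
    off-canvas samples clip to the border cell.  Returns (counts, n_kept).
    """
    w, h = canvas_px
    counts = np.zeros((h, w), dtype=float)
    n_kept = 0
    for ev in events:
        if ev.kind != SACCADE:
            continue
        pts = trace.points[ev.start_idx : ev.end_idx]
        ok = ~np.isnan(pts).any(axis=1)
        pts = pts[ok]
        if len(pts) == 0 or not filter_saccade(pts, min_extent_px, drop_if):
            continue
        xi = np.clip(np.rint(pts[:, 0]).astype(int), 0, w - 1)
        yi = np.clip(np.rint(pts[:, 1]).astype(int), 0, h - 1)
        np.add.at(counts, (yi, xi), 1.0)
        n_kept += 1
    return counts, n_kept


def area_resize(grid: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Exact area-weighted (mass-preserving) resampling to ``out_shape``.

    Each output cell receives the integral of the piecewise-constant input
    over its (generally fractional) source rectangle, computed from a
    linearly interpolated integral image; total mass is preserved to
    floating-point accuracy for any size ratio.
    """
    H, W = grid.shape
    oh, ow = out_shape
    integral = np.zeros((H + 1, W + 1), dtype=float)
    integral[1:, 1:] = grid.cumsum(axis=0).cumsum(axis=1)
    ys = np.linspace(0.0, H, oh + 1)
    xs = np.linspace(0.0, W, ow + 1)
    # The continuous integral of a piecewise-constant image is bilinear
    # between lattice points, so separable linear interpolation is exact.
    rows = np.empty((oh + 1, W + 1))
    for j in range(W + 1):
        rows[:, j] = np.interp(ys, np.arange(H + 1), integral[:, j])
    corner = np.empty((oh + 1, ow + 1))
    for i in range(oh + 1):
        corner[i, :] = np.interp(xs, np.arange(W + 1), rows[i, :])
    return np.diff(np.diff(corner, axis=0), axis=1)


def finalize_sdm(
    counts: np.ndarray,
    n_saccades_used: int = 0,
    out_shape: tuple[int, int] = SDM_SHAPE,
) -> SDM:
    """Downscale a count canvas and normalize it to a probability image."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("count grid has negative entries")
    small = area_resize(counts, out_shape)
    small = np.clip(small, 0.0, None)  # guard tiny negative rounding residue
    total = small.sum()
    if total == 0:
        return SDM(grid=np.zeros(out_shape), n_saccades_used=0,
                   canvas_px=(counts.shape[1], counts.shape[0]))
    return SDM(grid=small / total, n_saccades_used=n_saccades_used,
               canvas_px=(counts.shape[1], counts.shape[0]))


def build_sdm(
    events: list[EventSegment],
    trace: ScreenTrace,
    canvas_px: tuple[int, int] = CANVAS_PX,
    min_extent_px: float = 10.0,
    drop_if: str = "both_short",
    out_shape: tuple[int, int] = SDM_SHAPE,
    per_saccade_average: bool = False,
) -> SDM:
    """Full SDM pipeline for one recording segment.

    Default accumulates all kept saccades onto one canvas (one map per
    segment, matching the single-image network input).  With
    ``per_saccade_average=True`` each saccade is normalized into its own
    probability image and the images are averaged.
    """
    if not per_saccade_average:
        counts, n_kept = rasterize_saccades(
            events, trace, canvas_px, min_extent_px, drop_if
        )
        return finalize_sdm(counts, n_kept, out_shape)
    grids = []
    for ev in events:
        if ev.kind != SACCADE:
            continue
        counts, n_kept = rasterize_saccades(
            [ev], trace, canvas_px, min_extent_px, drop_if
        )
        if n_kept:
            grids.append(finalize_sdm(counts, n_kept, out_shape).grid)
    if not grids:
        return SDM(grid=np.zeros(out_shape), n_saccades_used=0, canvas_px=canvas_px)
    mean = np.mean(grids, axis=0)
    return SDM(grid=mean / mean.sum(), n_saccades_used=len(grids), canvas_px=canvas_px)
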