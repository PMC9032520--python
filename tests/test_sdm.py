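"""Saccade distribution maps: extent filter, rasterization, mass-preserving resize."""

import numpy as np
import pytest

from gazeauth.core import FIXATION, SACCADE, EventSegment, ScreenTrace
from gazeauth.sdm import (
    area_resize,
    build_sdm,
    filter_saccade,
    finalize_sdm,
    rasterize_saccades,
)


def seg(kind, a, b):
    return EventSegment(kind=kind, start_idx=a, end_idx=b, duration_ms=float(b - a))


def trace_of(pts):
    pts = np.asarray(pts, dtype=float)
    return ScreenTrace(
        x=pts[:, 0], y=pts[:, 1], valid=~np.isnan(pts).any(axis=1)
    )


class TestFilterSaccade:
    def test_single_point_dropped(self):
        assert not filter_saccade(np.array([[10.0, 10.0]]))

    def test_horizontal_sweep_kept(self):
        traj = np.column_stack([np.linspace(0, 200, 50), np.full(50, 7.0)])
        assert filter_saccade(traj)  # 200 px wide, 0 px tall

    def test_jitter_blob_dropped(self, rng):
        traj = rng.uniform(0, 5, size=(30, 2)) + 100.0
        assert not filter_saccade(traj, min_extent_px=10.0)

    def test_either_short_mode(self):
        traj = np.column_stack([np.linspace(0, 200, 50), np.full(50, 7.0)])
        assert not filter_saccade(traj, drop_if="either_short")


class TestRasterize:
    def test_zero_saccades(self):
        tr = trace_of(np.tile([5.0, 5.0], (10, 1)))
        counts, n = rasterize_saccades([seg(FIXATION, 0, 10)], tr)
        assert counts.sum() == 0 and n == 0

    def test_sample_counting(self):
        pts = np.column_stack([np.linspace(100, 400, 30), np.linspace(100, 300, 30)])
        tr = trace_of(pts)
        counts, n = rasterize_saccades([seg(SACCADE, 0, 30)], tr)
        assert counts.sum() == 30 and n == 1

    def test_crossing_saccades_accumulate(self):
        pts = np.vstack(
            [
                np.column_stack([np.linspace(100, 300, 21), np.full(21, 200.0)]),
                np.column_stack([np.full(21, 200.0), np.linspace(100, 300, 21)]),
            ]
        )
        tr = trace_of(pts)
        counts, n = rasterize_saccades([seg(SACCADE, 0, 21), seg(SACCADE, 21, 42)], tr)
        # dictionary-accumulation oracle
        expected = {}
        for x, y in pts:
            key = (int(round(y)), int(round(x)))
            expected[key] = expected.get(key, 0) + 1
        for (yy, xx), c in expected.items():
            assert counts[yy, xx] == c
        assert counts[200, 200] == 2  # shared pixel
        assert counts.sum() == 42 and n == 2

    def test_off_canvas_clipped_to_border(self):
        pts = np.array([[-50.0, -20.0], [2000.0, 1500.0]] * 10)
        tr = trace_of(pts)
        counts, n = rasterize_saccades([seg(SACCADE, 0, 20)], tr)
        assert counts[0, 0] == 10 and counts[1049, 1679] == 10

    def test_translation_equivariance(self, rng):
        pts = rng.uniform(200, 400, size=(40, 2))
        tr1 = trace_of(pts)
        tr2 = trace_of(pts + [100.0, 50.0])
        c1, _ = rasterize_saccades([seg(SACCADE, 0, 40)], tr1)
        c2, _ = rasterize_saccades([seg(SACCADE, 0, 40)], tr2)
        assert np.array_equal(np.roll(np.roll(c1, 50, axis=0), 100, axis=1), c2)


class TestAreaResize:
    def test_mass_preserved_random(self, rng):
        grid = rng.uniform(0, 3, size=(105, 168))
        out = area_resize(grid, (16, 16))
        assert out.sum() == pytest.approx(grid.sum(), rel=1e-12)

    def test_small_canvas_block_oracle(self, rng):
        """16x10 -> 4x4: brute-force fractional pixel-overlap oracle."""
        grid = rng.uniform(0, 5, size=(10, 16))
        out = area_resize(grid, (4, 4))
        oh, ow = 4, 4
        H, W = grid.shape
        expected = np.zeros((oh, ow))
        for i in range(oh):
            for j in range(ow):
                y0, y1 = i * H / oh, (i + 1) * H / oh
                x0, x1 = j * W / ow, (j + 1) * W / ow
                for py in range(H):
                    for px in range(W):
                        oy = max(0.0, min(y1, py + 1) - max(y0, py))
                        ox = max(0.0, min(x1, px + 1) - max(x0, px))
                        expected[i, j] += grid[py, px] * oy * ox
        assert np.allclose(out, expected, atol=1e-10)


class TestFinalize:
    def test_sums_to_one(self, rng):
        counts = np.zeros((1050, 1680))
        idx = rng.integers(0, 1000, size=(200, 2))
        np.add.at(counts, (idx[:, 0], idx[:, 1]), 1.0)
        sdm = finalize_sdm(counts, n_saccades_used=3)
        assert sdm.grid.shape == (128, 128)
        assert sdm.grid.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(sdm.grid >= 0)

    def test_uniform_grid(self):
        sdm = finalize_sdm(np.ones((1050, 1680)), n_saccades_used=1)
        assert np.allclose(sdm.grid, 1.0 / (128 * 128), atol=1e-12)

    def test_zero_input(self):
        sdm = finalize_sdm(np.zeros((1050, 1680)))
        assert np.all(sdm.grid == 0) and sdm.n_saccades_used == 0

    def test_negative_raises(self):
        grid = np.zeros((10, 10))
        grid[3, 3] = -1
        with pytest.raises(ValueError):
            finalize_sdm(grid)


class TestBuildSDM:
    def _events_trace(self, rng):
        pts = np.vstack(
            [
                np.tile([500.0, 500.0], (50, 1)),
                np.column_stack(
                    [np.linspace(500, 900, 30), np.linspace(500, 300, 30)]
                ),
                np.tile([900.0, 300.0], (50, 1)),
            ]
        )
        events = [
            seg(FIXATION, 0, 50),
            seg(SACCADE, 50, 80),
            seg(FIXATION, 80, 130),
        ]
        return events, trace_of(pts)

    def test_accumulated_map(self, rng):
        events, tr = self._events_trace(rng)
        sdm = build_sdm(events, tr)
        assert sdm.n_saccades_used == 1
        assert sdm.grid.sum() == pytest.approx(1.0, abs=1e-9)

    def test_per_saccade_average_mode(self, rng):
        events, tr = self._events_trace(rng)
        sdm = build_sdm(events, tr, per_saccade_average=True)
        assert sdm.grid.sum() == pytest.approx(1.0, abs=1e-9)
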