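"""Screen projection, angular velocity, and I-VT classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazeauth.core import (
    FIXATION,
    INVALID,
    SACCADE,
    DegenerateAngleError,
    EmptyEventError,
    ScreenGeometry,
    TooShortError,
    check_partition,
)
from gazeauth.preprocess import (
    angles_to_screen,
    classify_ivt,
    compute_velocity,
    extract_blinks,
    screen_to_angles,
)

from conftest import make_recording


class TestAnglesToScreen:
    def test_zero_angle_maps_to_center(self, geom):
        rec = make_recording([0.0], [0.0])
        tr = angles_to_screen(rec, geom)
        assert tr.x[0] == pytest.approx(840.0)
        assert tr.y[0] == pytest.approx(525.0)

    def test_ten_degrees_horizontal(self, geom):
        # (550*1680/474)*tan(10 deg) + 840
        rec = make_recording([10.0], [0.0])
        tr = angles_to_screen(rec, geom)
        expected = (550 * 1680 / 474) * np.tan(np.radians(10.0)) + 840
        assert tr.x[0] == pytest.approx(expected)
        assert tr.x[0] == pytest.approx(1183.7, abs=0.1)

    def test_vertical_symmetry(self, geom):
        rec = make_recording([0.0, 0.0], [7.5, -7.5])
        tr = angles_to_screen(rec, geom)
        assert tr.y[0] - 525.0 == pytest.approx(-(tr.y[1] - 525.0))

    def test_invalid_stays_invalid(self, geom):
        rec = make_recording([0.0, np.nan], [0.0, 0.0])
        tr = angles_to_screen(rec, geom)
        assert np.isnan(tr.x[1]) and not tr.valid[1]

    def test_degenerate_angle_names_index(self, geom):
        rec = make_recording([0.0, 0.0, 92.0], [0.0, 0.0, 0.0])
        with pytest.raises(DegenerateAngleError, match="index 2"):
            angles_to_screen(rec, geom)

    @given(
        theta=st.floats(-59.9, 59.9),
        axis=st.sampled_from(["x", "y"]),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip(self, theta, axis):
        geom = ScreenGeometry()
        tx, ty = (theta, 0.0) if axis == "x" else (0.0, theta)
        rec = make_recording([tx], [ty])
        tr = angles_to_screen(rec, geom)
        bx, by = screen_to_angles(tr.x, tr.y, geom)
        assert abs(bx[0] - tx) < 1e-9
        assert abs(by[0] - ty) < 1e-9


class TestVelocity:
    def test_constant_angles_zero_velocity(self, geom):
        rec = make_recording(np.full(100, 3.0), np.full(100, -2.0))
        tr = compute_velocity(angles_to_screen(rec, geom), rec)
        assert np.allclose(tr.velocity, 0.0)

    def test_linear_ramp(self, geom):
        rec = make_recording(np.arange(50) * 0.35, np.zeros(50))
        tr = compute_velocity(angles_to_screen(rec, geom), rec)
        assert np.allclose(tr.velocity, 350.0)

    def test_euclidean_combination(self, geom):
        rec = make_recording(np.arange(20) * 0.3, np.arange(20) * 0.3)
        tr = compute_velocity(angles_to_screen(rec, geom), rec)
        assert np.allclose(tr.velocity, np.hypot(0.3, 0.3) * 1000.0)
        assert tr.velocity[5] == pytest.approx(424.26, abs=0.01)

    def test_offset_invariance(self, geom, rng):
        tx = np.cumsum(rng.normal(0, 0.01, 200))
        ty = np.cumsum(rng.normal(0, 0.01, 200))
        v1 = compute_velocity(
            angles_to_screen(make_recording(tx, ty), geom), make_recording(tx, ty)
        ).velocity
        v2 = compute_velocity(
            angles_to_screen(make_recording(tx + 3, ty - 2), geom),
            make_recording(tx + 3, ty - 2),
        ).velocity
        assert np.allclose(v1, v2)

    def test_too_short(self, geom):
        rec = make_recording([0.0, np.nan], [0.0, np.nan])
        with pytest.raises(TooShortError):
            compute_velocity(angles_to_screen(rec, geom), rec)

    def test_undefined_across_gap_and_first_copies_second(self, geom):
        rec = make_recording([0, 0.1, np.nan, 0.3, 0.31], [0, 0, np.nan, 0, 0])
        tr = compute_velocity(angles_to_screen(rec, geom), rec)
        assert np.isnan(tr.velocity[2]) and np.isnan(tr.velocity[3])
        assert tr.velocity[0] == tr.velocity[1]


def _trace(geom, tx, ty):
    rec = make_recording(tx, ty)
    return compute_velocity(angles_to_screen(rec, geom), rec), rec


class TestClassifyIVT:
    def test_quiet_trace_single_fixation(self, geom):
        tx = np.cumsum(np.full(500, 0.01))  # 10 deg/s
        tr, _ = _trace(geom, tx, np.zeros(500))
        events = classify_ivt(tr)
        assert len(events) == 1 and events[0].kind == FIXATION
        check_partition(events, 500)

    def test_burst_gives_three_segments(self, geom):
        # 40 ms burst peaking 400 deg/s between two quiet spans
        tx = np.zeros(500)
        burst = 0.4 * np.sin(np.linspace(0, np.pi, 40))  # deg/ms rates
        tx[200:240] = np.cumsum(burst)
        tx[240:] = tx[239]
        tr, _ = _trace(geom, tx, np.zeros(500))
        events = classify_ivt(tr)
        kinds = [e.kind for e in events]
        assert kinds == [FIXATION, SACCADE, FIXATION]
        check_partition(events, 500)

    def test_unconfirmed_burst_merges_into_fixation(self, geom):
        # peaks at 150 deg/s: above fix threshold, below saccade peak threshold
        tx = np.zeros(500)
        burst = 0.15 * np.sin(np.linspace(0, np.pi, 40))
        tx[200:240] = np.cumsum(burst)
        tx[240:] = tx[239]
        tr, _ = _trace(geom, tx, np.zeros(500))
        events = classify_ivt(tr)
        assert all(e.kind != SACCADE for e in events)
        assert len(events) == 1

    def test_all_invalid_raises(self, geom):
        rec = make_recording([0.0, 0.1, np.nan, np.nan], [0.0] * 2 + [np.nan] * 2)
        tr = compute_velocity(angles_to_screen(rec, geom), rec)
        tr.valid[:] = False
        with pytest.raises(EmptyEventError):
            classify_ivt(tr)

    def test_partition_property_randomized(self, geom, rng):
        """Segments tile [0, n) over many random traces with blinks."""
        for _ in range(200):
            n = int(rng.integers(20, 200))
            tx = np.cumsum(rng.normal(0, 0.2, n))
            ty = np.cumsum(rng.normal(0, 0.2, n))
            if rng.random() < 0.5:
                a = int(rng.integers(0, n - 1))
                b = int(rng.integers(a + 1, n))
                tx[a:b] = np.nan
            rec = make_recording(tx, ty)
            if rec.valid.sum() < 2:
                continue
            tr = compute_velocity(angles_to_screen(rec, geom), rec)
            events = classify_ivt(tr)
            check_partition(events, n)

    def test_agrees_with_brute_force_oracle(self, geom, rng):
        """Away from duration limits, classification equals per-sample
        thresholding: fixation run iff all speeds < 100, saccade run iff
        >= 100 with peak >= 300."""
        for _ in range(30):
            # long quiet spans with long, clearly fast bursts
            pieces = []
            for k in range(4):
                pieces.append(np.full(int(rng.integers(80, 200)), rng.uniform(0, 0.05)))
                pieces.append(np.full(int(rng.integers(15, 40)), rng.uniform(0.35, 0.6)))
            pieces.append(np.full(int(rng.integers(80, 200)), rng.uniform(0, 0.05)))
            rates = np.concatenate(pieces)
            tx = np.cumsum(rates)
            tr, rec = _trace(geom, tx, np.zeros_like(tx))
            events = classify_ivt(tr)
            v = tr.velocity
            labels = np.where(v >= 100.0, SACCADE, FIXATION)
            for ev in events:
                assert all(labels[ev.start_idx : ev.end_idx] == ev.kind)

    def test_short_fixation_merged(self, geom):
        """A 20 ms quiet gap between two confirmed saccades is absorbed."""
        rates = np.concatenate(
            [np.full(100, 0.01), np.full(30, 0.45), np.full(20, 0.01),
             np.full(30, 0.45), np.full(100, 0.01)]
        )
        tr, _ = _trace(geom, np.cumsum(rates), np.zeros(280))
        events = classify_ivt(tr)
        sacs = [e for e in events if e.kind == SACCADE]
        assert len(sacs) == 1  # merged through the short fixation
        assert sacs[0].n_samples >= 80


class TestExtractBlinks:
    def test_no_invalid(self):
        rec = make_recording(np.zeros(50), np.zeros(50))
        assert extract_blinks(rec) == []

    def test_two_runs(self):
        tx = np.zeros(300)
        tx[10:60] = np.nan
        tx[200:220] = np.nan
        rec = make_recording(tx, np.zeros(300))
        runs = extract_blinks(rec)
        assert [(r.start_idx, r.end_idx) for r in runs] == [(10, 60), (200, 220)]
        assert all(r.kind == INVALID for r in runs)

    def test_fully_invalid(self):
        rec = make_recording(np.full(40, np.nan), np.full(40, np.nan))
        runs = extract_blinks(rec)
        assert len(runs) == 1 and runs[0].n_samples == 40

    def test_short_flagging(self):
        tx = np.zeros(100)
        tx[10:15] = np.nan  # 5 ms
        tx[50:90] = np.nan  # 40 ms
        rec = make_recording(tx, np.zeros(100))
        runs = extract_blinks(rec, min_blink_ms=20.0)
        assert [r.short for r in runs] == [True, False]
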