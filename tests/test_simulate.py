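"""Synthetic gaze simulator: stimulus scripts, kinematics, reproducibility."""

import numpy as np
import pytest

from gazeauth.core import SACCADE, ScreenGeometry
from gazeauth.preprocess import preprocess_recording
from gazeauth.simulate import (
    SubjectParams,
    make_stimulus,
    simulate_cohort,
    simulate_recording,
    well_separated_params,
)


class TestMakeStimulus:
    def test_fxs_single_center_target(self, geom):
        s = make_stimulus("FXS", 15.0, geom)
        assert len(s.entries) == 1
        assert s.entries[0][:2] == geom.center_px

    def test_hss_alternation(self, geom):
        s = make_stimulus("HSS", 10.0, geom, cadence_s=1.0)
        assert len(s.entries) == 10
        ys = {e[1] for e in s.entries}
        assert len(ys) == 1  # constant y
        xs = [e[0] for e in s.entries]
        assert all(a != b for a, b in zip(xs, xs[1:]))  # alternating
        assert len(set(xs)) == 2

    def test_ran_reproducible(self, geom):
        s1 = make_stimulus("RAN", 10.0, geom, seed=7)
        s2 = make_stimulus("RAN", 10.0, geom, seed=7)
        assert s1.entries == s2.entries
        s3 = make_stimulus("RAN", 10.0, geom, seed=8)
        assert s1.entries != s3.entries

    def test_tex_targets_on_screen(self, geom):
        s = make_stimulus("TEX", 20.0, geom, seed=0)
        for x, y, *_ in s.entries:
            assert 0 <= x <= geom.width_px and 0 <= y <= geom.height_px

    def test_unknown_task_raises(self, geom):
        with pytest.raises(ValueError):
            make_stimulus("XYZ", 5.0, geom)


class TestSimulateRecording:
    def test_noiseless_fixation_is_constant(self, geom):
        sp = SubjectParams(tremor_sd=0.0, blink_rate=0.0)
        rec = simulate_recording(make_stimulus("FXS", 5.0, geom), sp, geom)
        assert np.ptp(rec.theta_x) == 0.0 and np.ptp(rec.theta_y) == 0.0
        _, events = preprocess_recording(rec, geom)
        assert len(events) == 1 and events[0].kind == "fixation"

    def test_saccade_count_round_trip(self, geom):
        """I-VT recovers the script's target transitions within +/-1."""
        for seed in range(20):
            sp = SubjectParams(tremor_sd=0.03, blink_rate=0.0, seed=seed)
            script = make_stimulus("HSS", 10.0, geom, cadence_s=1.0)
            rec = simulate_recording(script, sp, geom)
            _, events = preprocess_recording(rec, geom)
            n_sac = sum(e.kind == SACCADE for e in events)
            assert abs(n_sac - 9) <= 1

    def test_fixation_velocity_mass_below_threshold(self, geom):
        """>= 99% of fixation-classified sample speeds below 100 deg/s when
        tremor_sd <= 0.1 deg."""
        sp = SubjectParams(tremor_sd=0.1, blink_rate=0.0, seed=3)
        rec = simulate_recording(make_stimulus("FXS", 10.0, geom), sp, geom)
        tr, events = preprocess_recording(rec, geom)
        mask = np.zeros(rec.n_samples, bool)
        for e in events:
            if e.kind == "fixation":
                mask[e.start_idx : e.end_idx] = True
        v = tr.velocity[mask & np.isfinite(tr.velocity)]
        assert (v < 100.0).mean() >= 0.99

    def test_saccade_peak_velocity_above_300(self, geom):
        """Saccades of >= 2 deg amplitude exceed the 300 deg/s peak threshold."""
        for amp in (2.0, 5.0, 12.0):
            sp = SubjectParams(tremor_sd=0.0, blink_rate=0.0, saccade_vpeak_scale=0.9)
            script = make_stimulus("HSS", 6.0, geom, hss_amplitude_deg=amp)
            rec = simulate_recording(script, sp, geom)
            v = np.hypot(np.diff(rec.theta_x), np.diff(rec.theta_y)) * 1000.0
            assert np.nanmax(v) >= 300.0

    def test_blink_count_poisson(self, geom):
        """Blink events over long simulations match the Poisson rate within
        3 standard errors."""
        from gazeauth.preprocess import extract_blinks

        rate = 20.0  # per minute
        total = 0
        n_rec, dur = 12, 30.0
        for seed in range(n_rec):
            sp = SubjectParams(tremor_sd=0.0, blink_rate=rate, seed=100 + seed)
            rec = simulate_recording(make_stimulus("FXS", dur, geom), sp, geom)
            total += len(extract_blinks(rec))
        lam = rate * dur / 60.0 * n_rec
        assert abs(total - lam) <= 3.0 * np.sqrt(lam)

    def test_attention_drift_mean_gamma(self, geom):
        """Mean offset angle tracks the prescribed law."""
        law = lambda t: t**2 / 144.0  # noqa: E731
        offsets = []
        for i in range(40):
            sp = SubjectParams(tremor_sd=0.0, blink_rate=0.0, seed=i)
            rec = simulate_recording(
                make_stimulus("FXS", 15.0, geom), sp, geom, attention_drift=law
            )
            offsets.append(np.hypot(rec.theta_x, rec.theta_y))
        mean_off = np.mean(offsets, axis=0)
        t = np.arange(len(mean_off)) / 1000.0
        i12 = 12000
        assert mean_off[i12] == pytest.approx(law(t[i12]), rel=0.25)

    def test_reproducibility(self, geom):
        sp = SubjectParams(tremor_sd=0.05, blink_rate=10.0, seed=42)
        script = make_stimulus("HSS", 5.0, geom)
        r1 = simulate_recording(script, sp, geom)
        r2 = simulate_recording(script, sp, geom)
        assert np.array_equal(r1.theta_x, r2.theta_x, equal_nan=True)

    def test_identical_params_identical_recordings(self, geom):
        sp1 = SubjectParams(tremor_sd=0.05, seed=9)
        sp2 = SubjectParams(tremor_sd=0.05, seed=9)
        script = make_stimulus("RAN", 4.0, geom, seed=1)
        r1 = simulate_recording(script, sp1, geom)
        r2 = simulate_recording(script, sp2, geom)
        assert np.array_equal(r1.theta_x, r2.theta_x, equal_nan=True)

    def test_negative_param_rejected(self):
        with pytest.raises(ValueError):
            SubjectParams(tremor_sd=-0.1)


class TestCohort:
    def test_round_structure_counts(self, geom, tmp_path):
        # 31 subjects x 8 rounds x 2 sessions x 1 task = 496 recordings
        # (structural match with the test cohort; short recordings for speed)
        manifest = simulate_cohort(
            tmp_path / "cohort", n_subjects=31, tasks=("HSS",), rounds=8,
            sessions=2, duration_s=1.0, geom=geom, master_seed=5,
        )
        assert len(manifest.recordings) == 496
        assert len(manifest.subjects()) == 31

    def test_same_seed_byte_identical_manifests(self, geom, tmp_path):
        m1 = simulate_cohort(tmp_path / "a", 2, rounds=1, sessions=1,
                             duration_s=1.0, geom=geom, master_seed=3)
        m2 = simulate_cohort(tmp_path / "b", 2, rounds=1, sessions=1,
                             duration_s=1.0, geom=geom, master_seed=3)
        j1 = (tmp_path / "a" / "manifest.json").read_text()
        j2 = (tmp_path / "b" / "manifest.json").read_text()
        assert j1.replace(str(tmp_path / "a"), "") == j2.replace(str(tmp_path / "b"), "")

    def test_well_separated_params_deterministic(self):
        p1 = well_separated_params(10, master_seed=1)
        p2 = well_separated_params(10, master_seed=1)
        assert p1 == p2
        tremors = sorted(p.tremor_sd for p in p1)
        assert tremors[0] == pytest.approx(0.02) and tremors[-1] == pytest.approx(0.2)
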