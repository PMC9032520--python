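"""Synthetic 1000 Hz gaze recordings with per-subject oculomotor signatures.

Fixations are the stimulus position plus low-pass-filtered tremor (a 50 ms
moving average of white noise, rescaled to the subject's tremor amplitude;
unfiltered 1000 Hz white noise would produce sample-to-sample velocities far
above the 100 deg/s fixation threshold).  Saccades follow a minimum-jerk
position profile whose peak velocity scales with amplitude (a main-sequence
style relationship) and is kept above the 300 deg/s detection threshold for
amplitudes of 2 degrees or more.  Blinks are Poisson events that replace
samples with NaN.  Identity enters through tremor amplitude, peak-velocity
scaling, saccade curvature, latency, and blink statistics, so both the
motion-information and saccade-distribution features carry subject signal.

An optional attention-drift process for fixation tasks makes the gaze wander
off the target so that the expected distraction angle follows a prescribed
law gamma(t): the offset is a 2-D Brownian path rescaled so
E[|offset|](t) = gamma(t) exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import TASKS, GazeRecording, ScreenGeometry
from .preprocess import screen_to_angles

__all__ = [
    "SubjectParams",
    "StimulusScript",
    "make_stimulus",
    "simulate_recording",
    "draw_subject_params",
    "well_separated_params",
    "simulate_cohort",
]

TREMOR_SMOOTH_MS = 50.0
MIN_JERK_PEAK = 1.875  # peak of the minimum-jerk velocity profile, x A/T


@dataclass
class SubjectParams:
    """Oculomotor signature of one synthetic subject."""

    tremor_sd: float = 0.05  # fixation noise amplitude, deg
    drift_rate: float = 0.0  # slow ocular drift scale, deg/sqrt(s)
    saccade_vpeak_scale: float = 1.0  # main-sequence peak-velocity multiplier
    saccade_curvature: float = 0.1  # lateral deviation scale (fraction of amplitude)
    blink_rate: float = 10.0  # events per minute
    blink_dur_ms: float = 150.0  # mean blink duration
    latency_ms: float = 180.0  # stimulus-to-saccade delay
    seed: int = 0

    def __post_init__(self):
        for name in (
            "tremor_sd", "drift_rate", "saccade_vpeak_scale",
            "saccade_curvature", "blink_rate", "blink_dur_ms", "latency_ms",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"SubjectParams.{name} must be nonnegative")


@dataclass
class StimulusScript:
    """Sequence of screen targets: (x_px, y_px, onset_s, duration_s)."""

    task: str
    entries: list[tuple[float, float, float, float]]

    def __post_init__(self):
        onsets = [e[2] for e in self.entries]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be increasing")

    @property
    def duration_s(self) -> float:
        last = self.entries[-1]
        return last[2] + last[3]


def make_stimulus(
    task: str,
    duration_s: float,
    geom: ScreenGeometry,
    seed: int = 0,
    cadence_s: float = 1.0,
    hss_amplitude_deg: float = 10.0,
) -> StimulusScript:
    """Target sequence for one of the four recording tasks.

    FXS: a single center dot.  HSS: alternation between two horizontally
    separated points (``hss_amplitude_deg`` apart) at fixed cadence.  RAN:
    uniform-random on-screen jumps at fixed cadence.  TEX: reading-like
    left-to-right, top-to-bottom sweep with occasional regressions.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    rng = np.random.default_rng(seed)
    cx, cy = geom.center_px
    entries: list[tuple[float, float, float, float]] = []
    if task == "FXS":
        entries = [(cx, cy, 0.0, duration_s)]
    elif task == "HSS":
        half = np.radians(hss_amplitude_deg / 2.0)
        dx = geom.distance_mm * geom.width_px / geom.width_mm * np.tan(half)
        t = 0.0
        side = 0
        while t < duration_s:
            entries.append(
                (cx + (dx if side else -dx), cy, t, min(cadence_s, duration_s - t))
            )
            side ^= 1
            t += cadence_s
    elif task == "RAN":
        t = 0.0
        while t < duration_s:
            x = rng.uniform(0.1 * geom.width_px, 0.9 * geom.width_px)
            y = rng.uniform(0.1 * geom.height_px, 0.9 * geom.height_px)
            entries.append((x, y, t, min(cadence_s, duration_s - t)))
            t += cadence_s
    else:  # TEX
        dwell = 0.25
        n_lines = 8
        xs = np.linspace(0.1 * geom.width_px, 0.9 * geom.width_px, 12)
        ys = np.linspace(0.2 * geom.height_px, 0.8 * geom.height_px, n_lines)
        t, line, col = 0.0, 0, 0
        while t < duration_s:
            entries.append((xs[col], ys[line % n_lines], t, min(dwell, duration_s - t)))
            if rng.random() < 0.08 and col >= 2:
                col -= 2  # regression
            else:
                col += 1
                if col >= len(xs):
                    col = 0
                    line += 1
            t += dwell
    return StimulusScript(task=task, entries=entries)


def _main_sequence_vpeak(amplitude_deg: float, scale: float) -> float:
    """Amplitude-dependent peak velocity (deg/s), floored so saccades of
    >= 2 deg always exceed the 300 deg/s detection threshold."""
    v = scale * (270.0 + 45.0 * amplitude_deg)
    if amplitude_deg >= 2.0:
        v = max(v, 330.0)
    return v


def simulate_recording(
    script: StimulusScript,
    params: SubjectParams,
    geom: ScreenGeometry,
    subject_id: str = "S000",
    round: int = 1,
    session: int = 1,
    sample_rate: float = 1000.0,
    duration_s: float | None = None,
    attention_drift: Callable[[np.ndarray], np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> GazeRecording:
    """Simulate one recording of a subject following a stimulus script.

    ``attention_drift`` is an optional gamma(t) law in degrees (t in seconds
    from recording start); the gaze then wanders off the target so that the
    expected offset angle follows the law.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    dur = duration_s if duration_s is not None else script.duration_s
    n = int(round_half_up(dur * sample_rate))
    dt = 1.0 / sample_rate

    # stimulus targets in gaze-angle space
    ex = np.array([e[0] for e in script.entries])
    ey = np.array([e[1] for e in script.entries])
    tax, tay = screen_to_angles(ex, ey, geom)
    onsets = np.array([e[2] for e in script.entries])

    tx = np.empty(n)
    ty = np.empty(n)
    cur = np.array([tax[0], tay[0]])
    cursor = 0
    for k in range(1, len(script.entries)):
        delta = np.array([tax[k], tay[k]]) - cur
        amp = float(np.hypot(*delta))
        latency = params.latency_ms / 1000.0 + max(0.0, rng.normal(0.0, 0.010))
        start = int((onsets[k] + latency) * sample_rate)
        start = max(start, cursor)
        if start >= n:
            break
        tx[cursor:start] = cur[0]
        ty[cursor:start] = cur[1]
        if amp == 0.0:
            cursor = start
            continue
        vpeak = _main_sequence_vpeak(amp, params.saccade_vpeak_scale)
        T = MIN_JERK_PEAK * amp / vpeak
        m = max(2, int(round_half_up(T * sample_rate)))
        tau = np.arange(1, m + 1) / m
        s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
        end = min(start + m, n)
        seg = slice(start, end)
        prof_x = cur[0] + delta[0] * s[: end - start]
        prof_y = cur[1] + delta[1] * s[: end - start]
        # curved saccade: lateral minimum-deviation bump, perpendicular
        perp = np.array([-delta[1], delta[0]]) / amp
        lat = params.saccade_curvature * amp * 0.1 * np.sin(np.pi * tau[: end - start])
        lat *= rng.choice([-1.0, 1.0])
        tx[seg] = prof_x + lat * perp[0]
        ty[seg] = prof_y + lat * perp[1]
        cursor = end
        cur = np.array([tax[k], tay[k]])
    tx[cursor:] = cur[0]
    ty[cursor:] = cur[1]

    # low-pass tremor
    if params.tremor_sd > 0:
        w = max(2, int(TREMOR_SMOOTH_MS * sample_rate / 1000.0))
        for arr in (tx, ty):
            noise = uniform_filter1d(rng.standard_normal(n), w, mode="nearest")
            sd = noise.std()
            if sd > 0:
                arr += noise * (params.tremor_sd / sd)
    # slow ocular drift
    if params.drift_rate > 0:
        for arr in (tx, ty):
            arr += np.cumsum(rng.normal(0.0, params.drift_rate * np.sqrt(dt), n))
    # attention drift with prescribed E[gamma](t)
    if attention_drift is not None:
        t = np.arange(n) * dt
        law = np.asarray(attention_drift(t), dtype=float)
        wx = np.cumsum(rng.normal(0.0, np.sqrt(dt), n))
        wy = np.cumsum(rng.normal(0.0, np.sqrt(dt), n))
        denom = np.sqrt(np.maximum(t, dt)) * np.sqrt(np.pi / 2.0)
        tx += law * wx / denom
        ty += law * wy / denom

    # blinks: Poisson events replacing samples with NaN
    if params.blink_rate > 0:
        k = rng.poisson(params.blink_rate * dur / 60.0)
        for _ in range(k):
            onset = int(rng.uniform(0, n))
            blink_ms = max(20.0, rng.normal(params.blink_dur_ms, params.blink_dur_ms / 4))
            blen = int(blink_ms * sample_rate / 1000.0)
            tx[onset : onset + blen] = np.nan
            ty[onset : onset + blen] = np.nan

    return GazeRecording(
        subject_id=subject_id,
        task=script.task,
        round=round,
        session=session,
        timestamps=np.arange(n) * (1000.0 / sample_rate),
        theta_x=tx,
        theta_y=ty,
        sample_rate=sample_rate,
    )


def round_half_up(x: float) -> float:
    return np.floor(x + 0.5)


def draw_subject_params(rng: np.random.Generator, seed: int = 0) -> SubjectParams:
    """Draw one subject from the default hyper-distributions."""
    return SubjectParams(
        tremor_sd=float(np.exp(rng.uniform(np.log(0.02), np.log(0.15)))),
        drift_rate=float(rng.uniform(0.0, 0.02)),
        saccade_vpeak_scale=float(rng.uniform(0.95, 1.35)),
        saccade_curvature=float(rng.uniform(0.0, 0.25)),
        blink_rate=float(rng.uniform(5.0, 25.0)),
        blink_dur_ms=float(rng.uniform(80.0, 250.0)),
        latency_ms=float(rng.uniform(130.0, 260.0)),
        seed=seed,
    )


def well_separated_params(n_subjects: int, master_seed: int = 0) -> list[SubjectParams]:
    """Subjects with widely spread oculomotor signatures.

    Each trait is spread across its physiological range and the trait orders
    are shuffled independently, so every subject gets a distinct combination.
    """
    rng = np.random.default_rng(master_seed)
    tremor = np.exp(np.linspace(np.log(0.02), np.log(0.2), n_subjects))
    vpeak = np.linspace(0.9, 1.4, n_subjects)
    curv = np.linspace(0.0, 0.3, n_subjects)
    latency = np.linspace(120.0, 280.0, n_subjects)
    blink = np.linspace(5.0, 25.0, n_subjects)
    for arr in (vpeak, curv, latency, blink):
        rng.shuffle(arr)
    return [
        SubjectParams(
            tremor_sd=float(tremor[i]),
            drift_rate=0.0,
            saccade_vpeak_scale=float(vpeak[i]),
            saccade_curvature=float(curv[i]),
            blink_rate=float(blink[i]),
            blink_dur_ms=150.0,
            latency_ms=float(latency[i]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for i in range(n_subjects)
    ]


def simulate_cohort(
    outdir,
    n_subjects: int,
    tasks: Sequence[str] = ("HSS",),
    rounds: int = 8,
    sessions: int = 2,
    duration_s: float = 60.0,
    geom: ScreenGeometry | None = None,
    master_seed: int = 0,
    params_mode: str = "random",
):
    """Simulate a round-structured cohort and write it to disk as CSV.

    Returns the :class:`~gazeauth.io.DatasetManifest`.  All randomness flows
    from ``master_seed`` through per-recording derived seeds, so the same
    seed reproduces the dataset byte for byte.
    """
    from . import io as gio  # local import to avoid cycle

    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    geom = geom or ScreenGeometry()
    if params_mode == "separated":
        subject_params = well_separated_params(n_subjects, master_seed)
    elif params_mode == "random":
        rng = np.random.default_rng(master_seed)
        subject_params = [
            draw_subject_params(rng, seed=int(rng.integers(0, 2**31 - 1)))
            for _ in range(n_subjects)
        ]
    else:
        raise ValueError(f"unknown params_mode {params_mode!r}")

    infos = []
    outdir = gio.ensure_dir(outdir)
    for si, sp in enumerate(subject_params):
        subject = f"S{si:03d}"
        for rnd in range(1, rounds + 1):
            for sess in range(1, sessions + 1):
                for ti, task in enumerate(tasks):
                    ss = np.random.SeedSequence(
                        entropy=master_seed, spawn_key=(si, rnd, sess, ti)
                    )
                    rec_rng = np.random.default_rng(ss)
                    script = make_stimulus(
                        task, duration_s, geom,
                        seed=int(ss.generate_state(1)[0] % (2**31 - 1)),
                    )
                    rec = simulate_recording(
                        script, sp, geom,
                        subject_id=subject, round=rnd, session=sess, rng=rec_rng,
                    )
                    path = outdir / f"{subject}_{task}_r{rnd:02d}_s{sess}.csv"
                    gio.write_recording(path, rec)
                    infos.append(
                        gio.RecordingInfo(
                            path=str(path), subject=subject, task=task,
                            round=rnd, session=sess, duration_s=rec.duration_s,
                        )
                    )
    manifest = gio.DatasetManifest(
        recordings=infos,
        metadata={
            "master_seed": master_seed,
            "params_mode": params_mode,
            "subject_params": [asdict(sp) for sp in subject_params],
        },
    )
    manifest.save(outdir / "manifest.json")
    return manifest
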