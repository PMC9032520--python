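"""Recording CSV I/O, dataset manifests, segmentation, and subject splits.

The native schema is a CSV with columns ``time_ms, theta_x_deg,
theta_y_deg``; empty or NaN angle cells mark invalid (blink) samples.
Recording metadata (subject, task, round, session) lives in the filename
(``{subject}_{task}_r{round:02d}_s{session}.csv``) and in the dataset
manifest JSON.  An adapter for GazeBase-style CSVs (columns ``n, x, y``) is
provided via a column map.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FormatError, GazeRecording

__all__ = [
    "RecordingInfo",
    "DatasetManifest",
    "SegmentInfo",
    "SegmentedDataset",
    "read_recording",
    "write_recording",
    "segment_recordings",
    "make_splits",
    "closed_set_split",
    "load_segment",
]

logger = logging.getLogger(__name__)

FILENAME_RE = re.compile(r"(?P<subject>[^_]+)_(?P<task>[A-Z]+)_r(?P<round>\d+)_s(?P<session>\d+)\.csv$")

GAZEBASE_COLUMN_MAP = {"n": "time_ms", "x": "theta_x_deg", "y": "theta_y_deg"}


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


@dataclass
class RecordingInfo:
    path: str
    subject: str
    task: str
    round: int
    session: int
    duration_s: float


@dataclass
class DatasetManifest:
    """Recording inventory with optional subject splits and fold assignments."""

    recordings: list[RecordingInfo]
    splits: dict = field(default_factory=dict)  # {"train": [...], "val": [...], "test": [...]}
    folds: dict = field(default_factory=dict)  # subject -> fold index
    metadata: dict = field(default_factory=dict)

    def subjects(self) -> list[str]:
        return sorted({r.subject for r in self.recordings})

    def validate_splits(self) -> None:
        train = set(self.splits.get("train", []))
        val = set(self.splits.get("val", []))
        test = set(self.splits.get("test", []))
        if test & (train | val):
            raise ValueError("test subjects overlap train/val")
        for s in train | val:
            if s not in self.folds:
                raise ValueError(f"subject {s} missing fold assignment")

    def save(self, path) -> None:
        obj = {
            "recordings": [asdict(r) for r in self.recordings],
            "splits": self.splits,
            "folds": self.folds,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        obj = json.loads(Path(path).read_text())
        return cls(
            recordings=[RecordingInfo(**r) for r in obj["recordings"]],
            splits=obj.get("splits", {}),
            folds=obj.get("folds", {}),
            metadata=obj.get("metadata", {}),
        )


@dataclass
class SegmentInfo:
    recording: RecordingInfo
    start_s: float
    duration_s: float


@dataclass
class SegmentedDataset:
    segments: list[SegmentInfo]
    segment_s: float

    def by_subject(self) -> dict[str, list[int]]:
        """Segment indices per subject, in temporal (round, session, start) order."""
        order = sorted(
            range(len(self.segments)),
            key=lambda i: (
                self.segments[i].recording.subject,
                self.segments[i].recording.round,
                self.segments[i].recording.session,
                self.segments[i].start_s,
            ),
        )
        out: dict[str, list[int]] = {}
        for i in order:
            out.setdefault(self.segments[i].recording.subject, []).append(i)
        return out


def write_recording(path, rec: GazeRecording) -> None:
    df = pd.DataFrame(
        {
            "time_ms": rec.timestamps,
            "theta_x_deg": rec.theta_x,
            "theta_y_deg": rec.theta_y,
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_recording(
    path,
    subject_id: str | None = None,
    task: str | None = None,
    round: int | None = None,
    session: int | None = None,
    sample_rate: float = 1000.0,
    column_map: dict | None = None,
) -> GazeRecording:
    """Read a recording CSV; NaN/empty angle cells become invalid samples.

    Metadata defaults are parsed from the filename when not given.
    ``column_map`` renames foreign schemas (e.g. ``GAZEBASE_COLUMN_MAP``)
    onto the native one.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = ["time_ms", "theta_x_deg", "theta_y_deg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    t = df["time_ms"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # +3: 1-based lines, header row, and the offense is at index bad+1
        raise FormatError(f"{path}: non-monotone time_ms at line {bad[0] + 3}")
    meta = {"subject": "unknown", "task": "FXS", "round": 1, "session": 1}
    m = FILENAME_RE.search(path.name)
    if m:
        meta = {
            "subject": m["subject"],
            "task": m["task"],
            "round": int(m["round"]),
            "session": int(m["session"]),
        }
    return GazeRecording(
        subject_id=subject_id if subject_id is not None else meta["subject"],
        task=task if task is not None else meta["task"],
        round=round if round is not None else meta["round"],
        session=session if session is not None else meta["session"],
        timestamps=t,
        theta_x=df["theta_x_deg"].to_numpy(dtype=float),
        theta_y=df["theta_y_deg"].to_numpy(dtype=float),
        sample_rate=sample_rate,
    )


def load_segment(seg: SegmentInfo, sample_rate: float = 1000.0) -> GazeRecording:
    """Load the recording slice backing one segment."""
    rec = read_recording(
        seg.recording.path,
        subject_id=seg.recording.subject,
        task=seg.recording.task,
        round=seg.recording.round,
        session=seg.recording.session,
        sample_rate=sample_rate,
    )
    i0 = int(seg.start_s * rec.sample_rate)
    i1 = i0 + int(seg.duration_s * rec.sample_rate)
    return rec.slice(i0, i1)


def segment_recordings(
    manifest: DatasetManifest,
    segment_s: float,
    usable_s: float = 60.0,
    subjects: set | None = None,
) -> SegmentedDataset:
    """Cut each recording's first ``usable_s`` seconds into non-overlapping
    ``segment_s`` segments in temporal order.

    Recordings shorter than ``usable_s`` are truncated to the full segments
    available (with a warning).  ``subjects`` optionally restricts the set.
    """
    if segment_s > usable_s:
        raise ValueError("segment_s must be <= usable_s")
    segments = []
    for info in manifest.recordings:
        if subjects is not None and info.subject not in subjects:
            continue
        avail = min(info.duration_s, usable_s)
        if info.duration_s < usable_s:
            logger.warning(
                "recording %s is %.1f s < usable %.1f s; truncating",
                info.path, info.duration_s, usable_s,
            )
        n = int(np.floor(avail / segment_s + 1e-9))
        for k in range(n):
            segments.append(SegmentInfo(info, start_s=k * segment_s, duration_s=segment_s))
    return SegmentedDataset(segments=segments, segment_s=segment_s)


def make_splits(
    manifest: DatasetManifest,
    test_subjects: list[str] | None = None,
    test_rule=None,
    n_folds: int = 10,
    seed: int = 0,
) -> DatasetManifest:
    """Assign held-out test subjects and k-fold train/val assignments.

    ``test_rule`` is a predicate on (subject, set of rounds present); e.g.
    membership in all 8 rounds.  The remaining subjects are trimmed to a
    multiple of ``n_folds`` (keeping the first in sorted order) and dealt
    into folds by a seeded shuffle.
    """
    subjects = manifest.subjects()
    rounds_by_subject: dict[str, set] = {}
    for r in manifest.recordings:
        rounds_by_subject.setdefault(r.subject, set()).add(r.round)
    if test_subjects is None:
        if test_rule is None:
            raise ValueError("provide test_subjects or test_rule")
        test_subjects = [s for s in subjects if test_rule(s, rounds_by_subject[s])]
    if not test_subjects:
        raise ValueError("test subject set is empty")
    rest = [s for s in subjects if s not in set(test_subjects)]
    keep = len(rest) - len(rest) % n_folds
    rest = rest[:keep]
    rng = np.random.default_rng(seed)
    order = list(rest)
    rng.shuffle(order)
    folds = {s: i % n_folds for i, s in enumerate(order)}
    manifest.splits = {"train": rest, "val": [], "test": list(test_subjects)}
    manifest.folds = folds
    manifest.validate_splits()
    return manifest


def closed_set_split(
    manifest: DatasetManifest,
    train_rounds=(1, 2, 3, 4),
    val_rounds=(5, 6),
    test_rounds=(7, 8),
) -> dict[str, list[RecordingInfo]]:
    """Temporal closed-set split: earlier rounds train, later rounds test."""
    out = {"train": [], "val": [], "test": []}
    for info in manifest.recordings:
        if info.round in train_rounds:
            out["train"].append(info)
        elif info.round in val_rounds:
            out["val"].append(info)
        elif info.round in test_rounds:
            out["test"].append(info)
    return out
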