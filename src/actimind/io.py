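"""Reading and writing subject actigraphy CSV files.

The on-disk dialect mirrors the public Depresjon/Psykose layout: one CSV
per participant with a ``timestamp,date,activity`` header, timestamps at
minute resolution, and non-negative integer activity counts.  The 32
healthy controls are shared between the two source datasets, so cohort
assembly de-duplicates subjects by identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ManifestError
from .synthetic import GROUPS, SubjectRecording

__all__ = [
    "CohortManifest",
    "read_subject_csv",
    "write_subject_csv",
    "write_cohort_csv",
    "assemble_cohort",
    "manifest_from_dirs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortManifest:
    """List of (file path, subject_id, group) entries plus a provenance note."""

    entries: Sequence[tuple[Path | str, str, int]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for _, _, group in self.entries:
            if group not in GROUPS:
                raise ManifestError(f"group label {group} not in {GROUPS}")


def read_subject_csv(path: Path | str, subject_id: str, group: int) -> SubjectRecording:
    """Read one participant CSV into a labeled recording.

    Rows whose timestamp or activity fail to parse are dropped with a
    logged count.  A negative activity value is treated as file corruption
    and raises :class:`FormatError` naming the offending line.  Timestamps
    may carry or omit seconds; duplicated timestamps are an error, gaps are
    tolerated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    required = {"timestamp", "activity"}
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    if raw.empty:
        raise FormatError(f"{path}: no data rows")

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="mixed")
    act = pd.to_numeric(raw["activity"], errors="coerce")
    bad = ts.isna() | act.isna()
    if bad.any():
        logger.warning("%s: dropped %d unparseable row(s)", path, int(bad.sum()))
    negative = act < 0
    if negative.any():
        # +2: one for the header row, one for 0- vs 1-based indexing
        line = int(negative.idxmax()) + 2
        raise FormatError(f"{path}: negative activity value at line {line}")
    frame = pd.DataFrame({"timestamp": ts[~bad], "activity": act[~bad]}).reset_index(drop=True)
    if frame.empty:
        raise FormatError(f"{path}: no valid data rows")
    if frame["timestamp"].duplicated().any():
        raise FormatError(f"{path}: duplicated timestamps")
    frame["activity"] = frame["activity"].astype(np.int64)
    return SubjectRecording(subject_id=subject_id, group=group, data=frame)


def write_subject_csv(recording: SubjectRecording, path: Path | str) -> None:
    """Write a recording in the ``timestamp,date,activity`` dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ts = pd.to_datetime(recording.data["timestamp"])
    out = pd.DataFrame(
        {
            "timestamp": ts.dt.strftime("%Y-%m-%d %H:%M:%S"),
            "date": ts.dt.strftime("%Y-%m-%d"),
            "activity": recording.data["activity"].astype(np.int64),
        }
    )
    out.to_csv(path, index=False)


def write_cohort_csv(recordings: Iterable[SubjectRecording], directory: Path | str) -> list[Path]:
    """Write one CSV per recording under `directory`; returns written paths."""
    directory = Path(directory)
    paths = []
    for rec in recordings:
        p = directory / f"{rec.subject_id}.csv"
        write_subject_csv(rec, p)
        paths.append(p)
    return paths


def assemble_cohort(manifest: CohortManifest) -> list[SubjectRecording]:
    """Read every manifest entry, keeping each unique subject exactly once.

    Controls listed by both source datasets collapse to a single recording.
    The same subject_id appearing with two different group labels is a
    manifest error.
    """
    if not manifest.entries:
        raise ManifestError("empty manifest")
    seen: dict[str, int] = {}
    recordings: list[SubjectRecording] = []
    for path, subject_id, group in manifest.entries:
        if subject_id in seen:
            if seen[subject_id] != group:
                raise ManifestError(
                    f"subject {subject_id!r} listed with conflicting groups "
                    f"{seen[subject_id]} and {group}"
                )
            continue  # shared control: keep the first occurrence
        seen[subject_id] = group
        recordings.append(read_subject_csv(path, subject_id, group))
    return recordings


def manifest_from_dirs(
    control_dir: Path | str | None = None,
    depression_dir: Path | str | None = None,
    schizophrenia_dir: Path | str | None = None,
    provenance: str = "",
) -> CohortManifest:
    """Build a manifest from per-group directories of subject CSV files.

    Subject ids are file basenames, so a control file present in more than
    one directory de-duplicates naturally at assembly.
    """
    entries: list[tuple[Path, str, int]] = []
    for directory, group in (
        (control_dir, 0),
        (depression_dir, 1),
        (schizophrenia_dir, 2),
    ):
        if directory is None:
            continue
        for path in sorted(Path(directory).glob("*.csv")):
            entries.append((path, path.stem, group))
    return CohortManifest(entries=entries, provenance=provenance)
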