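"""Actigraphy I/O: per-minute activity CSVs, subject metadata, cohort summaries.

The on-disk dialect follows the publicly deposited Depresjon/PSYKOSE wrist
actigraphy recordings: comma-separated files with a header row
``timestamp,date,activity``, timestamps at one-minute cadence formatted
``YYYY-MM-DD HH:MM:SS``, and nonnegative integer activity counts.  Condition
labels are never inferred from file content; they come from the caller or
from the directory layout (one subdirectory per condition).
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from collections import Counter
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from ._util import round_half_up

logger = logging.getLogger(__name__)

TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M:%S"


class Condition(str, enum.Enum):
    """Diagnostic group of a subject, with the dataset's integer label coding."""

    CONTROL = "control"
    DEPRESSION = "depression"
    SCHIZOPHRENIA = "schizophrenia"

    @property
    def label(self) -> int:
        return CONDITION_LABELS[self]


#: Integer class coding used throughout: control 0, depression 1, schizophrenia 2.
CONDITION_LABELS: dict[Condition, int] = {
    Condition.CONTROL: 0,
    Condition.DEPRESSION: 1,
    Condition.SCHIZOPHRENIA: 2,
}
LABEL_CONDITIONS: dict[int, Condition] = {v: k for k, v in CONDITION_LABELS.items()}


@dataclasses.dataclass(frozen=True)
class ActivitySample:
    """One per-minute observation: a timestamp and a nonnegative count."""

    timestamp: pd.Timestamp
    activity: int


@dataclasses.dataclass
class SubjectSeries:
    """One subject's ordered per-minute activity recording.

    Invariants enforced at construction: activity counts are nonnegative
    integers, timestamps are strictly increasing and have a zero seconds
    component (per-minute cadence).
    """

    subject_id: str
    condition: Condition | None
    timestamps: pd.DatetimeIndex
    activity: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.activity = np.asarray(self.activity, dtype=np.int64)
        if len(self.timestamps) != len(self.activity):
            raise ValueError("timestamps and activity differ in length")
        if len(self.timestamps) == 0:
            raise ValueError("empty series")
        if (self.activity < 0).any():
            bad = int(np.argmax(self.activity < 0))
            raise ValueError(f"negative activity count at sample {bad}")
        if (self.timestamps.second != 0).any() or (
            getattr(self.timestamps, "nanosecond", np.zeros(1)) != 0
        ).any():
            raise ValueError("timestamps must be at whole-minute resolution")
        if len(self.timestamps) > 1 and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")

    def __len__(self) -> int:
        return len(self.activity)

    @property
    def samples(self) -> Iterator[ActivitySample]:
        for ts, a in zip(self.timestamps, self.activity):
            yield ActivitySample(ts, int(a))


@dataclasses.dataclass(frozen=True)
class CadenceIssue:
    """One irregularity in the one-minute cadence of a recording."""

    kind: str  # "gap" or "duplicate"
    start: pd.Timestamp
    minutes: int


@dataclasses.dataclass
class SubjectMetadata:
    """Per-subject demographics and clinical scores.

    Clinical fields (MADRS scores, affective subtype, melancholia,
    inpatient status, marriage, work, education, schizophrenia subtype,
    migraines, clozapine) are optional and absent for control subjects.
    """

    subject_id: str
    gender: str | None = None
    age_group: str | None = None
    days_recorded: int | None = None
    madrs_initial: int | None = None
    madrs_final: int | None = None
    aftype: str | None = None
    melancholia: str | None = None
    inpatient: str | None = None
    marriage: str | None = None
    work: str | None = None
    education: str | None = None
    schizo_subtype: str | None = None
    migraines: str | None = None
    clozapine: str | None = None


@dataclasses.dataclass
class CohortSummary:
    """Counts and percentages of one categorical field across a cohort."""

    category: str
    total: int
    counts: dict[str, int]
    percentages: dict[str, float]


def read_activity_csv(
    path: str | Path,
    *,
    condition: Condition | str | None = None,
    subject_id: str | None = None,
    dayfirst: bool = False,
) -> SubjectSeries:
    """Read one subject's actigraphy CSV.

    Parameters
    ----------
    path
        CSV file with at least a ``timestamp`` and an ``activity`` column
        (a ``date`` column, present in the deposited files, is ignored).
    condition
        Diagnostic group; never inferred from content.
    subject_id
        Defaults to the file stem.
    dayfirst
        Permissive flag for recordings whose timestamps use day-first
        date order.
    """
    path = Path(path)
    df = pd.read_csv(path)
    columns = {c.strip().lower(): c for c in df.columns}
    for required in ("timestamp", "activity"):
        if required not in columns:
            raise ValueError(f"{path}: missing required column {required!r}")
    ts = pd.to_datetime(df[columns["timestamp"]], errors="coerce", dayfirst=dayfirst)
    if ts.isna().any():
        line = int(np.argmax(ts.isna().to_numpy())) + 2  # header is line 1
        raise ValueError(f"{path}: malformed timestamp on line {line}")
    act = pd.to_numeric(df[columns["activity"]], errors="coerce")
    if act.isna().any():
        line = int(np.argmax(act.isna().to_numpy())) + 2
        raise ValueError(f"{path}: malformed activity value on line {line}")
    if (act < 0).any():
        line = int(np.argmax((act < 0).to_numpy())) + 2
        raise ValueError(f"{path}: negative activity count on line {line}")
    if condition is not None and not isinstance(condition, Condition):
        condition = Condition(condition)
    return SubjectSeries(
        subject_id=subject_id or path.stem,
        condition=condition,
        timestamps=pd.DatetimeIndex(ts),
        activity=act.to_numpy(dtype=np.int64),
    )


def write_activity_csv(series: SubjectSeries, path: str | Path) -> Path:
    """Write a series in the deposited dialect (``timestamp,date,activity``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "timestamp": series.timestamps.strftime(TIMESTAMP_FORMAT),
            "date": series.timestamps.strftime("%Y-%m-%d"),
            "activity": series.activity,
        }
    )
    df.to_csv(path, index=False)
    return path


def read_condition_tree(
    root: str | Path, *, conditions: Sequence[Condition] = tuple(Condition)
) -> dict[Condition, list[SubjectSeries]]:
    """Read a directory with one subdirectory of CSVs per condition."""
    root = Path(root)
    cohorts: dict[Condition, list[SubjectSeries]] = {}
    for cond in conditions:
        sub = root / cond.value
        if not sub.is_dir():
            continue
        cohorts[cond] = [
            read_activity_csv(p, condition=cond) for p in sorted(sub.glob("*.csv"))
        ]
    return cohorts


def validate_cadence(series: SubjectSeries) -> list[CadenceIssue]:
    """Report every deviation from a strict one-minute cadence.

    Returns an empty list iff the recording is perfectly regular: one issue
    per missing minute and one per duplicated timestamp.
    """
    issues: list[CadenceIssue] = []
    ts = series.timestamps
    deltas = (ts[1:] - ts[:-1]) / pd.Timedelta(minutes=1)
    for i, d in enumerate(deltas):
        if d == 0:
            issues.append(CadenceIssue("duplicate", ts[i + 1], 1))
        elif d > 1:
            for m in range(1, int(d)):
                issues.append(
                    CadenceIssue("gap", ts[i] + pd.Timedelta(minutes=m), 1)
                )
    return issues


def read_metadata_csv(path: str | Path) -> list[SubjectMetadata]:
    """Read a subject metadata table (one row per subject)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing subject_id column")
    known = {f.name for f in dataclasses.fields(SubjectMetadata)}
    records = []
    for _, row in df.iterrows():
        kwargs = {
            k: (None if pd.isna(v) else v)
            for k, v in row.items()
            if k in known
        }
        records.append(SubjectMetadata(**kwargs))
    return records


def summarize_cohort(
    metadata: Sequence[SubjectMetadata] | Sequence[dict], category: str
) -> CohortSummary:
    """Tabulate one categorical field: counts and percentages to one decimal.

    Percentages are ``100 * count / total`` rounded half away from zero, so
    within a category they sum to 100 up to rounding (±0.3).
    """
    if len(metadata) == 0:
        raise ValueError("empty metadata list")
    values = []
    for rec in metadata:
        v = rec.get(category) if isinstance(rec, dict) else getattr(rec, category)
        if v is None:
            raise ValueError(f"record missing category field {category!r}")
        values.append(str(v))
    counts = dict(Counter(values))
    total = len(values)
    percentages = {k: round_half_up(100.0 * c / total, 1) for k, c in counts.items()}
    return CohortSummary(category, total, counts, percentages)


def export_image_png(image, path: str | Path) -> Path:
    """Write a day-image as an 8-bit grayscale PNG (48 wide x 30 tall).

    ``image`` is an ``EncodedImage`` or a bare 2-D array with values in
    [0, 255]; values are rounded to the nearest integer, so the round trip is
    lossless for the rounded values.
    """
    pixels = np.asarray(getattr(image, "pixels", image), dtype=float)
    if pixels.ndim != 2:
        raise ValueError("image must be a 2-D grid")
    if not np.isfinite(pixels).all() or pixels.min() < 0 or pixels.max() > 255:
        raise ValueError("pixel values must lie within [0, 255]")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.rint(pixels).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    return path


def read_image_png(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG back into a 2-D uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)
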