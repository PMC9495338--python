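"""Reading, validating and segmenting Depresjon-format actigraphy CSVs.

The on-disk dialect is one CSV per subject with a ``timestamp,date,activity``
header: per-minute timestamps (``YYYY-MM-DD HH:MM:SS``), the calendar date of
each measurement, and a non-negative integer activity count from the actigraph
watch.  Subjects live under ``<root>/control/*.csv`` and
``<root>/condition/*.csv`` for the healthy (label 0) and depressed (label 1)
groups respectively.

Days are fixed 1440-slot grids: a record belongs to the calendar date of its
timestamp and to the wall-clock minute-of-day slot.  Daylight-saving or
timezone shifts are not modelled.  Only complete days (all 1440 minutes
present) are usable downstream; partial days are dropped, never imputed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440

REQUIRED_COLUMNS = ("timestamp", "date", "activity")

CONTROL, CONDITION = 0, 1


class FormatError(ValueError):
    """The file does not follow the expected CSV dialect (e.g. missing column)."""


class ValidationError(ValueError):
    """The file parses but violates a data invariant (negative count, bad
    timestamp, duplicate minute)."""


class InsufficientDataError(ValueError):
    """A subject does not have enough complete days for the requested operation."""


@dataclass(frozen=True)
class SubjectSeries:
    """One subject's ordered per-minute activity records plus group label.

    ``frame`` has columns ``timestamp`` (datetime64, strictly increasing,
    minute-aligned), ``date`` (datetime.date) and ``activity`` (int >= 0).
    """

    subject_id: str
    group: int
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.group not in (CONTROL, CONDITION):
            raise ValidationError(f"group must be 0 or 1, got {self.group!r}")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class CompleteDay:
    """A full calendar day: 1440 activity counts ordered 00:00 -> 23:59."""

    date: _dt.date
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != (MINUTES_PER_DAY,):
            raise ValidationError(
                f"a complete day has exactly {MINUTES_PER_DAY} values, "
                f"got shape {values.shape}"
            )
        if np.any(values < 0):
            raise ValidationError("activity counts must be non-negative")
        object.__setattr__(self, "values", values)


def _validate_frame(frame: pd.DataFrame, origin: str) -> pd.DataFrame:
    try:
        ts = pd.to_datetime(frame["timestamp"], format="%Y-%m-%d %H:%M:%S")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{origin}: unparseable timestamp: {exc}") from exc
    activity = pd.to_numeric(frame["activity"], errors="coerce")
    if activity.isna().any():
        raise ValidationError(f"{origin}: non-numeric activity value")
    if (activity < 0).any():
        bad = activity[activity < 0].iloc[0]
        raise ValidationError(f"{origin}: negative activity value {bad}")
    if (ts.dt.second != 0).any():
        raise ValidationError(f"{origin}: timestamp not minute-aligned (seconds != 0)")
    out = pd.DataFrame(
        {
            "timestamp": ts,
            "date": ts.dt.date,
            "activity": activity.astype(np.int64),
        }
    ).sort_values("timestamp", kind="stable", ignore_index=True)
    if out["timestamp"].duplicated().any():
        dup = out.loc[out["timestamp"].duplicated(), "timestamp"].iloc[0]
        raise ValidationError(f"{origin}: duplicate timestamp {dup}")
    return out


def read_subject_csv(path: str | Path, group: int) -> SubjectSeries:
    """Parse one subject CSV into a :class:`SubjectSeries`.

    Records are parsed in file order then sorted by timestamp.  Duplicate
    timestamps, negative counts and unparseable timestamps are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return SubjectSeries(
        subject_id=path.stem, group=group, frame=_validate_frame(frame, str(path))
    )


def write_subject_csv(series: SubjectSeries, path: str | Path) -> Path:
    """Write a :class:`SubjectSeries` in the same dialect ``read_subject_csv``
    accepts (round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = pd.DataFrame(
        {
            "timestamp": series.frame["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S"),
            "date": [d.isoformat() for d in series.frame["date"]],
            "activity": series.frame["activity"],
        }
    )
    out.to_csv(path, index=False)
    return path


def read_cohort(root: str | Path) -> list[SubjectSeries]:
    """Read ``<root>/control/*.csv`` and ``<root>/condition/*.csv``."""
    root = Path(root)
    cohort: list[SubjectSeries] = []
    for sub, group in (("control", CONTROL), ("condition", CONDITION)):
        folder = root / sub
        if not folder.is_dir():
            raise FormatError(f"missing group folder {folder}")
        for path in sorted(folder.glob("*.csv")):
            cohort.append(read_subject_csv(path, group))
    if not cohort:
        raise FormatError(f"no subject CSVs found under {root}")
    return cohort


def segment_complete_days(series: SubjectSeries) -> list[CompleteDay]:
    """Split a series into complete calendar days (all 1440 minutes present).

    Partial days are dropped.  Values within each day are ordered by
    minute-of-day.  The result is sorted by date.
    """
    if len(series) == 0:
        raise ValidationError(f"{series.subject_id}: empty series")
    frame = series.frame
    minute_of_day = frame["timestamp"].dt.hour * 60 + frame["timestamp"].dt.minute
    days: list[CompleteDay] = []
    for date, idx in frame.groupby("date", sort=True).groups.items():
        if len(idx) != MINUTES_PER_DAY:
            continue
        order = np.argsort(minute_of_day.loc[idx].to_numpy(), kind="stable")
        values = frame.loc[idx, "activity"].to_numpy()[order]
        days.append(CompleteDay(date=date, values=values))
    days.sort(key=lambda d: d.date)
    return days


def select_week(days: Sequence[CompleteDay], subject_id: str = "?") -> list[CompleteDay]:
    """Return the 7 earliest complete days in chronological order."""
    if len(days) < 7:
        raise InsufficientDataError(
            f"subject {subject_id}: needs 7 complete days, has {len(days)}"
        )
    return sorted(days, key=lambda d: d.date)[:7]
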