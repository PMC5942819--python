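"""Event-date series I/O and conversions.

The raw observable is an ordered list of calendar dates, one per event
(several events may share a date).  All model arithmetic happens on 0-based
integer day offsets from the start of the study span; calendar dates appear
only at the I/O boundary, which removes leap-year and timezone ambiguity
from the model core.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EventSeries",
    "DailyCounts",
    "GapSample",
    "GapHistogram",
    "read_events",
    "write_events",
    "to_daily_counts",
    "write_daily_counts",
    "events_from_day_indices",
    "gaps_from_events",
    "gap_histogram",
]


@dataclass(frozen=True)
class EventSeries:
    """Ordered calendar dates of events within a study span.

    Parameters
    ----------
    dates : tuple of datetime.date
        Event dates, sorted non-decreasing.  Duplicates are legal and
        meaningful (multiple events on one day).
    span_start, span_end : datetime.date
        Inclusive bounds of the study period.  Default to the tight span
        ``[min(dates), max(dates)]``; a wider span may be given explicitly,
        since the study period is an analyst's choice, not a data property.
    """

    dates: tuple
    span_start: _dt.date
    span_end: _dt.date

    def __init__(self, dates, span_start=None, span_end=None):
        dates = tuple(sorted(dates))
        if not dates and (span_start is None or span_end is None):
            raise ValueError("an empty EventSeries requires an explicit span")
        if span_start is None:
            span_start = dates[0]
        if span_end is None:
            span_end = dates[-1]
        if span_end < span_start:
            raise ValueError(f"span_end {span_end} precedes span_start {span_start}")
        for d in dates:
            if d < span_start or d > span_end:
                raise ValueError(f"event date {d} outside span [{span_start}, {span_end}]")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "span_start", span_start)
        object.__setattr__(self, "span_end", span_end)

    @property
    def n_events(self) -> int:
        return len(self.dates)

    @property
    def n_days(self) -> int:
        """Days in the span, inclusive of both endpoints."""
        return (self.span_end - self.span_start).days + 1

    def day_indices(self) -> np.ndarray:
        """0-based integer day offset of each event from ``span_start``."""
        start = self.span_start
        return np.array([(d - start).days for d in self.dates], dtype=np.int64)


@dataclass(frozen=True)
class DailyCounts:
    """Integer events-per-day vector over a study span.

    ``counts[k]`` is the number of events on day ``origin + k``.  Zero-count
    days are retained: every day of the span informs an unbinned likelihood,
    even when nothing happened on it.
    """

    counts: np.ndarray
    origin: _dt.date

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integral")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_days(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def weekday_of_index(self, i) -> np.ndarray:
        """ISO weekday index (Monday=0 .. Sunday=6) of day offset ``i``."""
        return (self.origin.weekday() + np.asarray(i)) % 7


@dataclass(frozen=True)
class GapSample:
    """Integer-day differences between successive events.

    Events on the same day yield a gap of zero.  A series with fewer than
    two events has an empty (but valid) gap sample.
    """

    gaps: np.ndarray
    n_events: int

    def __post_init__(self):
        gaps = np.asarray(self.gaps, dtype=np.int64)
        if gaps.ndim != 1:
            raise ValueError("gaps must be one-dimensional")
        if np.any(gaps < 0):
            raise ValueError("gaps must be non-negative")
        if self.n_events >= 2 and len(gaps) != self.n_events - 1:
            raise ValueError("gap count must be n_events - 1")
        object.__setattr__(self, "gaps", gaps)

    def __len__(self):
        return len(self.gaps)


@dataclass(frozen=True)
class GapHistogram:
    """Gap counts per integer-day bin ``d = 0..d_max`` plus an overflow bin."""

    counts: np.ndarray
    overflow: int
    d_max: int

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if len(counts) != self.d_max + 1:
            raise ValueError("histogram must have d_max + 1 bins")
        if np.any(counts < 0) or self.overflow < 0:
            raise ValueError("bin counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.overflow

    def all_bins(self) -> np.ndarray:
        """Bins 0..d_max followed by the overflow bin."""
        return np.concatenate([self.counts, [self.overflow]])


def read_events(path, column: str = "date", span_start=None, span_end=None) -> EventSeries:
    """Read an event-date series from a CSV with an ISO-8601 date column.

    Raises
    ------
    ValueError
        If the file has no rows, the column is missing, or a date fails to
        parse (the error names the offending row).
    """
    frame = pd.read_csv(path, dtype=str)
    if column not in frame.columns:
        raise ValueError(f"column {column!r} not found in {path}")
    if len(frame) == 0:
        raise ValueError(f"no event rows in {path}")
    dates = []
    for row, value in enumerate(frame[column], start=2):  # row 1 is the header
        try:
            dates.append(_dt.date.fromisoformat(str(value).strip()))
        except ValueError as exc:
            raise ValueError(f"unparseable date {value!r} at row {row} of {path}") from exc
    if isinstance(span_start, str):
        span_start = _dt.date.fromisoformat(span_start)
    if isinstance(span_end, str):
        span_end = _dt.date.fromisoformat(span_end)
    return EventSeries(dates, span_start=span_start, span_end=span_end)


def write_events(events: EventSeries, path, column: str = "date") -> None:
    """Write an event series as a one-column CSV of ISO dates."""
    pd.DataFrame({column: [d.isoformat() for d in events.dates]}).to_csv(path, index=False)


def to_daily_counts(events: EventSeries) -> DailyCounts:
    """Bin an event series into an events-per-day vector over its span."""
    counts = np.bincount(events.day_indices(), minlength=events.n_days)
    return DailyCounts(counts=counts, origin=events.span_start)


def write_daily_counts(counts: DailyCounts, path) -> None:
    """Write a daily-count series as a two-column CSV (date, count)."""
    dates = [(counts.origin + _dt.timedelta(days=int(i))).isoformat() for i in range(counts.n_days)]
    pd.DataFrame({"date": dates, "count": counts.counts}).to_csv(path, index=False)


def events_from_day_indices(days, origin: _dt.date, span_days: int | None = None) -> EventSeries:
    """Build an :class:`EventSeries` from 0-based integer day offsets."""
    days = np.asarray(days, dtype=np.int64)
    dates = [origin + _dt.timedelta(days=int(d)) for d in days]
    span_end = None
    if span_days is not None:
        span_end = origin + _dt.timedelta(days=int(span_days) - 1)
    return EventSeries(dates, span_start=origin, span_end=span_end)


def gaps_from_events(events: EventSeries) -> GapSample:
    """Integer-day gaps between successive events (empty if fewer than 2)."""
    days = events.day_indices()
    gaps = np.diff(days) if len(days) >= 2 else np.array([], dtype=np.int64)
    return GapSample(gaps=gaps, n_events=events.n_events)


def gap_histogram(gaps: GapSample | np.ndarray, d_max: int) -> GapHistogram:
    """Histogram gaps into integer-day bins 0..d_max with an overflow bin."""
    if d_max < 0:
        raise ValueError("d_max must be non-negative")
    g = gaps.gaps if isinstance(gaps, GapSample) else np.asarray(gaps, dtype=np.int64)
    inside = g[g <= d_max]
    counts = np.bincount(inside, minlength=d_max + 1)
    return GapHistogram(counts=counts, overflow=int(np.sum(g > d_max)), d_max=d_max)
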