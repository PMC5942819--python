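import datetime as dt

import numpy as np
import pytest

from selfexcite import DailyCounts, EventSeries

ORIGIN = dt.date(2006, 1, 1)


@pytest.fixture
def origin():
    return ORIGIN


@pytest.fixture
def make_counts():
    """Build a DailyCounts from a vector of per-day counts."""
    def _make(counts, origin=ORIGIN):
        return DailyCounts(counts=np.asarray(counts), origin=origin)
    return _make


@pytest.fixture
def make_events():
    """Build an EventSeries from 0-based day offsets (span optional)."""
    def _make(day_offsets, span_days=None, origin=ORIGIN):
        dates = [origin + dt.timedelta(days=int(d)) for d in day_offsets]
        span_end = origin + dt.timedelta(days=span_days - 1) if span_days else None
        return EventSeries(dates, span_start=origin, span_end=span_end)
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20060101)
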