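"""The night axis: decimal hours since noon of the evening anchor date.

All night-level quantities in this package live on a single monotone axis so
that arithmetic across midnight needs no wraparound handling: 7 PM on the
anchor date is 7.0, midnight is 12.0, 3 AM is 15.0 and 3 PM on the next
calendar day is 27.0.  Clock strings and absolute timestamps are converted to
and from this axis only at I/O boundaries.
"""

from __future__ import annotations

import datetime as dt
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

#: Morning-side cutoff: clock times at or before 15:00 on a morning report
#: belong to the report date; later clock times belong to the previous
#: calendar date when mapped onto the night axis (the analysis window ends
#: at 3 PM).
MORNING_CUTOFF_H = 15.0

NOON_H = 12.0


def clock_to_axis(hours: float | np.ndarray) -> float | np.ndarray:
    """Map clock hours-of-day in [0, 24) to night-axis hours.

    Clock times <= 15:00 are read as the morning after the anchor evening
    (axis 12..27); later clock times as the anchor evening itself (axis 3..12).
    """
    h = np.asarray(hours, dtype=float)
    out = np.where(h <= MORNING_CUTOFF_H, h + NOON_H, h - NOON_H)
    if np.isscalar(hours) or np.ndim(hours) == 0:
        return float(out)
    return out


def axis_to_clock(axis: float) -> float:
    """Map night-axis hours back to clock hours-of-day in [0, 24)."""
    return (axis + NOON_H) % 24.0


def parse_clock(s: str) -> float:
    """Parse an ``HH:MM`` (optionally ``HH:MM:SS``) string to clock hours."""
    parts = str(s).strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"not a clock time: {s!r}")
    h, m = int(parts[0]), int(parts[1])
    sec = int(parts[2]) if len(parts) == 3 else 0
    if not (0 <= h < 24 and 0 <= m < 60 and 0 <= sec < 60):
        raise ValueError(f"not a clock time: {s!r}")
    return h + m / 60.0 + sec / 3600.0


def format_clock(axis: float, seconds: bool = False) -> str:
    """Format a night-axis value as an ``HH:MM`` clock string (nearest min)."""
    if axis is None or (isinstance(axis, float) and np.isnan(axis)):
        return ""
    clock = axis_to_clock(float(axis))
    total = round(clock * (3600 if seconds else 60))
    if seconds:
        total %= 24 * 3600
        h, rem = divmod(total, 3600)
        m, s = divmod(rem, 60)
        return f"{h:02d}:{m:02d}:{s:02d}"
    total %= 24 * 60
    h, m = divmod(total, 60)
    return f"{h:02d}:{m:02d}"


def noon_of(anchor_date: dt.date, tz: str | ZoneInfo | None = None) -> dt.datetime:
    """Local noon of the anchor date as an (aware, if tz given) datetime."""
    tzinfo = ZoneInfo(tz) if isinstance(tz, str) else tz
    return dt.datetime.combine(anchor_date, dt.time(12, 0), tzinfo=tzinfo)


def timestamp_to_axis(ts: pd.Series | pd.Timestamp, anchor_date: dt.date,
                      tz: str | None = None) -> pd.Series | float:
    """Hours elapsed since local noon of ``anchor_date``.

    Durations are computed on the absolute timeline, so a DST transition in
    the night shows up as a shifted wall clock, never as a crash.
    """
    scalar = isinstance(ts, pd.Timestamp)
    s = pd.Series([ts]) if scalar else ts
    if s.dt.tz is not None:
        noon = pd.Timestamp(noon_of(anchor_date, tz or str(s.dt.tz)))
        s = s.dt.tz_convert(noon.tz)
    else:
        noon = pd.Timestamp(noon_of(anchor_date))
    hours = (s - noon) / pd.Timedelta(hours=1)
    return float(hours.iloc[0]) if scalar else hours


def axis_to_timestamp(axis: float, anchor_date: dt.date, tz: str) -> pd.Timestamp:
    """Absolute timestamp for a night-axis value on a given anchor date."""
    return pd.Timestamp(noon_of(anchor_date, tz)) + pd.Timedelta(hours=float(axis))


def anchor_for_event(ts_local: pd.Series) -> pd.Series:
    """Anchor (evening) date whose nightly window an event can belong to.

    Events from 19:00 to midnight anchor on their own date; events from
    midnight to 15:00 anchor on the previous date; afternoon events
    (15:00-19:00) fall outside every nightly window and get NaT.
    """
    if ts_local.dt.tz is not None:
        ts_local = ts_local.dt.tz_localize(None)  # wall-clock view
    hours = ts_local.dt.hour + ts_local.dt.minute / 60.0 + ts_local.dt.second / 3600.0
    date = ts_local.dt.normalize()
    anchor = pd.Series(pd.NaT, index=ts_local.index, dtype="datetime64[ns]")
    evening = hours >= 19.0
    morning = hours <= MORNING_CUTOFF_H
    anchor[evening] = date[evening]
    anchor[morning] = date[morning] - pd.Timedelta(days=1)
    return anchor.dt.date
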