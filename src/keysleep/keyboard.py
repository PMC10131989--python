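"""Keyboard-derived rest-activity estimation.

The nightly estimate is built from the longest interval without keyboard
activity between 7 PM and 3 PM the next day (the keystroke-absence period,
KAP).  The keystrokes bracketing that gap are the last-keystroke and
first-keystroke estimates of rest onset and activity onset; their midpoint
is the keyboard proxy for midsleep.  The KAP must be bracketed by
keystrokes: gaps running into the window edges are not candidates, and ties
resolve to the earliest-starting gap.
"""

from __future__ import annotations

import datetime as dt
import logging
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .timeaxis import anchor_for_event

logger = logging.getLogger(__name__)

WINDOW_START = 7.0   # 7 PM on the anchor date, night-axis hours
WINDOW_END = 27.0    # 3 PM on the next day

ESTIMATE_COLUMNS = ["participant_id", "anchor_date", "last_keystroke",
                    "first_keystroke", "kap_h", "midpoint_kap",
                    "n_events_in_window", "valid"]


class KapEstimate(NamedTuple):
    last_keystroke: float
    first_keystroke: float
    kap_h: float
    midpoint_kap: float
    n_events_in_window: int
    valid: bool


def extract_kap(axis_hours: Iterable[float],
                window: tuple[float, float] = (WINDOW_START, WINDOW_END)) -> KapEstimate:
    """Longest keystroke-absence period among events inside the window.

    ``axis_hours`` are event times on the night axis.  With fewer than two
    in-window events there is no bracketed gap and the night is invalid
    (all estimate fields NaN) — never an exception.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"degenerate window {window}")
    t = np.sort(np.asarray(list(axis_hours), dtype=float))
    t = t[(t >= lo) & (t <= hi)]  # bounds inclusive
    n = int(t.size)
    if n < 2:
        return KapEstimate(np.nan, np.nan, np.nan, np.nan, n, False)
    gaps = np.diff(t)
    i = int(np.argmax(gaps))  # earliest-starting gap wins ties
    last, first = float(t[i]), float(t[i + 1])
    if first == last:  # all events coincident: no gap at all
        return KapEstimate(np.nan, np.nan, np.nan, np.nan, n, False)
    return KapEstimate(last, first, first - last, 0.5 * (last + first), n, True)


def hours_with_activity(clock_hours: Iterable[float]) -> int:
    """Distinct hour-of-day bins (00-23) containing at least one keystroke."""
    h = np.asarray(list(clock_hours), dtype=float)
    if h.size == 0:
        return 0
    return int(np.unique(np.floor(h).astype(int) % 24).size)


class KapExtractor(BaseEstimator, TransformerMixin):
    """Transformer: keystroke event table -> nightly keyboard estimates.

    Parameters
    ----------
    timezone : str
        Local timezone used to place events on the night axis.
    window : (float, float)
        Nightly analysis window on the night axis; the default [7, 27]
        spans 7 PM to 3 PM the next day.
    """

    def __init__(self, timezone: str = "Europe/Amsterdam",
                 window: tuple[float, float] = (WINDOW_START, WINDOW_END)):
        self.timezone = timezone
        self.window = window

    def fit(self, X: pd.DataFrame, y=None) -> "KapExtractor":
        return self

    def _localized(self, events: pd.DataFrame) -> pd.DataFrame:
        ts = events["timestamp"]
        local = ts.dt.tz_convert(self.timezone) if ts.dt.tz is not None \
            else ts.dt.tz_localize(self.timezone)
        naive = local.dt.tz_localize(None)
        return pd.DataFrame({
            "participant_id": events["participant_id"].astype(str),
            "local": naive,
            "clock_h": (naive.dt.hour + naive.dt.minute / 60.0
                        + naive.dt.second / 3600.0
                        + naive.dt.microsecond / 3.6e9),
            "date": naive.dt.date,
        })

    def transform(self, X: pd.DataFrame,
                  participants: Iterable[str] | None = None,
                  date_range: tuple[dt.date, dt.date] | None = None) -> pd.DataFrame:
        """One row per participant x anchor date (invalid nights retained)."""
        nights, _ = self.transform_with_activity(X, participants, date_range)
        return nights

    def transform_with_activity(self, X: pd.DataFrame,
                                participants: Iterable[str] | None = None,
                                date_range: tuple[dt.date, dt.date] | None = None,
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Nightly estimate table plus the hours-with-activity day table."""
        if X.empty:
            logger.warning("extract_all_nights: empty event table")
            empty = pd.DataFrame(columns=ESTIMATE_COLUMNS)
            day = pd.DataFrame(columns=["participant_id", "calendar_date",
                                        "hours_with_activity"])
            return empty, day
        loc = self._localized(X)
        loc["anchor"] = anchor_for_event(loc["local"])

        day = (loc.groupby(["participant_id", "date"])["clock_h"]
               .agg(hours_with_activity).reset_index())
        day.columns = ["participant_id", "calendar_date", "hours_with_activity"]

        inwin = loc.dropna(subset=["anchor"]).copy()
        anchor_ts = pd.to_datetime(inwin["anchor"])
        inwin["axis"] = ((inwin["local"] - anchor_ts) / pd.Timedelta(hours=1)
                         - 12.0)

        if participants is None:
            participants = sorted(loc["participant_id"].unique())
        if date_range is None:
            anchors = sorted(inwin["anchor"].unique())
        else:
            d0, d1 = date_range
            anchors = [d0 + dt.timedelta(days=k)
                       for k in range((d1 - d0).days + 1)]

        grouped = {k: v["axis"].to_numpy()
                   for k, v in inwin.groupby(["participant_id", "anchor"])}
        rows = []
        for pid in participants:
            for anchor in anchors:
                est = extract_kap(grouped.get((pid, anchor), ()), self.window)
                rows.append((pid, anchor, *est))
        nights = pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
        if len(nights):
            logger.info("extract_all_nights: %d/%d nights valid (%.1f%%)",
                        int(nights["valid"].sum()), len(nights),
                        100.0 * nights["valid"].mean())
        return nights, day


def extract_all_nights(events: pd.DataFrame,
                       participants: Iterable[str] | None = None,
                       date_range: tuple[dt.date, dt.date] | None = None,
                       timezone: str = "Europe/Amsterdam",
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Functional wrapper over :class:`KapExtractor`."""
    return KapExtractor(timezone=timezone).transform_with_activity(
        events, participants, date_range)
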