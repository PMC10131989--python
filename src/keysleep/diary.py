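"""Self-reported rest-activity metrics from morning sleep-diary records.

Eight night-level metrics are derived per report, all exact arithmetic on
the night axis: bedtime, try-to-sleep, sleep onset (try-to-sleep + latency),
midsleep (midpoint of onset and offset), sleep offset, out-of-bed, total
sleep period (offset - onset) and total bed period (out-of-bed - bedtime).
A pooled 4-SD rule masks outliers per metric before any modeling.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .timeaxis import clock_to_axis

logger = logging.getLogger(__name__)

DERIVED_COLUMNS = ["participant_id", "anchor_date", "bedtime", "try_to_sleep",
                   "sleep_onset", "midsleep", "sleep_offset", "out_of_bed",
                   "total_sleep_period_h", "total_bed_period_h"]


class DiaryDeriver(BaseEstimator, TransformerMixin):
    """Transformer: raw diary records -> nightly diary estimates.

    Input is the table produced by :func:`keysleep.io.read_diary` (clock
    hours as floats).  Missing fields propagate to the derived values;
    ordering violations after mapping onto the night axis (e.g. out-of-bed
    before sleep offset) null only the affected derived fields.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "DiaryDeriver":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame({
            "participant_id": X["participant_id"].astype(str),
            "anchor_date": [d - dt.timedelta(days=1) if pd.notna(d) else pd.NaT
                            for d in X["report_date"]],
        })
        for col in ("bedtime", "try_to_sleep", "sleep_offset", "out_of_bed"):
            vals = pd.to_numeric(X[col], errors="coerce").astype(float)
            out[col] = clock_to_axis(vals.to_numpy())
        latency_h = pd.to_numeric(X["latency_min"], errors="coerce") / 60.0
        out["sleep_onset"] = out["try_to_sleep"] + latency_h.to_numpy()
        out["midsleep"] = 0.5 * (out["sleep_onset"] + out["sleep_offset"])
        out["total_sleep_period_h"] = out["sleep_offset"] - out["sleep_onset"]
        out["total_bed_period_h"] = out["out_of_bed"] - out["bedtime"]

        bad_sleep = out["total_sleep_period_h"] < 0
        bad_bed = (out["total_bed_period_h"] < 0) \
            | (out["out_of_bed"] < out["sleep_offset"]) \
            | (out["bedtime"] > out["try_to_sleep"])
        n_bad = int(bad_sleep.sum() + bad_bed.sum())
        if n_bad:
            logger.warning("derive_nights: %d ordering violation(s); affected "
                           "derived fields coded missing", n_bad)
        out.loc[bad_sleep, ["midsleep", "total_sleep_period_h"]] = np.nan
        out.loc[bad_bed, "total_bed_period_h"] = np.nan
        return out[DERIVED_COLUMNS]


def derive_nights(records: pd.DataFrame) -> pd.DataFrame:
    """Functional wrapper over :class:`DiaryDeriver`."""
    return DiaryDeriver().transform(records)


class OutlierFlagger(BaseEstimator, TransformerMixin):
    """Mask values more than ``k`` pooled SDs from the pooled mean.

    The rule is applied per metric column, pooled across participants and
    nights, in a single pass (statistics are frozen at :meth:`fit`, so
    repeated transforms are idempotent).  Columns with fewer than three
    non-missing values, or zero spread, are left untouched.
    """

    def __init__(self, k: float = 4.0, columns: list[str] | None = None):
        self.k = k
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None) -> "OutlierFlagger":
        cols = self.columns or [c for c in X.columns
                                if pd.api.types.is_numeric_dtype(X[c])]
        self.columns_ = list(cols)
        self.means_, self.sds_ = {}, {}
        for c in cols:
            vals = pd.to_numeric(X[c], errors="coerce")
            n = int(vals.notna().sum())
            if n == 0:
                logger.warning("OutlierFlagger: column %r is all-missing", c)
            if n < 3:
                self.means_[c], self.sds_[c] = np.nan, np.nan
                continue
            self.means_[c] = float(vals.mean())
            self.sds_[c] = float(vals.std(ddof=1))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        total = 0
        for c in self.columns_:
            m, s = self.means_[c], self.sds_[c]
            if not np.isfinite(m) or not np.isfinite(s) or s == 0:
                continue
            z = (pd.to_numeric(out[c], errors="coerce") - m) / s
            mask = z.abs() > self.k
            total += int(mask.sum())
            out[c] = out[c].mask(mask)
        if total:
            logger.info("OutlierFlagger: masked %d value(s) beyond %.1f SD",
                        total, self.k)
        return out


def flag_outliers(values: pd.Series, k: float = 4.0) -> pd.Series:
    """Boolean mask of values with pooled |z| > k (single pass)."""
    vals = pd.to_numeric(values, errors="coerce")
    if vals.notna().sum() < 3:
        if vals.notna().sum() == 0:
            logger.warning("flag_outliers: all-missing series")
        return pd.Series(False, index=values.index)
    m, s = vals.mean(), vals.std(ddof=1)
    if s == 0 or not np.isfinite(s):
        return pd.Series(False, index=values.index)
    return ((vals - m).abs() / s) > k
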