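"""Readers and writers for the external tables.

All on-disk formats are plain text: ``events.csv`` (or ``events.jsonl``)
with one row per keystroke, ``diary.csv`` with one morning report per row,
and ``traits.csv`` with one participant per row.  Readers validate strictly
and never silently alter a valid value; invalid diary values are coded
missing (the row is retained), unparseable event timestamps are an error.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .timeaxis import parse_clock

logger = logging.getLogger(__name__)

DIARY_COLUMNS = ["participant_id", "report_date", "bedtime", "try_to_sleep",
                 "latency_min", "sleep_offset", "out_of_bed", "woke_by_alarm"]
TRAIT_COLUMNS = ["participant_id", "msfsc", "psqi", "tsc"]


class SchemaError(ValueError):
    """A required column is missing or a file is structurally invalid."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


# --------------------------------------------------------------------------
# keystroke events
# --------------------------------------------------------------------------

def read_events(path: str | Path, default_timezone: str | None = None) -> pd.DataFrame:
    """Read a keystroke event table (CSV or JSON-lines).

    Timestamps must be ISO-8601.  Stamps without a UTC offset are localized
    to ``default_timezone``; if none is configured they are an error.  The
    result is sorted per participant with exact duplicates dropped (count
    logged).
    """
    path = Path(path)
    if path.suffix == ".jsonl":
        df = pd.read_json(path, lines=True, convert_dates=False)
    else:
        df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["participant_id", "timestamp"], path.name)
    raw = df["timestamp"].astype(str).str.strip()
    has_offset = raw.str.contains(r"(?:Z|[+-]\d{2}:?\d{2})$")

    def _parse(chunk: pd.Series, utc: bool) -> pd.Series:
        parsed = pd.to_datetime(chunk, format="ISO8601", utc=utc, errors="coerce")
        bad = np.flatnonzero(parsed.isna().to_numpy())
        if bad.size:
            line = chunk.index[bad[0]] + 1
            raise SchemaError(f"{path.name}: unparseable timestamp at data "
                              f"line {line}: {chunk.iloc[bad[0]]!r}")
        return parsed

    ts = pd.Series(pd.NaT, index=raw.index, dtype="datetime64[ns, UTC]")
    if has_offset.any():
        ts[has_offset] = _parse(raw[has_offset], utc=True)
    if (~has_offset).any():
        if default_timezone is None:
            line = int(np.flatnonzero(~has_offset.to_numpy())[0]) + 1
            raise SchemaError(
                f"{path.name}: timestamp without UTC offset at data line "
                f"{line} and no default timezone is configured")
        naive = _parse(raw[~has_offset], utc=False)
        ts[~has_offset] = naive.dt.tz_localize(
            default_timezone, ambiguous=True,
            nonexistent="shift_forward").dt.tz_convert("UTC")
    out = pd.DataFrame({"participant_id": df["participant_id"].astype(str),
                        "timestamp": ts})
    n0 = len(out)
    out = out.drop_duplicates().sort_values(
        ["participant_id", "timestamp"], kind="stable", ignore_index=True)
    if n0 - len(out):
        logger.warning("read_events: dropped %d exact duplicate record(s)",
                       n0 - len(out))
    return out


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write events as CSV or JSON-lines with explicit UTC offsets."""
    path = Path(path)
    ts = events["timestamp"]
    stamps = ts.dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    out = pd.DataFrame({"participant_id": events["participant_id"],
                        "timestamp": stamps})
    if path.suffix == ".jsonl":
        out.to_json(path, orient="records", lines=True)
    else:
        out.to_csv(path, index=False)


# --------------------------------------------------------------------------
# sleep diary
# --------------------------------------------------------------------------

def _clean_clock(series: pd.Series) -> pd.Series:
    def one(v):
        if pd.isna(v) or str(v).strip() == "":
            return np.nan
        try:
            return parse_clock(v)
        except ValueError:
            return np.nan
    return series.map(one)


def read_diary(path: str | Path) -> pd.DataFrame:
    """Read the morning sleep-diary CSV.

    Clock times come back as clock hours (floats); ambiguous or impossible
    values (unparseable times, negative latencies) are coded missing and the
    row is retained, with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, DIARY_COLUMNS, path.name)
    out = pd.DataFrame({"participant_id": df["participant_id"].astype(str)})
    out["report_date"] = pd.to_datetime(df["report_date"], errors="coerce").dt.date
    n_invalid = int(out["report_date"].isna().sum())
    for col in ("bedtime", "try_to_sleep", "sleep_offset", "out_of_bed"):
        vals = _clean_clock(df[col])
        n_invalid += int(vals.isna().sum() - df[col].isna().sum())
        out[col] = vals
    lat = pd.to_numeric(df["latency_min"], errors="coerce")
    bad_lat = lat < 0
    n_invalid += int(bad_lat.sum())
    out["latency_min"] = lat.mask(bad_lat)
    alarm = df["woke_by_alarm"].astype(str).str.strip().str.lower()
    out["woke_by_alarm"] = alarm.map(
        {"true": True, "false": False, "1": True, "0": False}).astype("boolean")
    if n_invalid:
        logger.warning("read_diary: coded %d ambiguous value(s) as missing",
                       n_invalid)
    return out


def write_diary(diary: pd.DataFrame, path: str | Path) -> None:
    """Write a raw diary table (clock strings as given) to CSV."""
    diary.loc[:, DIARY_COLUMNS].to_csv(path, index=False)


# --------------------------------------------------------------------------
# participant traits
# --------------------------------------------------------------------------

def read_traits(path: str | Path) -> pd.DataFrame:
    """Read the person-level trait table (chronotype, PSQI, TSC)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TRAIT_COLUMNS, path.name)
    out = df.copy()
    out["participant_id"] = out["participant_id"].astype(str)
    for col in ("msfsc", "psqi", "tsc"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    bad_psqi = ~out["psqi"].between(0, 21)
    bad_tsc = ~out["tsc"].between(1, 5)
    n = int(bad_psqi.sum() + bad_tsc.sum())
    if n:
        logger.warning("read_traits: coded %d out-of-range score(s) as missing", n)
    out["psqi"] = out["psqi"].mask(bad_psqi)
    out["tsc"] = out["tsc"].mask(bad_tsc)
    return out


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, index=False)
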