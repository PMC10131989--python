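"""Shared helpers for the test suite."""

import pandas as pd

from keysleep.timeaxis import parse_clock


def diary_roundtrip(diaries: pd.DataFrame) -> pd.DataFrame:
    """Raw diary table (clock strings) -> parsed records, bypassing disk."""
    out = pd.DataFrame({
        "participant_id": diaries["participant_id"].astype(str),
        "report_date": diaries["report_date"],
    })
    for c in ("bedtime", "try_to_sleep", "sleep_offset", "out_of_bed"):
        out[c] = diaries[c].map(parse_clock)
    out["latency_min"] = diaries["latency_min"].astype(float)
    out["woke_by_alarm"] = diaries["woke_by_alarm"].astype(bool)
    return out
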