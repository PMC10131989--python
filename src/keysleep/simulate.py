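"""Synthetic cohort generator with a known ground-truth sleep model.

Each participant carries a chronotype offset, a habitual sleep-duration
offset, a personal keystroke rate and an in-bed phone-use propensity.  Each
night, true bedtime, try-to-sleep, onset, offset and out-of-bed times are
drawn on the night axis; the keystroke stream is a homogeneous Poisson
process during the wake period, silenced between bedtime (or try-to-sleep,
on in-bed-use nights) and out-of-bed, except for sleep-quality-dependent
nocturnal awakening bursts.  Diaries report the truth plus Gaussian noise
rounded to the 5-minute grid.  Everything is deterministic given the seed,
with per-participant substreams, so any slice can be regenerated.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import SimConfig
from .timeaxis import format_clock, noon_of

logger = logging.getLogger(__name__)

#: probability of waking by alarm, by day type (weekday / weekend morning)
P_ALARM_WEEKDAY = 0.60
P_ALARM_WEEKEND = 0.46

_MAX_NIGHT_RETRIES = 100


class SimulatedCohort(NamedTuple):
    events: pd.DataFrame   # participant_id, timestamp (tz-aware)
    diaries: pd.DataFrame  # raw diary table (clock strings, 5-min grid)
    traits: pd.DataFrame   # participant_id, msfsc, psqi, tsc, social_jetlag_h
    truth: pd.DataFrame    # ground-truth night table (night-axis hours)


@dataclass
class PersonParams:
    participant_id: str
    chronotype_offset_h: float
    sleep_offset_h: float
    rate_per_h: float
    p_inbed: float
    psqi: int
    tsc: float


class NightResult(NamedTuple):
    truth: dict
    diary: dict
    event_axis_h: np.ndarray  # night-axis hours, within [7, 27]


def _draw_person(pid: str, cfg: SimConfig, rng: np.random.Generator) -> PersonParams:
    c = rng.normal(0.0, cfg.sd_chronotype_h)
    d = rng.normal(0.0, cfg.sd_sleep_person_h)
    # mean-preserving lognormal spread of the personal keystroke rate
    rate = cfg.keystroke_rate_per_h * np.exp(
        rng.normal(-0.5 * cfg.rate_sigma**2, cfg.rate_sigma))
    p = cfg.p_inbed_use
    if 0.0 < p < 1.0:
        kappa = 8.0  # concentration of the in-bed-use propensity across people
        p = rng.beta(p * kappa, (1.0 - p) * kappa)
    psqi = int(np.clip(np.round(rng.normal(cfg.psqi_mean, cfg.psqi_sd)), 0, 21))
    tsc = float(np.clip(rng.normal(cfg.tsc_mean, cfg.tsc_sd), 1.0, 5.0))
    return PersonParams(pid, float(c), float(d), float(rate), float(p), psqi, tsc)


def _round5(axis_h: float) -> float:
    """Round a night-axis time to the diary's 5-minute grid."""
    return round(axis_h * 12.0) / 12.0


def simulate_night(person: PersonParams, anchor_date: dt.date, cfg: SimConfig,
                   rng: np.random.Generator, weekend: bool) -> NightResult:
    """One participant-night: ground truth, diary report, in-window events.

    Returned event times are night-axis hours restricted to the nightly
    analysis window [7, 27] (7 PM to 3 PM next day).  Daytime filler outside
    the window is added by :func:`simulate_cohort`.
    """
    mu = cfg.mu_try_sleep - 12.0  # to night-axis hours
    for _ in range(_MAX_NIGHT_RETRIES):
        try_sleep = mu + person.chronotype_offset_h + rng.normal(0.0, cfg.sd_night_h)
        if weekend:
            try_sleep += cfg.weekend_delay_h
        prebed = rng.exponential(cfg.mean_prebed_gap_h) if cfg.mean_prebed_gap_h else 0.0
        bedtime = try_sleep - prebed
        latency_h = (rng.exponential(cfg.mean_latency_min / 60.0)
                     if cfg.mean_latency_min else 0.0)
        onset = try_sleep + latency_h
        dur = rng.normal(cfg.mean_sleep_h + person.sleep_offset_h, cfg.sd_sleep_h)
        offset = onset + dur
        rise = rng.exponential(cfg.mean_rise_lag_h) if cfg.mean_rise_lag_h else 0.0
        out_of_bed = offset + rise
        if dur >= 2.0 and bedtime > 7.5 and out_of_bed < 26.5:
            break
    else:
        raise RuntimeError(
            f"could not draw a valid night for {person.participant_id} "
            f"on {anchor_date} after {_MAX_NIGHT_RETRIES} attempts")

    # --- keystroke process inside the window -------------------------------
    # phone-away and pick-up behavior does not track the diary anchors
    # exactly: independent jitter, bounded so no wake typing leaks into the
    # sleep period (in-bed use runs until try-to-sleep instead)
    inbed = rng.random() < person.p_inbed
    jitter = cfg.sd_phone_behavior_h
    if inbed:
        evening_end = try_sleep
    else:
        evening_end = min(bedtime + (rng.normal(0.0, jitter) if jitter else 0.0),
                          try_sleep)
    resume = max(offset,
                 out_of_bed + (rng.normal(0.0, jitter) if jitter else 0.0))
    pieces = [_poisson_times(7.0, evening_end, person.rate_per_h, rng),
              _poisson_times(min(resume, 27.0), 27.0, person.rate_per_h, rng)]

    n_awakenings = (rng.poisson(cfg.awakening_rate_per_psqi * person.psqi)
                    if cfg.awakening_rate_per_psqi else 0)
    for _ in range(n_awakenings):
        if rng.random() < cfg.p_keystroke_on_awakening:
            t0 = rng.uniform(onset, offset)
            m = rng.integers(1, 6)
            burst = t0 + np.sort(rng.uniform(0.0, 10.0 / 60.0, size=m))
            pieces.append(burst[burst < offset])
    events = np.sort(np.concatenate(pieces))
    # exact simultaneity has probability zero but would break strict ordering
    events = np.unique(events)

    noise_h = cfg.diary_noise_sd_min / 60.0

    def report(x: float) -> float:
        return _round5(x + rng.normal(0.0, noise_h) if noise_h else x)

    rep_bedtime = report(bedtime)
    rep_try = report(try_sleep)
    rep_offset = report(offset)
    rep_oob = report(out_of_bed)
    # diarists report internally consistent orderings even when imprecise
    rep_bedtime = min(rep_bedtime, rep_try)
    rep_oob = max(rep_oob, rep_offset)
    rep_latency = latency_h * 60.0 + (rng.normal(0.0, cfg.diary_noise_sd_min)
                                      if noise_h else 0.0)
    rep_latency = max(0.0, 5.0 * round(rep_latency / 5.0))
    p_alarm = P_ALARM_WEEKEND if weekend else P_ALARM_WEEKDAY

    truth = {
        "participant_id": person.participant_id,
        "anchor_date": anchor_date,
        "true_bedtime": bedtime,
        "true_try_sleep": try_sleep,
        "true_sleep_onset": onset,
        "true_sleep_offset": offset,
        "true_out_of_bed": out_of_bed,
        "n_awakenings": int(n_awakenings),
        "weekend": bool(weekend),
    }
    diary = {
        "participant_id": person.participant_id,
        "report_date": anchor_date + dt.timedelta(days=1),
        "bedtime": format_clock(rep_bedtime),
        "try_to_sleep": format_clock(rep_try),
        "latency_min": rep_latency,
        "sleep_offset": format_clock(rep_offset),
        "out_of_bed": format_clock(rep_oob),
        "woke_by_alarm": bool(rng.random() < p_alarm),
    }
    return NightResult(truth, diary, events)


def _poisson_times(start: float, end: float, rate: float,
                   rng: np.random.Generator) -> np.ndarray:
    if end <= start or rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * (end - start))
    return np.sort(rng.uniform(start, end, size=n))


def simulate_cohort(config: SimConfig | None = None) -> SimulatedCohort:
    """Generate keystroke events, diaries, traits and truth for a cohort."""
    cfg = config or SimConfig()
    cfg.validate()
    master = np.random.SeedSequence(cfg.seed)
    streams = master.spawn(cfg.n_participants)
    width = max(3, len(str(cfg.n_participants)))

    truth_rows, diary_rows, trait_rows = [], [], []
    ev_pid, ev_hours = [], []
    for i in range(cfg.n_participants):
        rng = np.random.default_rng(streams[i])
        pid = f"P{i + 1:0{width}d}"
        person = _draw_person(pid, cfg, rng)
        abs_hours = []
        for j in range(cfg.n_nights):
            anchor = cfg.start_date + dt.timedelta(days=j)
            weekend = (anchor + dt.timedelta(days=1)).weekday() >= 5
            night = simulate_night(person, anchor, cfg, rng, weekend)
            truth_rows.append(night.truth)
            diary_rows.append(night.diary)
            abs_hours.append(night.event_axis_h + 24.0 * j)
            # daytime filler outside the nightly window (3 PM - 7 PM, and the
            # first afternoon before the first window) keeps the
            # hours-with-activity covariate defined for every calendar day
            if j == 0:
                abs_hours.append(_poisson_times(0.0, 7.0, person.rate_per_h, rng))
            if j < cfg.n_nights - 1:
                abs_hours.append(
                    _poisson_times(27.0, 31.0, person.rate_per_h, rng) + 24.0 * j)
        hours = np.sort(np.concatenate(abs_hours))
        ev_pid.append(np.repeat(pid, hours.size))
        ev_hours.append(hours)

        midsleep_free_clock = ((cfg.mu_try_sleep - 24.0)
                               + person.chronotype_offset_h + cfg.weekend_delay_h
                               + cfg.mean_latency_min / 60.0
                               + 0.5 * (cfg.mean_sleep_h + person.sleep_offset_h)
                               + rng.normal(0.0, 0.25))
        trait_rows.append({
            "participant_id": pid,
            "msfsc": round(midsleep_free_clock % 24.0, 3),
            "psqi": person.psqi,
            "tsc": round(person.tsc, 3),
            "social_jetlag_h": round(abs(cfg.weekend_delay_h
                                         + rng.normal(0.0, 0.6)), 3),
        })

    noon0 = pd.Timestamp(noon_of(cfg.start_date, cfg.timezone))
    all_hours = np.concatenate(ev_hours)
    stamps = noon0 + pd.to_timedelta(np.round(all_hours * 3600.0, 3), unit="s")
    events = pd.DataFrame({
        "participant_id": np.concatenate(ev_pid),
        "timestamp": stamps,
    }).sort_values(["participant_id", "timestamp"], kind="stable",
                   ignore_index=True)

    truth = pd.DataFrame(truth_rows)
    diaries = pd.DataFrame(diary_rows)
    traits = pd.DataFrame(trait_rows)
    logger.info("simulated cohort: %d participants, %d nights, %d events",
                cfg.n_participants, cfg.n_nights, len(events))
    return SimulatedCohort(events, diaries, traits, truth)
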