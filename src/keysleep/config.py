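"""Simulation configuration: the study conditions of the synthetic cohort.

Defaults emulate a one-week experience-sampling cohort of ~157 students with
parallel smartphone keyboard logging: mean try-to-sleep time around 00:30,
~7.75 h of sleep, moderate between-person timing spread (timing ICCs in the
low .2s), a modest weekday-to-weekend delay, and sleep-quality-dependent
nocturnal phone checks.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass

import yaml


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass
class SimConfig:
    """Ground-truth circadian sleep model and keystroke-process parameters.

    Times are clock hours on the night axis (hours since noon of the anchor
    evening; 24.5 = 00:30), durations in hours, latencies in minutes.
    """

    n_participants: int = 157
    n_nights: int = 7
    start_date: dt.date = dt.date(2020, 9, 14)  # a Monday
    #: population mean try-to-sleep time, extended clock hours (24.5 = 00:30)
    mu_try_sleep: float = 24.5
    #: between-person SD of sleep timing (chronotype offset), hours
    sd_chronotype_h: float = 0.75
    #: night-to-night within-person SD of sleep timing, hours
    sd_night_h: float = 1.25
    #: mean delay of sleep timing on weekend nights, hours
    weekend_delay_h: float = 0.5
    #: mean sleep-onset latency, minutes (exponential)
    mean_latency_min: float = 16.0
    #: mean nightly sleep duration (onset to offset), hours
    mean_sleep_h: float = 7.75
    #: within-person SD of sleep duration, hours
    sd_sleep_h: float = 1.1
    #: between-person SD of sleep duration, hours (keeps duration ICC > 0)
    sd_sleep_person_h: float = 0.45
    #: mean time in bed before trying to sleep, hours (exponential)
    mean_prebed_gap_h: float = 0.5
    #: mean time from sleep offset to getting out of bed, hours (exponential)
    mean_rise_lag_h: float = 0.5
    #: wake-period homogeneous Poisson keystroke rate, events/hour
    keystroke_rate_per_h: float = 60.0
    #: between-person log-scale SD of the keystroke rate
    rate_sigma: float = 0.4
    #: probability a night's keyboard use continues in bed until try-to-sleep
    p_inbed_use: float = 0.25
    #: SD of the independent behavioral offsets between phone-away time and
    #: bedtime, and between phone pick-up and out-of-bed time, hours
    sd_phone_behavior_h: float = 0.6
    #: expected nocturnal awakenings per PSQI point
    awakening_rate_per_psqi: float = 0.05
    #: probability an awakening emits a keystroke burst
    p_keystroke_on_awakening: float = 0.2
    #: SD of additive diary reporting noise, minutes (then 5-min rounding)
    diary_noise_sd_min: float = 15.0
    psqi_mean: float = 5.16
    psqi_sd: float = 2.27
    tsc_mean: float = 2.98
    tsc_sd: float = 0.56
    timezone: str = "Europe/Amsterdam"
    seed: int = 20200914

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if isinstance(self.start_date, str):
            self.start_date = dt.date.fromisoformat(self.start_date)
        counts = {"n_participants": 1, "n_nights": 1}
        for name, lo in counts.items():
            v = getattr(self, name)
            if not isinstance(v, int) or v < lo:
                raise ConfigError(f"{name} must be an integer >= {lo}, got {v!r}")
        nonneg = [
            "sd_chronotype_h", "sd_night_h", "mean_latency_min", "mean_sleep_h",
            "sd_sleep_h", "sd_sleep_person_h", "mean_prebed_gap_h",
            "mean_rise_lag_h", "keystroke_rate_per_h", "rate_sigma",
            "sd_phone_behavior_h",
            "awakening_rate_per_psqi", "diary_noise_sd_min", "psqi_sd", "tsc_sd",
        ]
        for name in nonneg:
            v = getattr(self, name)
            if not (v >= 0):
                raise ConfigError(f"{name} must be >= 0, got {v!r}")
        for name in ("p_inbed_use", "p_keystroke_on_awakening"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        if self.keystroke_rate_per_h <= 0:
            raise ConfigError("keystroke_rate_per_h must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["start_date"] = self.start_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config field(s): {sorted(extra)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)
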