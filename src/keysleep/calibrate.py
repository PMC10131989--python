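"""Monte-Carlo parameter-recovery harnesses for the analysis models.

Each function simulates data from a known generative design and pushes it
through the package's own estimators, returning per-replicate results.
They quantify whether the pipeline recovers what it claims to estimate:
variance components (ICC), standardized slopes and their CI coverage,
random-slope SDs and likelihood-ratio detection rates, and cross-level
trait moderation.  The TOST calibration harness lives in
:mod:`keysleep.agreement`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import IccEstimator
from .mlm import AssociationModel, CrossLevelModel, RandomSlopeModel


@dataclass
class IccSimSpec:
    n_participants: int = 200
    n_nights: int = 7
    var_between: float = 1.0
    var_within: float = 3.0

    @property
    def true_icc(self) -> float:
        return self.var_between / (self.var_between + self.var_within)


def icc_recovery(spec: IccSimSpec, n_reps: int,
                 seed: int | None = None) -> np.ndarray:
    """ICC estimates over replicates of a two-level Gaussian design."""
    rng = np.random.default_rng(seed)
    n, k = spec.n_participants, spec.n_nights
    pids = np.repeat(np.arange(n), k)
    out = np.empty(n_reps)
    for r in range(n_reps):
        a = rng.normal(0.0, np.sqrt(spec.var_between), size=n)[pids]
        vals = a + rng.normal(0.0, np.sqrt(spec.var_within), size=n * k)
        df = pd.DataFrame({"participant_id": pids, "value": vals})
        out[r] = IccEstimator(value_col="value").fit(df).icc_
    return out


@dataclass
class AssocSimSpec:
    """Standardized random-intercept design: the predictor is a unit-variance
    two-level variable, the outcome has true standardized slope ``beta`` and
    unit total variance split across slope, intercept and residual."""
    n_participants: int = 150
    n_nights: int = 7
    beta: float = 0.75
    icc_x: float = 0.25
    var_intercept: float = 0.15

    @property
    def var_resid(self) -> float:
        v = 1.0 - self.beta**2 - self.var_intercept
        if v <= 0:
            raise ValueError("beta and var_intercept imply negative residual")
        return v


def _draw_x(spec, rng, pids, n, k):
    a = rng.normal(0.0, np.sqrt(spec.icc_x), size=n)[pids]
    return a + rng.normal(0.0, np.sqrt(1.0 - spec.icc_x), size=n * k)


def association_recovery(spec: AssocSimSpec, n_reps: int,
                         seed: int | None = None) -> pd.DataFrame:
    """Slope estimates and 99%-CI coverage of the true standardized slope."""
    rng = np.random.default_rng(seed)
    n, k = spec.n_participants, spec.n_nights
    pids = np.repeat(np.arange(n), k)
    rows = []
    for _ in range(n_reps):
        x = _draw_x(spec, rng, pids, n, k)
        u = rng.normal(0.0, np.sqrt(spec.var_intercept), size=n)[pids]
        y = spec.beta * x + u + rng.normal(0.0, np.sqrt(spec.var_resid),
                                           size=n * k)
        paired = pd.DataFrame({"participant_id": pids, "keyboard": x,
                               "diary": y})
        m = AssociationModel().fit(paired)
        lo, hi = m.ci99_
        rows.append({"beta_hat": m.beta_, "ci_lo": lo, "ci_hi": hi,
                     "covered": lo <= spec.beta <= hi, "p": m.p_})
    return pd.DataFrame(rows)


@dataclass
class SlopeSimSpec:
    n_participants: int = 150
    n_nights: int = 7
    beta: float = 0.75
    slope_sd: float = 0.35
    intercept_sd: float = 0.4
    resid_sd: float = 0.5


def random_slope_recovery(spec: SlopeSimSpec, n_reps: int,
                          seed: int | None = None) -> pd.DataFrame:
    """Recovered slope SDs and LRT p values over replicates."""
    rng = np.random.default_rng(seed)
    n, k = spec.n_participants, spec.n_nights
    pids = np.repeat(np.arange(n), k)
    rows = []
    for _ in range(n_reps):
        x = rng.normal(0.0, 1.0, size=n * k)
        slope = spec.beta + rng.normal(0.0, spec.slope_sd, size=n)[pids]
        u = rng.normal(0.0, spec.intercept_sd, size=n)[pids]
        y = u + slope * x + rng.normal(0.0, spec.resid_sd, size=n * k)
        paired = pd.DataFrame({"participant_id": pids, "keyboard": x,
                               "diary": y})
        m = RandomSlopeModel().fit(paired)
        rows.append({"slope_sd_hat": m.slope_sd_, "lrt_p": m.lrt_p_,
                     "boundary": m.boundary_})
    return pd.DataFrame(rows)


@dataclass
class CrossLevelSimSpec:
    """Sleep-quality-dependent slope attenuation: each participant's
    within-person slope is ``beta + gamma_psqi * (psqi - mean psqi)``; the
    other traits are independent of the slopes."""
    n_participants: int = 157
    n_nights: int = 7
    beta: float = 0.75
    gamma_psqi: float = -0.04
    slope_noise_sd: float = 0.12
    intercept_sd: float = 0.4
    resid_sd: float = 0.5
    psqi_mean: float = 5.16
    psqi_sd: float = 2.27


def cross_level_recovery(spec: CrossLevelSimSpec, n_reps: int,
                         seed: int | None = None) -> pd.DataFrame:
    """Estimated psqi x slope interaction and its p value per replicate."""
    rng = np.random.default_rng(seed)
    n, k = spec.n_participants, spec.n_nights
    pids = np.repeat(np.arange(n), k)
    rows = []
    for _ in range(n_reps):
        psqi = np.clip(np.round(rng.normal(spec.psqi_mean, spec.psqi_sd,
                                           size=n)), 0, 21)
        traits = pd.DataFrame({
            "participant_id": [str(i) for i in range(n)],
            "msfsc": rng.normal(4.8, 1.0, size=n),
            "psqi": psqi,
            "tsc": np.clip(rng.normal(2.98, 0.56, size=n), 1, 5),
        })
        slope = (spec.beta + spec.gamma_psqi * (psqi - psqi.mean())
                 + rng.normal(0.0, spec.slope_noise_sd, size=n))[pids]
        x = rng.normal(0.0, 1.0, size=n * k)
        u = rng.normal(0.0, spec.intercept_sd, size=n)[pids]
        y = u + slope * x + rng.normal(0.0, spec.resid_sd, size=n * k)
        paired = pd.DataFrame({"participant_id": pids.astype(str),
                               "keyboard": x, "diary": y})
        m = CrossLevelModel().fit(paired, traits=traits)
        term = "x_c:psqi_gc"
        rows.append({"gamma_hat": m.coefs_.loc[term, "beta"],
                     "p": m.coefs_.loc[term, "p"],
                     "vif_flag": m.vif_flag_})
    return pd.DataFrame(rows)
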