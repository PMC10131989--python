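"""Agreement between keyboard-derived and self-reported estimates.

Eight metric pairs are compared: last keystroke against bedtime,
try-to-sleep and sleep onset; midpoint KAP against midsleep; first keystroke
against sleep offset and out-of-bed; and KAP against total sleep and total
bed period.  Difference scores follow the convention keyboard minus diary,
so a negative difference means an earlier timing or shorter duration for the
keyboard-derived estimate.

Inference mirrors a stacked multilevel design: both modalities of a night
enter as rows, modality is a fixed factor, and participant is the only
random intercept.  Significance uses alpha = .01 (99% CI); equivalence is
the two one-sided tests criterion, declared when the 98% CI lies inside the
bounds (0.5 h and 1.0 h).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._mixed import DF_METHOD, fit_mixedlm, residual_df

logger = logging.getLogger(__name__)

#: (label, keyboard column, diary column, kind)
METRIC_PAIRS = [
    ("last_keystroke~bedtime", "last_keystroke", "bedtime", "timing"),
    ("last_keystroke~try_to_sleep", "last_keystroke", "try_to_sleep", "timing"),
    ("last_keystroke~sleep_onset", "last_keystroke", "sleep_onset", "timing"),
    ("midpoint_kap~midsleep", "midpoint_kap", "midsleep", "timing"),
    ("first_keystroke~sleep_offset", "first_keystroke", "sleep_offset", "timing"),
    ("first_keystroke~out_of_bed", "first_keystroke", "out_of_bed", "timing"),
    ("kap~total_sleep_period", "kap_h", "total_sleep_period_h", "duration"),
    ("kap~total_bed_period", "kap_h", "total_bed_period_h", "duration"),
]

TIMING_PAIRS = [p[0] for p in METRIC_PAIRS if p[3] == "timing"]
DURATION_PAIRS = [p[0] for p in METRIC_PAIRS if p[3] == "duration"]


def pair_nights(keyboard: pd.DataFrame, diary: pd.DataFrame,
                day_activity: pd.DataFrame | None = None,
                ) -> dict[str, pd.DataFrame]:
    """Align the two modalities per metric pair (full outer join on night).

    Weekend nights are those whose morning falls on Saturday or Sunday.
    ``hours_prev_day`` / ``hours_next_day`` are the hours-with-activity
    counts for the anchor date and the morning date.
    """
    keys = ["participant_id", "anchor_date"]
    merged = keyboard.merge(diary, on=keys, how="outer",
                            suffixes=("_kb", "_dy"))
    if merged.empty:
        logger.warning("pair_nights: no overlapping participant-nights")
    anchor = pd.to_datetime(merged["anchor_date"])
    merged["type_of_day"] = np.where(
        (anchor + pd.Timedelta(days=1)).dt.dayofweek >= 5, "weekend", "weekday")
    if day_activity is not None and len(day_activity):
        act = day_activity.copy()
        act["calendar_date"] = pd.to_datetime(act["calendar_date"]).dt.date
        lut = act.set_index(["participant_id", "calendar_date"])[
            "hours_with_activity"]
        dates = [d.date() if hasattr(d, "date") else d for d in anchor]
        merged["hours_prev_day"] = [
            lut.get((p, d), np.nan)
            for p, d in zip(merged["participant_id"], dates)]
        merged["hours_next_day"] = [
            lut.get((p, d + dt.timedelta(days=1)), np.nan)
            for p, d in zip(merged["participant_id"], dates)]
    else:
        merged["hours_prev_day"] = np.nan
        merged["hours_next_day"] = np.nan

    out: dict[str, pd.DataFrame] = {}
    for label, kb_col, dy_col, _kind in METRIC_PAIRS:
        df = merged[keys + ["type_of_day", "hours_prev_day",
                            "hours_next_day"]].copy()
        df["keyboard"] = pd.to_numeric(merged.get(kb_col), errors="coerce")
        df["diary"] = pd.to_numeric(merged.get(dy_col), errors="coerce")
        df["diff_h"] = df["keyboard"] - df["diary"]
        out[label] = df
    return out


# --------------------------------------------------------------------------
# intraclass correlation from the unconditional model
# --------------------------------------------------------------------------

class IccEstimator(BaseEstimator):
    """Intraclass correlation from a random-intercept-only (null) model.

    Fitted attributes: ``icc_`` (between-person share of variance),
    ``var_between_``, ``var_within_``, ``singular_`` (True when the
    between-person variance collapsed to zero).
    """

    def __init__(self, value_col: str = "value",
                 group_col: str = "participant_id"):
        self.value_col = value_col
        self.group_col = group_col

    def fit(self, X: pd.DataFrame, y=None) -> "IccEstimator":
        df = X[[self.group_col, self.value_col]].dropna()
        df = df.rename(columns={self.value_col: "value"})
        sizes = df.groupby(self.group_col).size()
        if len(sizes) < 2 or (sizes >= 2).sum() < 2:
            raise ValueError(
                "ICC requires >=2 participants with >=2 observations each; "
                "between- and within-variance are not separable")
        res, converged = fit_mixedlm("value ~ 1", df, df[self.group_col])
        vb = float(np.asarray(res.cov_re)[0, 0])
        vw = float(res.scale)
        self.singular_ = bool(vb <= 1e-10 or not converged)
        if vb <= 1e-10:
            vb = 0.0
        self.var_between_, self.var_within_ = vb, vw
        self.icc_ = vb / (vb + vw) if (vb + vw) > 0 else 0.0
        self.n_obs_, self.n_groups_ = len(df), len(sizes)
        return self


def icc_unconditional(values: pd.Series, groups: pd.Series) -> IccEstimator:
    """Functional wrapper: ICC of ``values`` clustered by ``groups``."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "participant_id": np.asarray(groups)})
    return IccEstimator().fit(df)


# --------------------------------------------------------------------------
# NHST + TOST equivalence on stacked data
# --------------------------------------------------------------------------

@dataclass
class EquivalenceResult:
    label: str
    mean_diff_h: float
    se: float
    df: float
    nhst_t: float
    nhst_p: float
    ci99: tuple[float, float]
    ci98: tuple[float, float]
    tost_p: dict[float, float]
    equivalent: dict[float, bool]
    n_obs: int
    n_participants: int
    fallback: bool = False
    df_method: str = DF_METHOD

    def to_dict(self) -> dict:
        d = {
            "label": self.label, "mean_diff_h": self.mean_diff_h,
            "se": self.se, "df": self.df, "nhst_t": self.nhst_t,
            "nhst_p": self.nhst_p, "ci99": list(self.ci99),
            "ci98": list(self.ci98), "n_obs": self.n_obs,
            "n_participants": self.n_participants, "fallback": self.fallback,
            "df_method": self.df_method,
        }
        for b, p in self.tost_p.items():
            d[f"tost_p_at_{b:g}"] = p
        for b, e in self.equivalent.items():
            d[f"equivalent_at_{b:g}"] = bool(e)
        return d


class EquivalenceTester(BaseEstimator):
    """Modality difference test on stacked paired nights.

    The two modalities of each complete night enter as two rows; the model
    has a modality fixed effect and a participant random intercept, so the
    modality coefficient is the mean keyboard-minus-diary difference.  NHST
    uses the 99% CI (alpha .01); TOST declares equivalence at a bound when
    the 98% CI lies strictly inside it.
    """

    def __init__(self, bounds: tuple[float, ...] = (0.5, 1.0),
                 alpha: float = 0.01, min_participants: int = 10,
                 label: str = ""):
        self.bounds = bounds
        self.alpha = alpha
        self.min_participants = min_participants
        self.label = label

    def fit(self, X: pd.DataFrame, y=None) -> "EquivalenceTester":
        df = X.dropna(subset=["keyboard", "diary"])
        n_part = df["participant_id"].nunique()
        if n_part < self.min_participants:
            raise ValueError(f"need >= {self.min_participants} participants "
                             f"with both modalities, got {n_part}")
        stacked = pd.DataFrame({
            "value": np.concatenate([df["keyboard"], df["diary"]]),
            "modality": np.repeat([1.0, 0.0], len(df)),
            "participant_id": np.tile(df["participant_id"].to_numpy(), 2),
        })
        fallback = False
        diffs = (df["keyboard"] - df["diary"]).to_numpy()
        if np.var(stacked["value"]) < 1e-12:
            est, se = float(np.mean(diffs)), 0.0
            dof = residual_df(len(diffs), n_part, 1)
            fallback = True
        else:
            try:
                res, converged = fit_mixedlm("value ~ modality", stacked,
                                             stacked["participant_id"])
                est = float(res.params["modality"])
                se = float(res.bse_fe["modality"])
                dof = residual_df(len(stacked), n_part, 2)
                fallback = not converged
            except Exception:  # degenerate variance structure
                fallback = True
                est = float(np.mean(diffs))
                se = float(np.std(diffs, ddof=1) / np.sqrt(len(diffs)))
                dof = float(len(diffs) - 1)
        if fallback and se == 0.0:
            se = float(np.std(diffs, ddof=1) / np.sqrt(len(diffs))) or 0.0

        tdist = stats.t(dof)
        tval = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
        nhst_p = float(2 * tdist.sf(abs(tval))) if np.isfinite(tval) else (
            0.0 if est else 1.0)
        q99 = tdist.ppf(1 - self.alpha / 2)       # 99% CI for NHST
        q98 = tdist.ppf(1 - self.alpha)           # 98% CI for TOST
        ci99 = (est - q99 * se, est + q99 * se)
        ci98 = (est - q98 * se, est + q98 * se)
        tost_p, equivalent = {}, {}
        for b in self.bounds:
            if se > 0:
                p_lower = float(tdist.sf((est + b) / se))
                p_upper = float(tdist.sf((b - est) / se))
                tost_p[b] = max(p_lower, p_upper)
            else:
                tost_p[b] = 0.0 if abs(est) < b else 1.0
            equivalent[b] = bool(ci98[0] > -b and ci98[1] < b)

        self.result_ = EquivalenceResult(
            label=self.label, mean_diff_h=est, se=se, df=dof,
            nhst_t=float(tval), nhst_p=nhst_p, ci99=ci99, ci98=ci98,
            tost_p=tost_p, equivalent=equivalent, n_obs=len(df),
            n_participants=int(n_part), fallback=fallback)
        self.mean_diff_h_ = est
        self.se_ = se
        self.df_ = dof
        self.nhst_p_ = nhst_p
        self.ci99_, self.ci98_ = ci99, ci98
        self.equivalent_ = equivalent
        self.tost_p_ = tost_p
        return self


def test_difference(paired: pd.DataFrame, label: str = "",
                    bounds: tuple[float, ...] = (0.5, 1.0),
                    alpha: float = 0.01) -> EquivalenceResult:
    """Functional wrapper over :class:`EquivalenceTester`."""
    tester = EquivalenceTester(bounds=bounds, alpha=alpha, label=label)
    return tester.fit(paired).result_


test_difference.__test__ = False  # not a pytest case despite the field term


# --------------------------------------------------------------------------
# repeated-measures Bland-Altman
# --------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    bias: float
    loa_lower: float
    loa_upper: float
    var_between: float
    var_within: float
    table: pd.DataFrame = field(repr=False, default=None)


def bland_altman_rm(paired: pd.DataFrame) -> BlandAltmanResult:
    """Repeated-measures Bland-Altman summary of keyboard-minus-diary diffs.

    The bias is the intercept of a random-intercept model on the
    differences; limits of agreement are bias +/- 1.96 * sqrt of the total
    (between + within) difference variance, so they describe single new
    nights rather than participant means.
    """
    df = paired.dropna(subset=["keyboard", "diary"]).copy()
    df["diff_h"] = df["keyboard"] - df["diary"]
    df["mean_h"] = 0.5 * (df["keyboard"] + df["diary"])
    if len(df) == 0:
        raise ValueError("no complete pairs")
    if np.var(df["diff_h"]) < 1e-12:
        bias, vb, vw = float(df["diff_h"].mean()), 0.0, 0.0
    else:
        res, _ = fit_mixedlm("diff_h ~ 1", df, df["participant_id"])
        bias = float(res.params["Intercept"])
        vb = max(float(np.asarray(res.cov_re)[0, 0]), 0.0)
        vw = float(res.scale)
    half = 1.96 * np.sqrt(vb + vw)
    table = (df.groupby("participant_id")[["mean_h", "diff_h"]]
             .mean().reset_index())
    return BlandAltmanResult(bias, bias - half, bias + half, vb, vw,
                             table=table)


# --------------------------------------------------------------------------
# Monte-Carlo calibration of the TOST procedure
# --------------------------------------------------------------------------

@dataclass
class TostSimSpec:
    """Generative spec for TOST calibration: a stacked paired design with a
    participant intercept (between_sd) and independent residuals
    (within_sd), and a constant true modality difference."""
    n_participants: int = 150
    n_nights: int = 7
    true_diff_h: float = 0.0
    between_sd: float = 0.5
    within_sd: float = 1.0
    bound: float = 0.5


def tost_calibration(spec: TostSimSpec, n_reps: int,
                     seed: int | None = None) -> float:
    """Monte-Carlo rate at which equivalence is declared at ``spec.bound``."""
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    n, k = spec.n_participants, spec.n_nights
    pids = np.repeat(np.arange(n), k)
    declared = 0
    for _ in range(n_reps):
        a = rng.normal(0.0, spec.between_sd, size=n)[pids]
        kb = a + spec.true_diff_h + rng.normal(0.0, spec.within_sd, size=n * k)
        dy = a + rng.normal(0.0, spec.within_sd, size=n * k)
        paired = pd.DataFrame({"participant_id": pids, "keyboard": kb,
                               "diary": dy})
        res = test_difference(paired, bounds=(spec.bound,))
        declared += int(res.equivalent[spec.bound])
    return declared / n_reps
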