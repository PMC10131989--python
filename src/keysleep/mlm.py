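"""Association and moderation multilevel models.

All models put the self-reported (diary) metric as outcome and the
corresponding keyboard-derived metric as predictor, with a participant
random intercept.  Outcome and predictor are grand-standardized, so slopes
are reported as standardized betas.  Day-level predictors are cluster-mean
centered with empirical-Bayes person means (fixed intercept plus the
predicted random intercept of the metric's unconditional model), separating
within- from between-person slopes.  Inference uses alpha = .01 with 99%
CIs; .01 < p < .05 is labeled a trend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.outliers_influence import variance_inflation_factor

from ._mixed import DF_METHOD, fit_mixedlm, residual_df

logger = logging.getLogger(__name__)

ALPHA = 0.01
TREND_ALPHA = 0.05


def significance_label(p: float) -> str:
    if p < ALPHA:
        return "significant"
    if p < TREND_ALPHA:
        return "trend"
    return "ns"


@dataclass
class MlmFit:
    """Tidy summary of one multilevel model fit."""
    outcome: str
    predictors: list[str]
    coefs: pd.DataFrame = field(repr=False)  # beta, se, ci lo/hi, t, df, p
    var_between: float = np.nan
    var_within: float = np.nan
    slope_sd: float = np.nan
    r2_marginal: float = np.nan
    r2_conditional: float = np.nan
    n_obs: int = 0
    n_groups: int = 0
    converged: bool = True
    df_method: str = DF_METHOD

    def coef(self, term: str, col: str = "beta") -> float:
        return float(self.coefs.loc[term, col])

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "predictors": self.predictors,
            "coefs": self.coefs.reset_index().rename(
                columns={"index": "term"}).to_dict(orient="records"),
            "var_between": self.var_between, "var_within": self.var_within,
            "slope_sd": self.slope_sd, "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional, "n_obs": self.n_obs,
            "n_groups": self.n_groups, "converged": self.converged,
            "df_method": self.df_method,
        }


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.nanstd(x, ddof=1)
    return (x - np.nanmean(x)) / sd if sd > 0 else x - np.nanmean(x)


def _coef_table(res, dof: float, alpha: float = ALPHA) -> pd.DataFrame:
    """Fixed-effect table with t tests against the residual-style df."""
    names = res.model.exog_names
    q = stats.t(dof).ppf(1 - alpha / 2)
    rows = {}
    for name in names:
        b = float(res.params[name])
        se = float(res.bse_fe[name])
        if se > 0:
            t = b / se
        else:
            t = 0.0 if b == 0 else np.inf * np.sign(b)
        p = float(2 * stats.t(dof).sf(abs(t))) if np.isfinite(t) else 0.0
        rows[name] = {"beta": b, "se": se, "ci_lo": b - q * se,
                      "ci_hi": b + q * se, "t": t, "df": dof, "p": p,
                      "label": significance_label(p)}
    return pd.DataFrame(rows).T


def _variance_summary(res, data: pd.DataFrame, fixed_terms: list[str]):
    """Between/within variances and Nakagawa-style explained variance."""
    cov = np.asarray(res.cov_re)
    vb = max(float(cov[0, 0]), 0.0)
    vw = float(res.scale)
    fitted_fixed = np.zeros(len(data))
    for name in res.model.exog_names:
        if name == "Intercept":
            continue
        fitted_fixed = fitted_fixed + res.params[name] * res.model.exog[
            :, res.model.exog_names.index(name)]
    vf = float(np.var(fitted_fixed))
    slope_var = float(cov[1, 1]) if cov.shape[0] > 1 else 0.0
    total = vf + vb + slope_var + vw
    r2m = vf / total if total > 0 else np.nan
    r2c = (vf + vb + slope_var) / total if total > 0 else np.nan
    return vb, vw, slope_var, r2m, r2c


# --------------------------------------------------------------------------
# empirical-Bayes cluster-mean centering
# --------------------------------------------------------------------------

class ClusterMeanCenterer(BaseEstimator, TransformerMixin):
    """Decompose a day-level column into an EB person mean and a deviation.

    The person mean is the fixed intercept plus the predicted (shrunken)
    random intercept from the column's unconditional model; the centered
    score is observation minus person mean, so the decomposition
    reconstructs the observation exactly.
    """

    def __init__(self, col: str, group_col: str = "participant_id"):
        self.col = col
        self.group_col = group_col

    def fit(self, X: pd.DataFrame, y=None) -> "ClusterMeanCenterer":
        df = X[[self.group_col, self.col]].dropna()
        df = df.rename(columns={self.col: "value"})
        res, converged = fit_mixedlm("value ~ 1", df, df[self.group_col])
        self.grand_intercept_ = float(res.params["Intercept"])
        self.person_means_ = {
            g: self.grand_intercept_ + float(np.asarray(re).ravel()[0])
            for g, re in res.random_effects.items()}
        self.converged_ = converged
        self.missing_groups_: list = []
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        pm = []
        for g in out[self.group_col]:
            if g in self.person_means_:
                pm.append(self.person_means_[g])
            else:
                if g not in self.missing_groups_:
                    self.missing_groups_.append(g)
                pm.append(self.grand_intercept_)
        if self.missing_groups_:
            logger.warning("ClusterMeanCenterer(%s): %d group(s) absent from "
                           "the unconditional fit; grand intercept used",
                           self.col, len(self.missing_groups_))
        out[f"{self.col}_pm"] = np.asarray(pm, dtype=float)
        out[f"{self.col}_c"] = out[self.col] - out[f"{self.col}_pm"]
        return out


def center_predictor(X: pd.DataFrame, col: str,
                     group_col: str = "participant_id") -> pd.DataFrame:
    """Functional wrapper over :class:`ClusterMeanCenterer`."""
    return ClusterMeanCenterer(col, group_col).fit(X).transform(X)


# --------------------------------------------------------------------------
# association models
# --------------------------------------------------------------------------

def _prepare(paired: pd.DataFrame, extra: list[str] | None = None,
             standardize: bool = True) -> pd.DataFrame:
    cols = ["participant_id", "keyboard", "diary"] + (extra or [])
    df = paired[cols].dropna(subset=["keyboard", "diary"]).copy()
    if standardize:
        df["y"] = _zscore(df["diary"].to_numpy(dtype=float))
        df["x"] = _zscore(df["keyboard"].to_numpy(dtype=float))
    else:
        df["y"] = df["diary"].astype(float)
        df["x"] = df["keyboard"].astype(float)
    return df


class AssociationModel(BaseEstimator):
    """Random-intercept regression of the diary metric on the keyboard metric.

    Both variables are grand-standardized, so ``beta_`` is the standardized
    slope; ``r2_marginal_`` (fixed effects) and ``r2_conditional_``
    (fixed + random) summarize explained variance.
    """

    def __init__(self, standardize: bool = True, alpha: float = ALPHA,
                 min_participants: int = 20, label: str = ""):
        self.standardize = standardize
        self.alpha = alpha
        self.min_participants = min_participants
        self.label = label

    def fit(self, X: pd.DataFrame, y=None) -> "AssociationModel":
        df = _prepare(X, standardize=self.standardize)
        n_groups = df["participant_id"].nunique()
        if n_groups < self.min_participants:
            raise ValueError(f"need >= {self.min_participants} participants, "
                             f"got {n_groups}")
        res, converged = fit_mixedlm("y ~ x", df, df["participant_id"])
        dof = residual_df(len(df), n_groups, 2)
        coefs = _coef_table(res, dof, self.alpha)
        vb, vw, _sv, r2m, r2c = _variance_summary(res, df, ["x"])
        self.fit_ = MlmFit(
            outcome=self.label or "diary", predictors=["keyboard"],
            coefs=coefs, var_between=vb, var_within=vw,
            r2_marginal=r2m, r2_conditional=r2c, n_obs=len(df),
            n_groups=int(n_groups), converged=converged)
        self.beta_ = coefs.loc["x", "beta"]
        self.ci99_ = (coefs.loc["x", "ci_lo"], coefs.loc["x", "ci_hi"])
        self.t_, self.df_, self.p_ = (coefs.loc["x", "t"], dof,
                                      coefs.loc["x", "p"])
        self.r2_marginal_, self.r2_conditional_ = r2m, r2c
        self.result_ = res
        return self


def fit_association(paired: pd.DataFrame, label: str = "") -> MlmFit:
    return AssociationModel(label=label).fit(paired).fit_


# --------------------------------------------------------------------------
# first-level (day-level) moderation
# --------------------------------------------------------------------------

class FirstLevelModerationModel(BaseEstimator):
    """Moderation of the within-person slope by day-level predictors.

    The keyboard metric is EB cluster-mean centered; its person mean enters
    as a covariate.  Hours-with-activity moderators are cluster-mean
    centered the same way; type of day enters as a weekend indicator.  The
    model includes moderator main effects and centered-metric x moderator
    interactions.
    """

    def __init__(self, moderators: tuple[str, ...] = ("hours_prev_day",
                                                      "type_of_day"),
                 alpha: float = ALPHA, label: str = ""):
        self.moderators = moderators
        self.alpha = alpha
        self.label = label

    def fit(self, X: pd.DataFrame, y=None) -> "FirstLevelModerationModel":
        df = _prepare(X, extra=[m for m in self.moderators])
        df = df.dropna(subset=list(self.moderators))
        df = ClusterMeanCenterer("x").fit(df).transform(df)
        terms = ["x_c", "x_pm"]
        for m in self.moderators:
            if m == "type_of_day":
                df["weekend"] = (df[m] == "weekend").astype(float)
                terms += ["weekend", "x_c:weekend"]
            else:
                df[m] = df[m].astype(float)
                df = ClusterMeanCenterer(m).fit(df).transform(df)
                terms += [f"{m}_c", f"{m}_pm", f"x_c:{m}_c"]
        formula = "y ~ " + " + ".join(terms)
        res, converged = fit_mixedlm(formula, df, df["participant_id"])
        n_groups = df["participant_id"].nunique()
        dof = residual_df(len(df), n_groups, len(res.model.exog_names))
        coefs = _coef_table(res, dof, self.alpha)
        vb, vw, _sv, r2m, r2c = _variance_summary(res, df, terms)
        self.fit_ = MlmFit(
            outcome=self.label or "diary", predictors=terms, coefs=coefs,
            var_between=vb, var_within=vw, r2_marginal=r2m,
            r2_conditional=r2c, n_obs=len(df), n_groups=int(n_groups),
            converged=converged)
        self.coefs_ = coefs
        return self


def fit_first_level_moderation(paired: pd.DataFrame,
                               moderators=("hours_prev_day", "type_of_day"),
                               label: str = "") -> MlmFit:
    return FirstLevelModerationModel(moderators=moderators,
                                     label=label).fit(paired).fit_


# --------------------------------------------------------------------------
# random slopes
# --------------------------------------------------------------------------

@dataclass
class RandomSlopeFit:
    slope_sd: float
    loglik: float
    aic: float
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    boundary: bool
    n_obs: int
    n_groups: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("slope_sd", "loglik", "aic", "lrt_stat", "lrt_df", "lrt_p",
                 "boundary", "n_obs", "n_groups")}


class RandomSlopeModel(BaseEstimator):
    """Interindividual variation in the within-person slope.

    Compares the random-intercept model with a model adding a random slope
    (plus intercept-slope covariance) for the cluster-mean-centered keyboard
    metric; the likelihood-ratio test has 2 df.  Both models are REML fits
    with identical fixed effects, so their restricted likelihoods are
    comparable.  A boundary fit (slope variance ~0) reports slope_sd = 0 and
    flags the LRT as conservative.
    """

    def __init__(self, alpha: float = ALPHA, label: str = ""):
        self.alpha = alpha
        self.label = label

    def fit(self, X: pd.DataFrame, y=None) -> "RandomSlopeModel":
        df = _prepare(X)
        df = ClusterMeanCenterer("x").fit(df).transform(df)
        formula = "y ~ x_c + x_pm"
        reduced, _ = fit_mixedlm(formula, df, df["participant_id"])
        full, converged = fit_mixedlm(formula, df, df["participant_id"],
                                      re_formula="~x_c")
        cov = np.asarray(full.cov_re)
        slope_var = max(float(cov[1, 1]), 0.0)
        slope_sd = float(np.sqrt(slope_var))
        boundary = slope_var <= 1e-8
        lrt = max(2.0 * (float(full.llf) - float(reduced.llf)), 0.0)
        lrt_p = float(stats.chi2(2).sf(lrt))
        k_params = len(full.model.exog_names) + 3 + 1
        aic = -2.0 * float(full.llf) + 2.0 * k_params
        n_groups = df["participant_id"].nunique()
        self.fit_ = RandomSlopeFit(
            slope_sd=slope_sd if not boundary else 0.0,
            loglik=float(full.llf), aic=aic, lrt_stat=lrt, lrt_df=2,
            lrt_p=lrt_p, boundary=boundary, n_obs=len(df),
            n_groups=int(n_groups))
        self.slope_sd_ = self.fit_.slope_sd
        self.lrt_stat_, self.lrt_p_ = lrt, lrt_p
        self.boundary_ = boundary
        self.converged_ = converged
        return self


def fit_random_slope(paired: pd.DataFrame, label: str = "") -> RandomSlopeFit:
    return RandomSlopeModel(label=label).fit(paired).fit_


# --------------------------------------------------------------------------
# cross-level (trait) moderation
# --------------------------------------------------------------------------

class CrossLevelModel(BaseEstimator):
    """Trait moderation of the within-person slope (random-slope model).

    Chronotype (MSFsc), general sleep quality (PSQI) and trait self-control
    enter grand-mean centered, with main effects and trait x centered-metric
    cross-level interactions.  A collinearity screen (pairwise trait
    correlations and VIFs on the fixed design) runs before the fit; a VIF
    above the ceiling warns but the fit proceeds.
    """

    def __init__(self, traits: tuple[str, ...] = ("msfsc", "psqi", "tsc"),
                 vif_ceiling: float = 10.0, alpha: float = ALPHA,
                 label: str = ""):
        self.traits = traits
        self.vif_ceiling = vif_ceiling
        self.alpha = alpha
        self.label = label

    def fit(self, X: pd.DataFrame, traits: pd.DataFrame | None = None,
            y=None) -> "CrossLevelModel":
        if traits is None:
            raise ValueError("a participant trait table is required")
        df = _prepare(X)
        df = ClusterMeanCenterer("x").fit(df).transform(df)
        tr = traits.copy()
        tr["participant_id"] = tr["participant_id"].astype(str)
        df["participant_id"] = df["participant_id"].astype(str)
        df = df.merge(tr[["participant_id", *self.traits]], on="participant_id",
                      how="inner").dropna(subset=list(self.traits))
        terms = ["x_c", "x_pm"]
        # grand-mean center on the participant level (one value per person)
        person = df.drop_duplicates("participant_id")
        for t in self.traits:
            gm = float(person[t].mean())
            df[f"{t}_gc"] = df[t] - gm
            terms += [f"{t}_gc", f"x_c:{t}_gc"]

        self.trait_correlations_ = person[list(self.traits)].corr()
        design = pd.DataFrame({"x_c": df["x_c"], "x_pm": df["x_pm"]})
        for t in self.traits:
            design[t] = df[f"{t}_gc"]
            design[f"x_c:{t}"] = df["x_c"] * df[f"{t}_gc"]
        dm = np.column_stack([np.ones(len(design)), design.to_numpy()])
        self.vifs_ = pd.Series(
            [variance_inflation_factor(dm, i + 1)
             for i in range(design.shape[1])], index=design.columns)
        self.vif_flag_ = bool((self.vifs_ > self.vif_ceiling).any())
        if self.vif_flag_:
            logger.warning("CrossLevelModel: VIF above %.1f for %s",
                           self.vif_ceiling,
                           list(self.vifs_[self.vifs_ > self.vif_ceiling].index))

        formula = "y ~ " + " + ".join(terms)
        res, converged = fit_mixedlm(formula, df, df["participant_id"],
                                     re_formula="~x_c")
        n_groups = df["participant_id"].nunique()
        dof = residual_df(len(df), n_groups, len(res.model.exog_names))
        coefs = _coef_table(res, dof, self.alpha)
        vb, vw, sv, r2m, r2c = _variance_summary(res, df, terms)
        self.fit_ = MlmFit(
            outcome=self.label or "diary", predictors=terms, coefs=coefs,
            var_between=vb, var_within=vw, slope_sd=float(np.sqrt(sv)),
            r2_marginal=r2m, r2_conditional=r2c, n_obs=len(df),
            n_groups=int(n_groups), converged=converged)
        self.coefs_ = coefs
        return self


def fit_cross_level(paired: pd.DataFrame, traits: pd.DataFrame,
                    label: str = "") -> MlmFit:
    return CrossLevelModel(label=label).fit(paired, traits=traits).fit_
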