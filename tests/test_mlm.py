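import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import keysleep as ks
from keysleep.mlm import (AssociationModel, ClusterMeanCenterer,
                          CrossLevelModel, FirstLevelModerationModel,
                          RandomSlopeModel, significance_label)


def gen_assoc(rng, n=120, k=7, beta=0.6, u_sd=0.4, e_sd=0.6):
    pids = np.repeat(np.arange(n), k)
    x = rng.normal(0, 1, n * k)
    y = beta * x + rng.normal(0, u_sd, n)[pids] + rng.normal(0, e_sd, n * k)
    return pd.DataFrame({"participant_id": pids, "keyboard": x, "diary": y})


def test_identical_outcome_and_predictor(rng):
    df = gen_assoc(rng)
    df["diary"] = df["keyboard"]
    m = AssociationModel().fit(df)
    assert m.beta_ == pytest.approx(1.0, abs=1e-6)
    assert m.r2_marginal_ == pytest.approx(1.0, abs=1e-3)


def test_independent_noise_gives_null_slope(rng):
    df = gen_assoc(rng, beta=0.0)
    m = AssociationModel().fit(df)
    assert abs(m.beta_) < 0.1
    assert m.ci99_[0] < 0 < m.ci99_[1]


def test_standardization_invariance(rng):
    df = gen_assoc(rng)
    df["keyboard"] = 3.0 * df["keyboard"] + 14.0   # arbitrary units
    df["diary"] = 0.5 * df["diary"] - 2.0
    std = AssociationModel(standardize=True).fit(df)
    raw = AssociationModel(standardize=False).fit(df)
    sx = df["keyboard"].std(ddof=1)
    sy = df["diary"].std(ddof=1)
    assert std.beta_ == pytest.approx(raw.beta_ * sx / sy, abs=1e-6)


def test_too_few_participants_raises(rng):
    with pytest.raises(ValueError, match="participants"):
        AssociationModel().fit(gen_assoc(rng, n=10))


def test_association_matches_lme4_oracle(rng, tmp_path):
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    df = gen_assoc(rng, n=60, k=5)
    df.to_csv(tmp_path / "d.csv", index=False)
    script = tmp_path / "fit.R"
    script.write_text("""
suppressMessages(library(lme4))
d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
d$y <- scale(d$diary); d$x <- scale(d$keyboard)
m <- lmer(y ~ x + (1|participant_id), data=d, REML=TRUE)
cat(fixef(m)["x"], sqrt(diag(vcov(m)))["x"],
    as.data.frame(VarCorr(m))$vcov, sep="\\n")
""")
    out = subprocess.run(["Rscript", str(script), str(tmp_path / "d.csv")],
                         capture_output=True, text=True, check=True)
    beta_r, se_r, vb_r, vw_r = [float(v) for v in out.stdout.split()]
    m = AssociationModel().fit(df)
    assert m.beta_ == pytest.approx(beta_r, abs=2e-4)
    assert m.fit_.coefs.loc["x", "se"] == pytest.approx(se_r, rel=0.02)
    assert m.fit_.var_between == pytest.approx(vb_r, rel=0.05, abs=1e-3)
    assert m.fit_.var_within == pytest.approx(vw_r, rel=0.02)


# --------------------------------------------------------------------------
# cluster-mean centering
# --------------------------------------------------------------------------

def test_centering_decomposition_is_exact(rng):
    df = gen_assoc(rng, n=40)
    out = ks.center_predictor(df, "keyboard")
    recon = out["keyboard_pm"] + out["keyboard_c"]
    assert np.allclose(recon, df["keyboard"], atol=1e-12)


def test_full_shrinkage_when_no_between_variance(rng):
    n, k = 60, 6
    df = pd.DataFrame({"participant_id": np.repeat(np.arange(n), k),
                       "keyboard": rng.normal(5.0, 1.0, n * k)})
    out = ks.center_predictor(df, "keyboard")
    # person means shrink sharply toward the grand intercept: they retain
    # well under half the spread of the raw per-person means
    raw_sd = df.groupby("participant_id")["keyboard"].mean().std()
    assert out["keyboard_pm"].std() < 0.5 * raw_sd
    assert out["keyboard_pm"].mean() == pytest.approx(5.0, abs=0.1)


def test_shrinkage_vanishes_with_many_nights(rng):
    n, k = 30, 200
    a = rng.normal(0, 1.0, n)
    df = pd.DataFrame({"participant_id": np.repeat(np.arange(n), k),
                       "keyboard": a[np.repeat(np.arange(n), k)]
                       + rng.normal(0, 1.0, n * k)})
    out = ks.center_predictor(df, "keyboard")
    raw = df.groupby("participant_id")["keyboard"].transform("mean")
    assert np.abs(out["keyboard_pm"] - raw).max() < 0.05


def test_unseen_participant_falls_back_to_grand_intercept(rng):
    df = gen_assoc(rng, n=20)
    cen = ClusterMeanCenterer("keyboard").fit(df)
    new = pd.DataFrame({"participant_id": [999], "keyboard": [0.3]})
    out = cen.transform(new)
    assert out["keyboard_pm"].iloc[0] == pytest.approx(cen.grand_intercept_)
    assert 999 in cen.missing_groups_


# --------------------------------------------------------------------------
# first-level moderation
# --------------------------------------------------------------------------

def gen_moderated(rng, n=150, k=7, gamma=0.15):
    pids = np.repeat(np.arange(n), k)
    x = rng.normal(0, 1, n * k)
    hours = np.clip(rng.normal(12, 3, n * k), 1, 24)
    slope = 0.6 + gamma * (hours - hours.mean())
    y = slope * x + rng.normal(0, 0.3, n)[pids] + rng.normal(0, 0.5, n * k)
    tod = np.where(rng.random(n * k) < 2 / 7, "weekend", "weekday")
    return pd.DataFrame({"participant_id": pids, "keyboard": x, "diary": y,
                         "hours_prev_day": hours, "type_of_day": tod})


def test_moderation_by_hours_recovered(rng):
    df = gen_moderated(rng, gamma=0.15)
    m = FirstLevelModerationModel(moderators=("hours_prev_day",
                                              "type_of_day")).fit(df)
    inter = m.coefs_.loc["x_c:hours_prev_day_c"]
    assert inter["beta"] > 0
    assert inter["p"] < 0.01
    # type of day does not moderate in this design
    assert m.coefs_.loc["x_c:weekend", "p"] > 0.01


def test_null_moderator_stays_null(rng):
    df = gen_moderated(rng, gamma=0.0)
    # permute the day type to destroy any accidental structure
    df["type_of_day"] = rng.permutation(df["type_of_day"].to_numpy())
    m = FirstLevelModerationModel().fit(df)
    assert abs(m.coefs_.loc["x_c:hours_prev_day_c", "beta"]) < 0.05
    assert m.coefs_.loc["x_c:weekend", "p"] > 0.01


# --------------------------------------------------------------------------
# random slopes
# --------------------------------------------------------------------------

def test_common_slope_yields_boundary_fit(rng):
    df = gen_assoc(rng, n=100, k=7, beta=0.6)
    m = RandomSlopeModel().fit(df)
    assert m.slope_sd_ < 0.15  # boundary REML estimates hover above zero
    assert m.lrt_p_ > 0.01


def test_slope_variation_recovered_single_replicate(rng):
    from keysleep.calibrate import SlopeSimSpec, random_slope_recovery
    res = random_slope_recovery(SlopeSimSpec(slope_sd=0.35), n_reps=2, seed=11)
    assert res["lrt_p"].max() < 1e-3
    assert res["slope_sd_hat"].mean() == pytest.approx(0.35, abs=0.1)


# --------------------------------------------------------------------------
# cross-level moderation
# --------------------------------------------------------------------------

def test_independent_traits_show_no_moderation():
    from keysleep.calibrate import CrossLevelSimSpec, cross_level_recovery
    res = cross_level_recovery(CrossLevelSimSpec(gamma_psqi=0.0), n_reps=3,
                               seed=4)
    assert (res["p"] > 0.01).all()
    assert not res["vif_flag"].any()


def test_psqi_attenuation_recovered():
    from keysleep.calibrate import CrossLevelSimSpec, cross_level_recovery
    res = cross_level_recovery(CrossLevelSimSpec(), n_reps=2, seed=9)
    assert (res["gamma_hat"] < 0).all()
    assert (res["p"] < 0.01).all()


def test_duplicated_trait_raises_vif_flag(rng):
    df = gen_assoc(rng, n=60, k=6)
    df["participant_id"] = df["participant_id"].astype(str)
    n = df["participant_id"].nunique()
    psqi = rng.integers(0, 14, n).astype(float)
    traits = pd.DataFrame({
        "participant_id": sorted(df["participant_id"].unique(), key=str),
        "msfsc": psqi * 0.5 + 2.0 + rng.normal(0, 0.01, n),  # near-duplicate
        "psqi": psqi,
        "tsc": rng.uniform(1, 5, n)})
    m = CrossLevelModel(vif_ceiling=10.0).fit(df, traits=traits)
    assert m.vif_flag_


def test_significance_labels():
    assert significance_label(0.002) == "significant"
    assert significance_label(0.03) == "trend"
    assert significance_label(0.2) == "ns"
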