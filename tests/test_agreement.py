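import datetime as dt

import numpy as np
import pandas as pd
import pytest

import keysleep as ks
from keysleep.agreement import (EquivalenceTester, IccEstimator, TostSimSpec,
                                bland_altman_rm, pair_nights, test_difference,
                                tost_calibration)


def make_paired(diffs, base=None, pids=None):
    n = len(diffs)
    base = np.zeros(n) if base is None else np.asarray(base)
    pids = np.repeat(np.arange(max(n // 7, 1)), 7)[:n] if pids is None else pids
    return pd.DataFrame({"participant_id": pids,
                         "keyboard": base + np.asarray(diffs),
                         "diary": base})


# --------------------------------------------------------------------------
# pairing
# --------------------------------------------------------------------------

def test_pair_nights_join_weekend_and_missing():
    kb = pd.DataFrame({
        "participant_id": ["a", "a"],
        "anchor_date": [dt.date(2020, 9, 18), dt.date(2020, 9, 14)],
        "last_keystroke": [12.1, 11.9], "first_keystroke": [21.0, 20.5],
        "kap_h": [8.9, 8.6], "midpoint_kap": [16.55, 16.2],
        "n_events_in_window": [100, 100], "valid": [True, True]})
    dy = pd.DataFrame({
        "participant_id": ["a"], "anchor_date": [dt.date(2020, 9, 18)],
        "bedtime": [12.0], "try_to_sleep": [12.2], "sleep_onset": [12.5],
        "midsleep": [16.4], "sleep_offset": [20.3], "out_of_bed": [20.8],
        "total_sleep_period_h": [7.8], "total_bed_period_h": [8.8]})
    paired = pair_nights(kb, dy)
    df = paired["last_keystroke~bedtime"].set_index("anchor_date")
    # Friday evening anchor (Saturday morning) counts as weekend
    assert df.loc[dt.date(2020, 9, 18), "type_of_day"] == "weekend"
    assert df.loc[dt.date(2020, 9, 14), "type_of_day"] == "weekday"
    # keyboard-valid + diary-missing night is retained with diff missing
    assert np.isnan(df.loc[dt.date(2020, 9, 14), "diff_h"])
    assert df.loc[dt.date(2020, 9, 18), "diff_h"] == pytest.approx(0.1)
    assert len(paired) == len(ks.METRIC_PAIRS)


def test_pair_nights_cardinality(small_config, small_paired):
    n = small_config.n_participants * small_config.n_nights
    for df in small_paired.values():
        assert len(df) == n


# --------------------------------------------------------------------------
# ICC
# --------------------------------------------------------------------------

def test_icc_generative_truth(rng):
    n, k = 200, 7
    a = rng.normal(0, 1.0, n)
    vals = (a[:, None] + rng.normal(0, np.sqrt(3.0), (n, k))).ravel()
    est = ks.icc_unconditional(vals, np.repeat(np.arange(n), k))
    assert est.icc_ == pytest.approx(0.25, abs=0.04)
    assert est.var_between_ / (est.var_between_ + est.var_within_) == \
        pytest.approx(est.icc_, abs=1e-12)


def test_icc_matches_pingouin_anova(rng):
    pg = pytest.importorskip("pingouin")
    n, k = 60, 5
    vals = (rng.normal(0, 1, n)[:, None] + rng.normal(0, 1.5, (n, k))).ravel()
    df = pd.DataFrame({"targets": np.repeat(np.arange(n), k),
                       "raters": np.tile(np.arange(k), n), "ratings": vals})
    tab = pg.intraclass_corr(df, targets="targets", raters="raters",
                             ratings="ratings")
    icc1 = float(tab.loc[tab["Type"].str.startswith("ICC(1,1)")
                         | tab["Type"].eq("ICC1"), "ICC"].iloc[0])
    est = ks.icc_unconditional(vals, np.repeat(np.arange(n), k))
    assert est.icc_ == pytest.approx(icc1, abs=0.02)


def test_icc_boundary_and_degenerate(rng):
    n, k = 50, 6
    vals = rng.normal(0, 1, n * k)  # no between-person signal
    est = ks.icc_unconditional(vals, np.repeat(np.arange(n), k))
    assert est.icc_ < 0.05
    with pytest.raises(ValueError, match="not separable"):
        ks.icc_unconditional(rng.normal(size=30), np.arange(30))


# --------------------------------------------------------------------------
# equivalence testing
# --------------------------------------------------------------------------

def test_zero_diffs_equivalent_at_both_bounds(rng):
    base = rng.normal(0, 1.5, 700)
    res = test_difference(make_paired(np.zeros(700), base=base))
    assert res.mean_diff_h == pytest.approx(0.0, abs=1e-8)
    assert res.equivalent[0.5] and res.equivalent[1.0]


def test_constant_two_hour_diff_rejected(rng):
    diffs = 2.0 + rng.normal(0, 0.05, 700)
    base = rng.normal(0, 1.0, 700)
    res = test_difference(make_paired(diffs, base=base))
    assert res.nhst_p < 0.01
    assert not res.equivalent[0.5] and not res.equivalent[1.0]
    # TOST monotonicity: equivalence at the tight bound implies the loose one
    assert (not res.equivalent[0.5]) or res.equivalent[1.0]


def test_matches_closed_form_balanced_oracle(rng):
    n, k, true_diff = 150, 7, 0.2
    pids = np.repeat(np.arange(n), k)
    a = rng.normal(0, 0.5, n)[pids]
    kb = a + true_diff + rng.normal(0, 1.0, n * k)
    dy = a + rng.normal(0, 1.0, n * k)
    paired = pd.DataFrame({"participant_id": pids, "keyboard": kb,
                           "diary": dy})
    res = test_difference(paired)
    # the modality estimate is exactly the raw mean difference
    assert res.mean_diff_h == pytest.approx(float(np.mean(kb - dy)), abs=1e-6)
    # closed form for the balanced design: SE = sqrt(2 sigma_w^2 / (n k))
    se_oracle = np.sqrt(2 * 1.0 / (n * k))
    assert res.se == pytest.approx(se_oracle, rel=0.05)
    halfwidth = res.ci98[1] - res.mean_diff_h
    from scipy import stats
    assert halfwidth == pytest.approx(stats.t(res.df).ppf(0.99) * res.se,
                                      rel=1e-6)


def test_antisymmetry_under_modality_swap(rng):
    paired = make_paired(rng.normal(0.3, 0.8, 350),
                         base=rng.normal(0, 1, 350))
    res = test_difference(paired)
    swapped = paired.rename(columns={"keyboard": "diary", "diary": "keyboard"})
    res2 = test_difference(swapped)
    assert res2.mean_diff_h == pytest.approx(-res.mean_diff_h, abs=1e-6)
    assert res2.ci99[0] == pytest.approx(-res.ci99[1], abs=1e-6)
    assert res2.ci98[1] == pytest.approx(-res.ci98[0], abs=1e-6)


def test_too_few_participants_is_an_error():
    with pytest.raises(ValueError, match="participants"):
        test_difference(make_paired(np.zeros(14),
                                    pids=np.repeat([0, 1], 7)))


# --------------------------------------------------------------------------
# Bland-Altman
# --------------------------------------------------------------------------

def test_bland_altman_degenerate_and_offset(rng):
    base = rng.normal(16, 1.0, 140)
    identical = make_paired(np.zeros(140), base=base)
    res = bland_altman_rm(identical)
    assert res.bias == pytest.approx(0.0, abs=1e-9)
    assert res.loa_lower == pytest.approx(0.0, abs=1e-9)
    assert res.loa_upper == pytest.approx(0.0, abs=1e-9)
    shifted = make_paired(np.full(140, 0.7), base=base)
    assert bland_altman_rm(shifted).bias == pytest.approx(0.7, abs=1e-9)


def test_bland_altman_limits_match_components_and_coverage(rng):
    n, k = 150, 7
    pids = np.repeat(np.arange(n), k)
    vb, vw = 0.3**2, 0.6**2
    diffs = rng.normal(0, np.sqrt(vb), n)[pids] + \
        rng.normal(0, np.sqrt(vw), n * k)
    paired = make_paired(diffs, base=rng.normal(16, 1.2, n * k), pids=pids)
    res = bland_altman_rm(paired)
    oracle = 1.96 * np.sqrt(vb + vw)
    assert res.loa_upper - res.bias == pytest.approx(oracle, rel=0.05)
    inside = ((diffs > res.loa_lower) & (diffs < res.loa_upper)).mean()
    assert inside == pytest.approx(0.95, abs=0.02)


# --------------------------------------------------------------------------
# TOST calibration harness
# --------------------------------------------------------------------------

def test_tost_calibration_edge_cases():
    with pytest.raises(ValueError, match="n_reps"):
        tost_calibration(TostSimSpec(), n_reps=1)
    # empty equivalence region: nothing is ever declared equivalent
    spec = TostSimSpec(n_participants=30, n_nights=4, bound=0.0)
    assert tost_calibration(spec, n_reps=3, seed=0) == 0.0


def test_tost_power_at_zero_difference_small():
    spec = TostSimSpec(n_participants=60, n_nights=7, true_diff_h=0.0,
                       bound=0.5)
    rate = tost_calibration(spec, n_reps=10, seed=1)
    assert rate >= 0.9
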