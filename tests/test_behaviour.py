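"""Bells-test scoring, pathology classification, and the group statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from convergemap.behaviour import (BellsRecord, build_behaviour_table,
                                   classify_pathological, mixed_rm_anova,
                                   paired_effects, score_bells, spearman_report)
from convergemap.stats import partial_eta_sq, signed_rank_sums, eta_p_sq_ci
from convergemap.synthdata import render_bells_sheet


@pytest.mark.parametrize("left,right,total,asym", [
    (5, 0, 5, 5),
    (0, 0, 0, 0),
    (2, 3, 5, -1),
    (17, 18, 35, -1),
])
def test_score_bells_formulas(left, right, total, asym):
    rec = BellsRecord("s1", "pre", left, right)
    assert score_bells(rec) == (total, asym)


@pytest.mark.parametrize("left,right", [(-1, 0), (0, -2), (20, 16)])
def test_invalid_counts_rejected(left, right):
    with pytest.raises(ValueError):
        BellsRecord("s1", "pre", left, right)


def test_rendered_sheet_recount_matches_scores(rng):
    """Recounting omitted targets on a rendered synthetic sheet reproduces the scores."""
    for _ in range(25):
        left = int(rng.integers(0, 19))
        right = int(rng.integers(0, min(18, 36 - left)))
        rec = BellsRecord("s", "post", left, right)
        sheet = render_bells_sheet(rec, rng)
        assert len(sheet) == 35
        recount_left = int(sheet.query("side == 'left'")["omitted"].sum())
        recount_right = int(sheet.query("side == 'right'")["omitted"].sum())
        assert (recount_left + recount_right,
                recount_left - recount_right) == score_bells(rec)


def _toy_table():
    records = []
    hemis = {}
    for i, (pre, post) in enumerate([((1, 0), (3, 0)), ((0, 0), (2, 1)),
                                     ((2, 2), (2, 2)), ((0, 1), (5, 1))]):
        sid = f"s{i}"
        records.append(BellsRecord(sid, "pre", *pre))
        records.append(BellsRecord(sid, "post", *post))
        hemis[sid] = "right" if i % 2 else "left"
    return build_behaviour_table(records, hemis)


def test_behaviour_table_deltas_worsening_positive():
    t = _toy_table()
    # s3: pre total 1, post total 6 -> delta_total +5 (worsening positive)
    assert t.loc["s3", "delta_total"] == 5
    assert t.loc["s3", "delta_asymmetry"] == (5 - 1) - (0 - 1)


def test_classify_pathological_strict_inequality():
    t = _toy_table()
    flags = classify_pathological(t, {"post_total": 4, "post_asymmetry": 2})
    assert flags.loc["s3", "post_total_pathological"]      # 6 > 4
    assert not flags.loc["s1", "post_total_pathological"]  # 3 > 4 false
    # boundary: asymmetry exactly at cutoff is not pathological
    t2 = t.copy()
    t2.loc["s0", "post_asymmetry"] = 2
    assert not classify_pathological(t2, {"post_asymmetry": 2}).loc[
        "s0", "post_asymmetry_pathological"]
    with pytest.raises(ValueError):
        classify_pathological(t, {})
    with pytest.raises(KeyError):
        classify_pathological(t, {"no_such_column": 1})


def test_all_zero_cohort_has_zero_flags():
    records = [BellsRecord(f"s{i}", tp, 0, 0) for i in range(4) for tp in ("pre", "post")]
    t = build_behaviour_table(records, {f"s{i}": "left" for i in range(4)})
    assert not classify_pathological(t, {"post_total": 4}).any().any()


# --- mixed split-plot ANOVA -------------------------------------------------

def _simulated_2x2(n_per_group=20, time_effect=1.0, inter=0.5, seed=5):
    rng = np.random.default_rng(seed)
    rows = []
    for g, gname in enumerate(("left", "right")):
        subj = rng.normal(0, 1.0, n_per_group)
        for i in range(n_per_group):
            pre = subj[i] + rng.normal(0, 1)
            post = subj[i] + time_effect + g * inter + rng.normal(0, 1)
            rows.append((f"{gname}{i}", gname, pre, post))
    df = pd.DataFrame(rows, columns=["sid", "group", "pre", "post"]).set_index("sid")
    return df


def test_mixed_anova_matches_pingouin_oracle():
    """Split-plot F statistics agree with an independent implementation."""
    pingouin = pytest.importorskip("pingouin")
    df = _simulated_2x2()
    out = mixed_rm_anova(df[["pre", "post"]], df["group"])
    long = df.reset_index().melt(id_vars=["sid", "group"], value_vars=["pre", "post"],
                                 var_name="time", value_name="y")
    ref = pingouin.mixed_anova(data=long, dv="y", within="time", subject="sid",
                               between="group")
    f_time = float(ref.loc[ref["Source"] == "time", "F"].iloc[0])
    f_inter = float(ref.loc[ref["Source"] == "Interaction", "F"].iloc[0])
    assert out["time"].F == pytest.approx(f_time, abs=1e-9)
    assert out["interaction"].F == pytest.approx(f_inter, abs=1e-9)
    np2_time = float(ref.loc[ref["Source"] == "time", "np2"].iloc[0])
    assert out["time"].partial_eta_sq == pytest.approx(np2_time, abs=1e-9)


def test_eta_p_sq_identity_with_ss_decomposition():
    """eta_p^2 from F and dfs equals the SS ratio to 1e-12 on arbitrary data."""
    df = _simulated_2x2(n_per_group=13, time_effect=0.3, seed=11)
    out = mixed_rm_anova(df[["pre", "post"]], df["group"])
    for eff in ("time", "interaction", "group"):
        r = out[eff]
        assert r.partial_eta_sq == pytest.approx(
            r.F * r.df1 / (r.F * r.df1 + r.df2), abs=1e-12)


def test_mixed_anova_null_rejection_rate_calibrated():
    """Under no time effect the Time F-test rejects at ~ the nominal 5% level."""
    reject = 0
    n_reps = 1000
    for rep in range(n_reps):
        df = _simulated_2x2(n_per_group=20, time_effect=0.0, inter=0.0, seed=50_000 + rep)
        out = mixed_rm_anova(df[["pre", "post"]], df["group"])
        reject += out["time"].p < 0.05
    assert 0.035 <= reject / n_reps <= 0.065


def test_mixed_anova_constant_data_flagged():
    df = pd.DataFrame({"pre": [1.0] * 6, "post": [1.0] * 6,
                       "group": ["a", "b"] * 3}, index=[f"s{i}" for i in range(6)])
    out = mixed_rm_anova(df[["pre", "post"]], df["group"])
    assert "constant_data_F_undefined" in out["time"].flags


# --- paired effects ---------------------------------------------------------

def test_paired_effects_dz_is_t_over_sqrt_n(rng):
    pre = rng.normal(size=30)
    post = pre + rng.normal(0.4, 1.0, size=30)
    r = paired_effects(pre, post)
    t_ref, _ = sps.ttest_rel(post, pre)
    assert r.t == pytest.approx(float(t_ref), abs=1e-12)
    assert r.cohens_dz == pytest.approx(r.t / math.sqrt(30), abs=1e-12)


def test_paired_effects_shift_invariance(rng):
    pre = rng.normal(size=25)
    post = pre + rng.normal(0.3, 0.8, size=25)
    a = paired_effects(pre, post)
    b = paired_effects(pre + 17.0, post + 17.0)
    assert a.cohens_dz == pytest.approx(b.cohens_dz, abs=1e-9)
    assert a.r_rb == pytest.approx(b.r_rb, abs=1e-12)


def test_one_sided_differences_give_unit_rank_biserial(rng):
    pre = rng.normal(size=12)
    r = paired_effects(pre, pre + 1.0)
    assert r.W_neg == 0
    assert r.r_rb == 1.0


def test_all_zero_differences_flagged():
    x = np.arange(10.0)
    r = paired_effects(x, x)
    assert "all_zero_differences_wilcoxon_undefined" in r.flags
    assert math.isnan(r.r_rb)


def test_signed_rank_sums_midranks():
    # diffs: +1, -1, +2 -> |d| ranks (1.5, 1.5, 3): W+ = 4.5, W- = 1.5
    wp, wn, n = signed_rank_sums(np.zeros(3), np.array([1.0, -1.0, 2.0]))
    assert (wp, wn, n) == (4.5, 1.5, 3)


# --- Spearman reports -------------------------------------------------------

def test_spearman_zero_rho_gives_zero_t():
    x = np.array([1.0, 2, 3, 4])
    y = np.array([1.0, 3, 2, 4])  # rho != 0; use symmetric construction instead
    x = np.array([1.0, 2, 3, 4, 5, 6])
    y = np.array([3.0, 6, 1, 4, 2, 5])
    r = spearman_report(x, y)
    assert r.rho == pytest.approx(float(sps.spearmanr(x, y).statistic), abs=1e-12)
    if r.rho == 0:
        assert r.t == 0


def test_spearman_degenerate_monotone_flagged():
    x = np.arange(5.0)
    r = spearman_report(x, x * 2 + 1)
    assert r.rho == 1.0
    assert "perfect_monotone_t_undefined" in r.flags


def test_spearman_zero_variance_flagged():
    r = spearman_report(np.ones(5), np.arange(5.0))
    assert "zero_variance_rho_undefined" in r.flags


def test_eta_ci_brackets_point_estimate():
    lo, hi = eta_p_sq_ci(54.23, 1, 161)
    point = partial_eta_sq(54.23, 1, 161)
    assert lo < point < hi
    assert 0 <= lo and hi <= 1
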