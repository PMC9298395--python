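import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from socialkin.social_stats import (
    bootstrap_category_comparison,
    chi_square_2x2,
    comparison_frame,
    dunnett_c,
    immigration_shares,
    km_gehan,
    one_sample_t,
    parentage_shares,
    summarize_structure,
    workload_composite,
)


# ----------------------------------------------------------------------
# workload
# ----------------------------------------------------------------------

@pytest.mark.parametrize("counts,protocol,expected", [
    ((2, 1, 3, 0), "single-10min", 6),
    ((6, 9, 12), "triple-15min", 6),
    ((1, 1, 2), "triple-15min", 1),  # 4/3 * 2/3 = 8/9, rounds half-up to 1
])
def test_workload_examples(counts, protocol, expected):
    assert workload_composite(counts, protocol) == expected


def test_workload_matrix_form():
    obs = [[1, 0, 2, 3], [2, 1, 3, 3], [0, 0, 2, 1]]  # totals 6, 9, 3 -> mean 6
    assert workload_composite(obs, "triple-15min") == 4


def test_workload_rejects_negative():
    with pytest.raises(ValueError):
        workload_composite((-1, 0, 0, 0))


# ----------------------------------------------------------------------
# chi-square / t
# ----------------------------------------------------------------------

def test_chi_square_flat_table_zero():
    stat, df, p = chi_square_2x2([[10, 10], [10, 10]])
    assert stat == 0.0 and df == 1 and p == 1.0


def test_chi_square_matches_direct_expansion():
    rng = np.random.default_rng(4)
    for _ in range(50):
        obs = rng.integers(1, 60, size=(2, 2)).astype(float)
        stat, _, p = chi_square_2x2(obs)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert stat == pytest.approx(((obs - expected) ** 2 / expected).sum())
        res = stats.chi2_contingency(obs, correction=False)
        assert stat == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)


def test_chi_square_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        chi_square_2x2([[0, 0], [5, 5]])


def test_one_sample_t_symmetric_sample():
    t, df, p = one_sample_t([1.0, 2.0, 3.0], mu0=2.0)
    assert t == 0.0 and df == 2 and p == pytest.approx(1.0)


def test_one_sample_t_moments_equal_raw():
    rng = np.random.default_rng(5)
    x = rng.normal(0.3, 1.1, size=40)
    t_raw, df_raw, p_raw = one_sample_t(x, mu0=0.1)
    t_m, df_m, p_m = one_sample_t(
        moments=(float(x.mean()), float(x.std(ddof=1)), 40), mu0=0.1)
    assert t_raw == pytest.approx(t_m, abs=1e-12)
    assert p_raw == pytest.approx(p_m, abs=1e-12)
    scipy_t, scipy_p = stats.ttest_1samp(x, 0.1)
    assert t_raw == pytest.approx(scipy_t)


def test_one_sample_t_rejects_degenerate():
    with pytest.raises(ValueError):
        one_sample_t([2.0, 2.0, 2.0], mu0=0.0)
    with pytest.raises(ValueError):
        one_sample_t([1.0], mu0=0.0)


# ----------------------------------------------------------------------
# Dunnett's C
# ----------------------------------------------------------------------

def test_dunnett_identical_samples_centered():
    ci = dunnett_c([[1.0, 2, 3, 4], [1.0, 2, 3, 4]])
    row = ci.iloc[0]
    assert row["mean_diff"] == 0.0
    assert row["lower"] == pytest.approx(-row["upper"])
    assert row["upper"] > 0


def test_dunnett_equal_variance_equal_halfwidths():
    rng = np.random.default_rng(6)
    base = rng.normal(0, 1, 12)
    groups = [base + shift for shift in (0.0, 5.0, 10.0)]
    ci = dunnett_c(groups)
    widths = ci["half_width"].to_numpy()
    assert np.allclose(widths, widths[0])


def test_dunnett_zero_variance_warns():
    with pytest.warns(UserWarning, match="zero variance"):
        ci = dunnett_c([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
    assert ci.iloc[0]["half_width"] == 0.0


def test_dunnett_coverage_conservative():
    """Monte-Carlo coverage of the true mean difference >= 93% at alpha=.05."""
    rng = np.random.default_rng(7)
    n, reps = 10, 3000
    covered = 0
    for _ in range(reps):
        a = rng.normal(0.0, 1.0, n)
        b = rng.normal(0.0, 2.5, n)
        ci = dunnett_c([a, b]).iloc[0]
        covered += ci["lower"] <= 0.0 <= ci["upper"]
    assert covered / reps >= 0.93


# ----------------------------------------------------------------------
# bootstrap comparison
# ----------------------------------------------------------------------

def _table(rng, means, n=40):
    rows = []
    for label, mu in means.items():
        for v in rng.normal(mu, 1.0, n):
            rows.append({"value": v, "category": label})
    return pd.DataFrame(rows)


def test_bootstrap_nreps1_is_plain_anova_dunnett():
    rng = np.random.default_rng(8)
    table = _table(rng, {"a": 0.0, "b": 2.0})
    res = bootstrap_category_comparison(table, n_reps=1, seed=0)
    groups = [table[table.category == c].value.to_numpy() for c in ("a", "b")]
    plain = dunnett_c(groups).iloc[0]
    _, p_anova = stats.f_oneway(*groups)
    assert res[0].avg_p == pytest.approx(p_anova)
    assert res[0].avg_lower == pytest.approx(plain["lower"])
    assert res[0].avg_upper == pytest.approx(plain["upper"])


def test_bootstrap_detects_separated_categories():
    rng = np.random.default_rng(9)
    table = _table(rng, {"a": 0.0, "b": 3.0, "c": 0.1}, n=50)
    res = {(r.cat_i, r.cat_j): r for r in
           bootstrap_category_comparison(table, n_reps=50, seed=1)}
    assert res[("a", "b")].significant
    assert res[("b", "c")].significant
    assert not res[("a", "c")].significant


def test_bootstrap_determinism():
    rng = np.random.default_rng(10)
    table = _table(rng, {"a": 0.0, "b": 1.0})
    r1 = bootstrap_category_comparison(table, n_reps=20, seed=5)
    r2 = bootstrap_category_comparison(table, n_reps=20, seed=5)
    assert r1[0].avg_p == r2[0].avg_p
    assert r1[0].avg_lower == r2[0].avg_lower


def test_bootstrap_validation():
    rng = np.random.default_rng(11)
    table = _table(rng, {"a": 0.0})
    with pytest.raises(ValueError, match="categories"):
        bootstrap_category_comparison(table)


def test_comparison_frame_layout():
    rng = np.random.default_rng(12)
    res = bootstrap_category_comparison(_table(rng, {"a": 0, "b": 0}), n_reps=5, seed=2)
    frame = comparison_frame(res, status="helper")
    assert list(frame.columns) == ["status", "cat_i", "cat_j", "mean_diff",
                                   "avg_p", "avg_lo", "avg_hi", "significant"]


# ----------------------------------------------------------------------
# Kaplan-Meier / Gehan
# ----------------------------------------------------------------------

def test_gehan_identical_strata_zero():
    t = [30.0, 60.0, 120.0, 250.0]
    stat, p = km_gehan(t, [1, 1, 1, 0], t, [1, 1, 1, 0])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_gehan_fully_separated_strata():
    rng = np.random.default_rng(13)
    a = rng.uniform(10, 50, 20)
    b = rng.uniform(100, 200, 20)
    stat, p = km_gehan(a, np.ones(20), b, np.ones(20))
    assert p < 0.01


def test_gehan_rank_invariance_under_time_scaling():
    rng = np.random.default_rng(14)
    a = rng.exponential(100, 15)
    b = rng.exponential(220, 15)
    ev = np.ones(15)
    stat1, _ = km_gehan(a, ev, b, ev)
    stat2, _ = km_gehan(2 * a, ev, 2 * b, ev)
    assert stat1 == pytest.approx(stat2)


def test_gehan_requires_events():
    with pytest.raises(ValueError, match="event"):
        km_gehan([1.0, 2.0], [0, 0], [1.0, 2.0], [1, 1])


# ----------------------------------------------------------------------
# structure summaries
# ----------------------------------------------------------------------

def test_immigration_shares_arithmetic():
    table = pd.DataFrame({
        "status": ["breeder male", "helper", "independent"],
        "non_immigrant": [10, 50, 5],
        "possible_immigrant": [2, 8, 1],
        "immigrant": [3, 12, 4],
    })
    out = immigration_shares(table)
    total = 10 + 50 + 2 + 8 + 3 + 12
    assert out["pct_assured_immigrant"] == pytest.approx(100 * 15 / total)
    assert out["pct_unique_genotype"] == pytest.approx(100 * 25 / total)


def test_parentage_shares_arithmetic():
    skew = pd.DataFrame({
        "status": ["breeder male", "helper", "breeder female", "helper"],
        "sex": ["M", "M", "F", "F"],
        "produced_own_subgroup": [100, 20, 60, 6],
        "produced_other_subgroup": [10, 10, 10, 0],
    })
    out = parentage_shares(skew)
    assert out["pct_helper_paternity"] == pytest.approx(100 * 30 / 140)
    assert out["pct_helper_maternity"] == pytest.approx(100 * 6 / 76)


def test_summarize_structure_conservation(recovery_run):
    from socialkin.kinship import parentage_frame

    demo = recovery_run["demography"].reset_index()
    immigration, skew = summarize_structure(
        demo, parentage_frame(recovery_run["parentage"]), recovery_run["dataset"])
    counted = (immigration["non_immigrant"] + immigration["possible_immigrant"]
               + immigration["immigrant"]).sum()
    known_sex = demo[demo["sex"].isin(["M", "F", "unknown"])]
    assert counted == len(known_sex)
    accepted = sum(1 for a in recovery_run["parentage"] if a.accepted)
    produced = (skew["produced_own_subgroup"] + skew["produced_other_subgroup"]).sum()
    assert produced == accepted


def test_summarize_structure_empty_parentage(recovery_run):
    demo = recovery_run["demography"].reset_index()
    empty = pd.DataFrame(columns=["offspring", "parent", "sex_role",
                                  "mismatches", "age_feasible", "accepted"])
    immigration, skew = summarize_structure(demo, empty, recovery_run["dataset"])
    assert (skew["produced_own_subgroup"] == 0).all()
    assert (skew["n_producers"] == 0).all()
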