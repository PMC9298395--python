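"""Statistical layer: workload composite, bootstrap ANOVA with Dunnett's C,
chi-square and one-sample t, Kaplan-Meier/Gehan tenure comparison, and the
immigration/reproductive-skew summary tables.

Model fitting (GLMM, multinomial, logistic regression) is deliberately out
of scope: this module emits model-ready tables and the study's bespoke
resampling statistics only.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "workload_composite",
    "chi_square_2x2",
    "one_sample_t",
    "dunnett_c",
    "bootstrap_category_comparison",
    "km_gehan",
    "summarize_structure",
    "immigration_shares",
    "parentage_shares",
]

logger = logging.getLogger(__name__)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def workload_composite(counts, protocol: str = "single-10min") -> int:
    """Composite workload from behavioural frequencies.

    ``single-10min``: plain sum of the counts of one observation.
    ``triple-15min``: per-observation totals (three numbers, or a 3 x k count
    matrix summed per row) are averaged and multiplied by 2/3 so the two
    observation protocols are comparable. Result rounded half-up to the
    nearest integer.
    """
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("behaviour counts must be nonnegative")
    if protocol == "single-10min":
        return _round_half_up(float(arr.sum()))
    if protocol == "triple-15min":
        if arr.ndim == 2:
            if arr.shape[0] != 3:
                raise ValueError("triple-15min expects three observations")
            totals = arr.sum(axis=1)
        else:
            if arr.size != 3:
                raise ValueError("triple-15min expects three observation totals")
            totals = arr
        return _round_half_up(float(totals.mean()) * 2.0 / 3.0)
    raise ValueError(f"unknown protocol {protocol!r}")


def chi_square_2x2(table) -> tuple[float, int, float]:
    """Pearson chi-square (df = 1, no continuity correction) of a 2x2 table."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any():
        raise ValueError("cell counts must be nonnegative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        which = "row" if (rows == 0).any() else "column"
        raise ValueError(f"zero {which} margin")
    expected = np.outer(rows, cols) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    return stat, 1, float(stats.chi2.sf(stat, 1))


def one_sample_t(sample=None, mu0: float = 0.0, *,
                 moments: Optional[tuple[float, float, int]] = None) -> tuple[float, int, float]:
    """Two-sided one-sample t-test from raw data or (mean, sd, n) moments."""
    if moments is not None:
        mean, sd, n = moments
    else:
        arr = np.asarray(sample, dtype=float)
        n = arr.size
        if n < 2:
            raise ValueError("need n >= 2")
        mean, sd = float(arr.mean()), float(arr.std(ddof=1))
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    t = (mean - mu0) / (sd / math.sqrt(n))
    df = n - 1
    return float(t), df, float(2.0 * stats.t.sf(abs(t), df))


#: df ladder for studentized-range quantiles; df is rounded *down* onto the
#: ladder, which makes the quantile (and the Dunnett C interval) slightly
#: conservative while keeping the expensive numerical ppf cacheable
_DF_LADDER = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 20, 24, 30, 40,
              60, 120, 10 ** 6)


@lru_cache(maxsize=4096)
def _srange_quantile(alpha: float, k: int, df: int) -> float:
    """Upper-alpha studentized-range quantile q(alpha; k, df).

    df is snapped down to a fixed ladder so repeated bootstrap calls reuse
    the cached numerical quantile; the snap never widens alpha.
    """
    df = max(df, 1)
    df_eff = max(d for d in _DF_LADDER if d <= df)
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df_eff))


def dunnett_c(samples: Sequence[Sequence[float]], alpha: float = 0.05) -> pd.DataFrame:
    """Dunnett's C pairwise confidence intervals (unequal variances).

    For groups i, j with variances ``s2`` and sizes ``n``::

        half = sqrt((s2_i/n_i + s2_j/n_j) / 2)
               * (q_i s2_i/n_i + q_j s2_j/n_j) / (s2_i/n_i + s2_j/n_j)

    with ``q_i = q(alpha; k, n_i - 1)`` the studentized-range upper quantile.
    Returns one row per pair: ``i, j, mean_diff, lower, upper, half_width``.
    Two zero-variance groups give a degenerate width-0 interval with a
    warning.
    """
    k = len(samples)
    if k < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    means = [float(a.mean()) for a in arrays]
    variances = [float(a.var(ddof=1)) for a in arrays]
    sizes = [a.size for a in arrays]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = variances[i] / sizes[i], variances[j] / sizes[j]
            if vi + vj == 0.0:
                warnings.warn(f"groups {i} and {j} both have zero variance; "
                              "degenerate zero-width interval")
                half = 0.0
            else:
                qi = _srange_quantile(alpha, k, sizes[i] - 1)
                qj = _srange_quantile(alpha, k, sizes[j] - 1)
                half = math.sqrt((vi + vj) / 2.0) * (qi * vi + qj * vj) / (vi + vj)
            diff = means[i] - means[j]
            rows.append({"i": i, "j": j, "mean_diff": diff,
                         "lower": diff - half, "upper": diff + half,
                         "half_width": half})
    return pd.DataFrame(rows)


@dataclass
class CategoryComparisonResult:
    """Averaged bootstrap comparison of one category pair."""

    cat_i: str
    cat_j: str
    mean_diff: float
    avg_p: float
    avg_lower: float
    avg_upper: float
    significant: bool
    n_reps: int


def bootstrap_category_comparison(
    table: pd.DataFrame,
    value_col: str = "value",
    category_col: str = "category",
    n_reps: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[CategoryComparisonResult]:
    """Bootstrap one-way ANOVA with Dunnett's C, averaged over repetitions.

    Each repetition resamples rows with replacement to the original size,
    runs a one-way ANOVA across categories and Dunnett's C on all category
    pairs. The ANOVA p-value and the CI bounds are averaged across the
    ``n_reps`` repetitions; a pair is significant iff its averaged interval
    excludes zero. Replicates missing a category (or leaving one with a
    single row) are redrawn and logged. Deterministic under ``seed``.

    Before the Dunnett stage each resampled group is rescaled about its mean
    by ``sqrt(n_g / (n_g - 1))``: the with-replacement resample understates
    the group variance by the factor ``1 - 1/n_g``, and without this
    standard correction the averaged intervals are slightly anti-
    conservative under the null.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cats = sorted(table[category_col].astype(str).unique())
    if len(cats) < 2:
        raise ValueError("need >= 2 categories")
    by_cat = {c: table.loc[table[category_col].astype(str) == c, value_col].to_numpy(dtype=float)
              for c in cats}
    if any(len(v) < 2 for v in by_cat.values()):
        raise ValueError("each category needs >= 2 dyads")

    values = table[value_col].to_numpy(dtype=float)
    labels = table[category_col].astype(str).to_numpy()
    n = len(values)
    rng = np.random.default_rng(seed)

    p_sum = 0.0
    lower_sum = {pair: 0.0 for pair in _pairs(cats)}
    upper_sum = {pair: 0.0 for pair in _pairs(cats)}
    redrawn = 0
    rep = 0
    while rep < n_reps:
        if n_reps == 1:
            idx = np.arange(n)  # degenerate bootstrap: averaging is identity
        else:
            idx = rng.integers(0, n, size=n)
        rep_labels = labels[idx]
        rep_values = values[idx]
        groups = [rep_values[rep_labels == c] for c in cats]
        if any(len(g) < 2 for g in groups):
            redrawn += 1
            if redrawn > 100 * n_reps:
                raise RuntimeError("bootstrap cannot retain all categories")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p_anova = stats.f_oneway(*groups)
        if math.isnan(p_anova):
            p_anova = 1.0
        p_sum += p_anova
        if n_reps > 1:  # resampling variance-bias correction (see docstring)
            groups = [(g - g.mean()) * math.sqrt(len(g) / (len(g) - 1)) + g.mean()
                      for g in groups]
        ci = dunnett_c(groups, alpha=alpha)
        for _, row in ci.iterrows():
            pair = (cats[int(row["i"])], cats[int(row["j"])])
            lower_sum[pair] += row["lower"]
            upper_sum[pair] += row["upper"]
        rep += 1
    if redrawn:
        logger.info("bootstrap_category_comparison: %d replicate(s) redrawn", redrawn)

    results = []
    for ci_pair in _pairs(cats):
        ci_lo = lower_sum[ci_pair] / n_reps
        ci_hi = upper_sum[ci_pair] / n_reps
        diff = float(by_cat[ci_pair[0]].mean() - by_cat[ci_pair[1]].mean())
        results.append(CategoryComparisonResult(
            ci_pair[0], ci_pair[1], diff, p_sum / n_reps, ci_lo, ci_hi,
            significant=not (ci_lo <= 0.0 <= ci_hi), n_reps=n_reps))
    return results


def _pairs(cats: Sequence[str]):
    return [(cats[i], cats[j]) for i in range(len(cats)) for j in range(i + 1, len(cats))]


def comparison_frame(results: Sequence[CategoryComparisonResult],
                     status: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [{"status": status, "cat_i": r.cat_i, "cat_j": r.cat_j,
          "mean_diff": r.mean_diff, "avg_p": r.avg_p, "avg_lo": r.avg_lower,
          "avg_hi": r.avg_upper, "significant": r.significant} for r in results],
        columns=["status", "cat_i", "cat_j", "mean_diff", "avg_p", "avg_lo",
                 "avg_hi", "significant"])


def km_gehan(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Gehan-Wilcoxon two-sample comparison of Kaplan-Meier tenure curves.

    ``events_*`` are 1/True for an observed terminal event, 0/False for a
    censored record. Returns the chi-square-distributed Gehan statistic
    (1 df) and its p-value.
    """
    from lifelines.statistics import logrank_test

    ev_a = np.asarray(events_a, dtype=bool)
    ev_b = np.asarray(events_b, dtype=bool)
    if not ev_a.any() or not ev_b.any():
        raise ValueError("each stratum needs at least one observed event")
    res = logrank_test(times_a, times_b, event_observed_A=ev_a,
                       event_observed_B=ev_b, weightings="wilcoxon")
    return float(res.test_statistic), float(res.p_value)


# ----------------------------------------------------------------------
# Structure summaries (immigration and reproductive skew)
# ----------------------------------------------------------------------

_STATUS_SEX_ROWS = (
    ("breeder male", "M"), ("breeder female", "F"),
    ("helper", "M"), ("helper", "F"), ("helper", "unknown"),
    ("independent", "M"), ("independent", "F"),
)


def summarize_structure(
    demography: pd.DataFrame,
    parentage: pd.DataFrame,
    dataset,
    min_age_gap_days: float = 210.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Immigration and reproductive-skew summary tables.

    The immigration table counts immigrant classes per status x sex with the
    percentage of assured immigrants. The skew table counts, per status x
    sex: producers, accepted offspring inside the producer's own subgroup vs
    other subgroups of the same group, and the number of potential offspring
    (members younger by at least ``min_age_gap_days``) in each scope.
    """
    demo = demography.set_index("id")
    observed_combos = {(s, x) for s, x in
                       zip(demo["status"].astype(str), demo["sex"].astype(str))}
    combos = list(_STATUS_SEX_ROWS) + sorted(observed_combos - set(_STATUS_SEX_ROWS))
    rows = []
    for status, sex in combos:
        sel = demo[(demo["status"] == status) & (demo["sex"] == sex)]
        counts = sel["immigrant_class"].value_counts()
        non_imm = int(counts.get("non-immigrant", 0))
        possible = int(counts.get("possible immigrant", 0))
        imm = int(counts.get("immigrant", 0))
        total = non_imm + possible + imm
        rows.append({
            "status": status, "sex": sex,
            "non_immigrant": non_imm, "possible_immigrant": possible,
            "immigrant": imm,
            "pct_immigrant": 100.0 * imm / total if total else 0.0,
        })
    immigration = pd.DataFrame(rows)

    accepted = parentage[parentage["accepted"].astype(bool)]
    off_by_parent: dict[str, list[str]] = {}
    for _, row in accepted.iterrows():
        off_by_parent.setdefault(str(row["parent"]), []).append(str(row["offspring"]))

    skew_rows = []
    for status, sex in combos:
        sel = demo[(demo["status"] == status) & (demo["sex"] == sex)]
        producers = [i for i in sel.index if i in off_by_parent]
        own = other = 0
        pot_own = pot_other = 0
        for prod in sel.index:
            p_sub = demo.at[prod, "subgroup"]
            p_grp = demo.at[prod, "group"]
            p_age = demo.at[prod, "age_days"]
            for off in off_by_parent.get(prod, []):
                if demo.at[off, "subgroup"] == p_sub:
                    own += 1
                else:
                    other += 1
            if prod not in off_by_parent:
                continue
            if p_age is None or (isinstance(p_age, float) and math.isnan(p_age)):
                continue
            members = demo[demo["group"] == p_grp]
            for member in members.index:
                if member == prod:
                    continue
                m_age = members.at[member, "age_days"]
                if m_age is None or (isinstance(m_age, float) and math.isnan(m_age)):
                    continue
                if p_age - m_age >= min_age_gap_days:
                    if members.at[member, "subgroup"] == p_sub:
                        pot_own += 1
                    else:
                        pot_other += 1
        skew_rows.append({
            "status": status, "sex": sex, "n_producers": len(producers),
            "produced_own_subgroup": own, "produced_other_subgroup": other,
            "potential_own_subgroup": pot_own, "potential_other_subgroup": pot_other,
            "pct_own": 100.0 * own / pot_own if pot_own else 0.0,
            "pct_other": 100.0 * other / pot_other if pot_other else 0.0,
        })
    skew = pd.DataFrame(skew_rows)
    return immigration, skew


def immigration_shares(table: pd.DataFrame,
                       exclude_status: Sequence[str] = ("independent",)) -> dict[str, float]:
    """Percent assured-immigrant and unique-genotype members from an
    immigration table (columns ``status, non_immigrant, possible_immigrant,
    immigrant``), excluding the given statuses from the denominator."""
    sel = table[~table["status"].isin(exclude_status)]
    non_imm = sel["non_immigrant"].sum()
    possible = sel["possible_immigrant"].sum()
    imm = sel["immigrant"].sum()
    total = non_imm + possible + imm
    if total == 0:
        raise ValueError("empty immigration table")
    return {
        "pct_assured_immigrant": 100.0 * imm / total,
        "pct_unique_genotype": 100.0 * (imm + possible) / total,
    }


def parentage_shares(skew: pd.DataFrame) -> dict[str, float]:
    """Helper share of detected paternities/maternities from a skew table.

    Expects columns ``status, sex, produced_own_subgroup,
    produced_other_subgroup``; totals are taken over male producers for
    paternities and female producers for maternities.
    """
    produced = skew["produced_own_subgroup"] + skew["produced_other_subgroup"]
    males = skew["sex"] == "M"
    females = skew["sex"] == "F"
    total_pat = produced[males].sum()
    total_mat = produced[females].sum()
    helper = skew["status"] == "helper"
    out = {}
    out["pct_helper_paternity"] = (
        100.0 * produced[males & helper].sum() / total_pat if total_pat else 0.0)
    out["pct_helper_maternity"] = (
        100.0 * produced[females & helper].sum() / total_mat if total_mat else 0.0)
    return out
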