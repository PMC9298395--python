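import numpy as np
import pandas as pd
import pytest

from socialkin.demography import (
    IMMIGRANT_CLASSES,
    TenureEstimate,
    classify_immigrant,
    detect_inheritance,
    estimate_tenure,
)


GROUP = ["focal", "a1", "a2", "b1", "b2", "x"]


def test_accepted_parent_makes_non_immigrant():
    out = classify_immigrant("focal", GROUP, {"c1": ["focal"]},
                             {("a1", "focal")}, {m: 100.0 for m in GROUP})
    assert out == "non-immigrant"


def test_own_offspring_do_not_make_non_immigrant():
    # focal produced a1 after arriving; that is no evidence of philopatry
    clusters = {"c1": ["focal", "a1"], "c2": ["b1", "b2"]}
    ages = {"focal": 300.0, "a1": 50.0, "b1": 400.0, "b2": 100.0, "a2": 90.0, "x": 10.0}
    out = classify_immigrant("focal", GROUP, clusters, {("focal", "a1")}, ages)
    assert out == "immigrant"  # flanked by older (b1) and younger (b2) kin group


def test_sibling_cluster_makes_non_immigrant():
    clusters = {"c1": ["focal", "a1"]}
    out = classify_immigrant("focal", GROUP, clusters, set(),
                             {m: 100.0 for m in GROUP})
    assert out == "non-immigrant"


def test_singleton_with_only_older_cluster_is_possible():
    clusters = {"c1": ["focal"], "c2": ["a1", "a2"]}
    ages = {"focal": 100.0, "a1": 300.0, "a2": 250.0}
    out = classify_immigrant("focal", ["focal", "a1", "a2"], clusters, set(), ages)
    assert out == "possible immigrant"


def test_flanking_clusters_make_assured_immigrant():
    clusters = {"c1": ["focal"], "c2": ["a1", "a2"], "c3": ["b1", "b2"]}
    ages = {"focal": 200.0, "a1": 400.0, "a2": 350.0, "b1": 80.0, "b2": 50.0}
    out = classify_immigrant("focal", ["focal", "a1", "a2", "b1", "b2"],
                             clusters, set(), ages)
    assert out == "immigrant"


def test_singletons_do_not_count_as_kin_groups():
    clusters = {"c1": ["focal"], "c2": ["a1"], "c3": ["b1"]}
    ages = {"focal": 200.0, "a1": 400.0, "b1": 50.0}
    out = classify_immigrant("focal", ["focal", "a1", "b1"], clusters, set(), ages)
    assert out == "possible immigrant"


def test_missing_age_conservative_with_warning():
    clusters = {"c1": ["focal"], "c2": ["a1", "a2"], "c3": ["b1", "b2"]}
    ages = {"a1": 400.0, "a2": 350.0, "b1": 80.0, "b2": 50.0}
    with pytest.warns(UserWarning, match="missing age"):
        out = classify_immigrant("focal", ["focal", "a1", "a2", "b1", "b2"],
                                 clusters, set(), ages)
    assert out == "possible immigrant"


def test_classes_exhaustive_and_exclusive():
    rng = np.random.default_rng(0)
    for _ in range(100):
        members = [f"m{i}" for i in range(rng.integers(1, 8))]
        focal = members[0]
        k = rng.integers(1, 4)
        clusters = {}
        for i, m in enumerate(members):
            clusters.setdefault(f"c{rng.integers(0, k)}", []).append(m)
        ages = {m: float(rng.integers(10, 500)) for m in members}
        links = set()
        if len(members) > 1 and rng.random() < 0.5:
            links.add((members[1], focal))
        out = classify_immigrant(focal, members, clusters, links, ages)
        assert out in IMMIGRANT_CLASSES


# ----------------------------------------------------------------------
# inheritance
# ----------------------------------------------------------------------

def test_other_sex_parent_present_is_inherited():
    links = {"mother": {("mum", "boss")}, "father": set()}
    assert detect_inheritance("boss", "M", ["boss", "mum"], {}, links,
                              {"boss": 400.0, "mum": 900.0})


def test_no_kin_in_group_not_inherited():
    links = {"mother": set(), "father": set()}
    assert not detect_inheritance("boss", "M", ["boss", "x"], {"c1": ["boss"]},
                                  links, {"boss": 400.0, "x": 100.0})


def test_similar_aged_sibling_triggers_inheritance():
    links = {"mother": set(), "father": set()}
    clusters = {"c1": ["boss", "sib"]}
    assert detect_inheritance("boss", "F", ["boss", "sib"], clusters, links,
                              {"boss": 400.0, "sib": 360.0}, similar_age_window=90.0)
    assert not detect_inheritance("boss", "F", ["boss", "sib"], clusters, links,
                                  {"boss": 400.0, "sib": 100.0},
                                  similar_age_window=90.0)


# ----------------------------------------------------------------------
# tenure
# ----------------------------------------------------------------------

def test_tenure_censored_without_older_non_immigrant():
    est = estimate_tenure("b", ["b", "y"], [], {"y": "immigrant"}, {"b": 500.0, "y": 300.0})
    assert est.t_min == 0.0 and est.censored and est.tenure is None


def test_tenure_mean_of_bounds():
    est = estimate_tenure(
        "b", ["b", "kid", "older"], ["kid"],
        {"kid": "non-immigrant", "older": "non-immigrant"},
        {"b": 600.0, "kid": 100.0, "older": 300.0})
    assert est.t_min == 100.0
    assert est.t_max == 300.0
    assert est.tenure == 200.0
    assert not est.censored


def test_tenure_ignores_own_offspring_and_immigrants_for_upper_bound():
    est = estimate_tenure(
        "b", ["b", "kid", "imm", "old_kid"], ["kid", "old_kid"],
        {"kid": "non-immigrant", "imm": "immigrant", "old_kid": "non-immigrant"},
        {"b": 600.0, "kid": 100.0, "imm": 250.0, "old_kid": 320.0})
    # own produced members and immigrants cannot bound the tenure above
    assert est.t_min == 320.0
    assert est.censored


def test_tenure_invariant_to_cluster_relabeling(recovery_run):
    """Tenure depends on parentage/immigrant classes only, not cluster ids."""
    demo = recovery_run["demography"]
    from socialkin.demography import build_demography_report

    relabeled = {
        group: {f"z{idx}": members for idx, (_, members) in enumerate(sorted(clusters.items()))}
        for group, clusters in recovery_run["partitions"].items()
    }
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        demo2 = build_demography_report(
            recovery_run["dataset"], recovery_run["freqs"], recovery_run["growth"],
            relabeled, recovery_run["parentage"]).set_index("id")
    breeders = demo[demo["status"].str.startswith("breeder")]
    for ind in breeders.index:
        a, b = demo.at[ind, "tenure_mean"], demo2.at[ind, "tenure_mean"]
        both_missing = pd.isna(a) and pd.isna(b)
        assert both_missing or a == b
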