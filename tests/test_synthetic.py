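import dataclasses

import numpy as np
import pytest
from scipy import stats

from socialkin.genotypes import MISSING
from socialkin.kinship import HYPOTHESES
from socialkin.synthetic_data import (
    SimulationConfig,
    inject_errors,
    simulate_dyads,
    simulate_population,
    write_truth_tables,
)


SMALL = dict(n_groups=8, sim_days=480.0, seed=3)


def test_config_validation():
    with pytest.raises(ValueError, match="outside"):
        SimulationConfig(p_helper_immigrant=1.5)
    with pytest.raises(ValueError, match="range"):
        SimulationConfig(subgroups_per_group=(3, 1))
    with pytest.raises(ValueError, match="sim_days"):
        SimulationConfig(sim_days=10.0, breeding_interval=30.0)
    with pytest.raises(ValueError, match="group size"):
        SimulationConfig(n_groups=0)
    with pytest.raises(ValueError, match="asymptotic"):
        SimulationConfig(maturity_sizes=(90.0, 31.5))


def test_seed_determinism():
    ds1, truth1 = simulate_population(SimulationConfig(**SMALL))
    ds2, truth2 = simulate_population(SimulationConfig(**SMALL))
    assert ds1.equals(ds2)
    assert truth1.pedigree == truth2.pedigree
    assert truth1.tenure_true == truth2.tenure_true
    assert truth1.group_history == truth2.group_history


def test_founder_frequencies_sum_to_one():
    _, truth = simulate_population(SimulationConfig(**SMALL))
    for locus, table in truth.founder_freqs.freqs.items():
        assert abs(sum(table.values()) - 1.0) < 1e-12


def test_mendelian_consistency_zero_error():
    ds, truth = simulate_population(SimulationConfig(**SMALL))
    present = set(ds.individuals)
    checked = 0
    for off, (mother, father, _) in truth.pedigree.items():
        if off not in present:
            continue
        for parent in (mother, father):
            if parent not in present:
                continue
            for locus in ds.loci:
                co, cp = ds.get_call(off, locus), ds.get_call(parent, locus)
                assert co is not None and cp is not None
                assert set(co) & set(cp), (off, parent, locus)
                checked += 1
    assert checked > 100


def test_closed_group_single_kin_line():
    cfg = SimulationConfig(n_groups=5, subgroups_per_group=(1, 1),
                           p_helper_immigrant=0.0, p_inherit_male=1.0,
                           p_inherit_female=1.0, p_helper_paternity=0.0,
                           p_helper_maternity=0.0, sim_days=480.0, seed=9)
    ds, truth = simulate_population(cfg)
    for ind, klass in truth.immigrant_class_true.items():
        if ind in truth.founders:
            continue
        assert klass == "philopatric"


def test_statuses_follow_size_boundary():
    ds, _ = simulate_population(SimulationConfig(**SMALL))
    for ind in ds.individuals:
        status = ds.meta.at[ind, "status"]
        sl = ds.meta.at[ind, "sl_mm"]
        if status == "offspring":
            assert sl < 15.0
        elif status == "helper":
            assert sl >= 15.0


def test_pedigree_parents_were_mature_at_birth():
    cfg = SimulationConfig(**SMALL)
    ds, truth = simulate_population(cfg)
    growth = cfg.growth_model()
    from socialkin.demography import get_size_age_cache

    cache = get_size_age_cache(growth)
    birth = {}
    for off, (m, f, day) in truth.pedigree.items():
        birth[off] = day
    male_mat, female_mat = cfg.maturity_sizes
    for off, (mother, father, day) in truth.pedigree.items():
        for parent, threshold in ((mother, female_mat), (father, male_mat)):
            if parent in birth:
                age_at_spawning = day - birth[parent]
                assert cache.size(age_at_spawning) >= threshold - 0.5


def test_tenure_truth_within_bounds():
    cfg = SimulationConfig(**SMALL)
    _, truth = simulate_population(cfg)
    for start, end, censored in truth.tenure_true.values():
        assert 0.0 <= start <= end <= cfg.sim_days


def test_immigrant_fraction_tracks_parameter():
    """Monte-Carlo check of the generator against its own parameter."""
    fracs = []
    for seed in range(10):
        cfg = SimulationConfig(n_groups=40, p_helper_immigrant=0.17,
                               p_inherit_male=1.0, p_inherit_female=1.0,
                               seed=100 + seed)
        ds, truth = simulate_population(cfg)
        nonfounders = [i for i in ds.individuals if i not in truth.founders]
        frac = np.mean([truth.immigrant_class_true[i] == "immigrant"
                        for i in nonfounders])
        fracs.append(frac)
    assert abs(np.mean(fracs) - 0.17) < 0.05


def test_truth_tables_written_as_csv(tmp_path):
    _, truth = simulate_population(SimulationConfig(**SMALL))
    write_truth_tables(truth, tmp_path)
    import pandas as pd

    ped = pd.read_csv(tmp_path / "pedigree.csv")
    imm = pd.read_csv(tmp_path / "immigrants.csv")
    ten = pd.read_csv(tmp_path / "tenure.csv")
    assert set(ped.columns) == {"offspring", "mother", "father", "birth_day"}
    assert len(imm) == len(truth.immigrant_class_true)
    assert len(ten) == len(truth.tenure_true)


# ----------------------------------------------------------------------
# simulate_dyads
# ----------------------------------------------------------------------

def test_po_pairs_share_allele_everywhere(uniform_freqs):
    for gx, gy in simulate_dyads(HYPOTHESES["PO"], 300, uniform_freqs, seed=1):
        for locus in uniform_freqs.loci:
            assert set(gx[locus]) & set(gy[locus])


def test_u_pairs_independent_hwe(uniform_freqs):
    pairs = simulate_dyads(HYPOTHESES["U"], 4000, uniform_freqs, seed=2)
    # allele frequency of second members approx uniform
    counts = {}
    for _, gy in pairs:
        for a in gy["L01"]:
            counts[a] = counts.get(a, 0) + 1
    freqs = np.array(sorted(counts.values())) / (2 * len(pairs))
    assert np.allclose(freqs, 0.1, atol=0.02)


def test_fs_mean_relatedness(uniform_freqs):
    from socialkin.genotypes import qg_relatedness

    pairs = simulate_dyads(HYPOTHESES["FS"], 4000, uniform_freqs, seed=3)
    rs = [qg_relatedness(gx, gy, uniform_freqs) for gx, gy in pairs]
    assert np.mean(rs) == pytest.approx(0.5, abs=0.03)


def test_simulate_dyads_validation(uniform_freqs):
    with pytest.raises(ValueError):
        simulate_dyads(HYPOTHESES["U"], 0, uniform_freqs, seed=1)


# ----------------------------------------------------------------------
# inject_errors
# ----------------------------------------------------------------------

def test_inject_zero_rates_identity():
    ds, _ = simulate_population(SimulationConfig(**SMALL))
    out = inject_errors(ds, 0.0, 0.0, seed=1)
    assert out.equals(ds)


def test_inject_all_missing():
    ds, _ = simulate_population(SimulationConfig(**SMALL))
    out = inject_errors(ds, 0.0, 1.0, seed=1)
    for locus in out.loci:
        assert (out.calls[locus + "_1"] == MISSING).all()


def test_inject_rate_validation():
    ds, _ = simulate_population(SimulationConfig(**SMALL))
    with pytest.raises(ValueError):
        inject_errors(ds, -0.1, 0.0)
    with pytest.raises(ValueError):
        inject_errors(ds, 0.0, 1.1)


def test_error_count_within_binomial_bounds(uniform_freqs):
    from socialkin.synthetic_data import simulate_dyads

    pairs = simulate_dyads(HYPOTHESES["U"], 100, uniform_freqs, seed=4)
    from conftest import make_dataset

    ds = make_dataset({f"i{n:03d}": gx for n, (gx, _) in enumerate(pairs)},
                      uniform_freqs.loci)
    out = inject_errors(ds, 0.01, 0.0, seed=5, freqs=uniform_freqs)
    altered = int((out.calls != ds.calls).to_numpy().sum())
    lo, hi = stats.binom.ppf([0.005, 0.995], 2000, 0.01)
    assert lo <= altered <= hi
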