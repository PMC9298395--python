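import io

import numpy as np
import pandas as pd
import pytest

from socialkin.genotypes import AlleleFrequencyBlock, GenotypeDataset


@pytest.fixture(scope="session")
def uniform_freqs():
    """10 loci x 10 equifrequent alleles."""
    return AlleleFrequencyBlock(
        {f"L{i:02d}": {str(a): 0.1 for a in range(1, 11)} for i in range(1, 11)})


@pytest.fixture(scope="session")
def biallelic_freqs():
    return AlleleFrequencyBlock({"L1": {"A": 0.5, "B": 0.5}})


@pytest.fixture(scope="session")
def growth_model():
    from socialkin.demography import GrowthModel

    return GrowthModel(alpha=0.38, beta=-0.087, s0=6.5)


def make_dataset(calls_by_ind, loci, meta_rows=None):
    """Build a GenotypeDataset from {id: {locus: (a, b) | None}}."""
    ids = list(calls_by_ind)
    calls = pd.DataFrame(index=pd.Index(ids, name="id"))
    for locus in loci:
        calls[locus + "_1"] = [
            (calls_by_ind[i].get(locus) or ("0", "0"))[0] for i in ids]
        calls[locus + "_2"] = [
            (calls_by_ind[i].get(locus) or ("0", "0"))[1] for i in ids]
    meta = pd.DataFrame(meta_rows or {}, index=calls.index)
    return GenotypeDataset(list(loci), calls, meta)


@pytest.fixture()
def tiny_csv_text():
    """Hand-written 3-individual, 2-locus pipeline CSV."""
    return (
        "id,population,group,subgroup,status,sex,sl_mm,LA_1,LA_2,LB_1,LB_2\n"
        "f1,KK,G1,G1s1,breeder male,M,55.0,1,2,3,3\n"
        "f2,KK,G1,G1s1,breeder female,F,44.5,2,2,1,3\n"
        "f3,KK,G1,G1s1,helper,unknown,20.0,1,2,0,0\n"
    )


@pytest.fixture(scope="session")
def sib_family_factory(uniform_freqs):
    """Factory producing full-sib families under the uniform 10x10 panel."""

    def make(n_kids, rng):
        loci = uniform_freqs.loci
        mom = {l: (str(rng.integers(1, 11)), str(rng.integers(1, 11))) for l in loci}
        dad = {l: (str(rng.integers(1, 11)), str(rng.integers(1, 11))) for l in loci}
        kids = []
        for _ in range(n_kids):
            kid = {l: (mom[l][rng.integers(0, 2)], dad[l][rng.integers(0, 2)])
                   for l in loci}
            kids.append(kid)
        return mom, dad, kids

    return make


@pytest.fixture(scope="session")
def recovery_run():
    """One full reconstruction on a simulated population (shared, seed-fixed).

    Used by the parameter-recovery tests; computed once per session.
    """
    import warnings

    from socialkin.demography import build_demography_report
    from socialkin.genotypes import estimate_allele_frequencies
    from socialkin.kinship import (HYPOTHESES, assign_parentage,
                                   null_lambda_sample, split_kin_groups)
    from socialkin.synthetic_data import SimulationConfig, simulate_population

    cfg = SimulationConfig(
        n_groups=35, seed=12, n_loci=13, alleles_per_locus=(8, 14),
        founder_freq_concentration=5.0, male_tenure_median=450.0,
        female_tenure_median=330.0, p_helper_paternity=0.05,
        p_helper_maternity=0.05)
    dataset, truth = simulate_population(cfg)
    freqs = estimate_allele_frequencies(dataset, method="corrected")
    growth = cfg.growth_model()
    null_fs = null_lambda_sample(HYPOTHESES["FS"], HYPOTHESES["U"], freqs, 2000, 101)
    genotypes = {i: dataset.genotype_of(i) for i in dataset.individuals}
    partitions = {}
    for group, members in sorted(dataset.groups().items()):
        part = split_kin_groups(members, genotypes, freqs, null_lambdas=null_fs)
        partitions[group] = part.clusters
    parentage = assign_parentage(dataset, freqs, growth,
                                 maturity_sizes=cfg.maturity_sizes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        demography = build_demography_report(dataset, freqs, growth,
                                             partitions, parentage)
    return {
        "config": cfg, "dataset": dataset, "truth": truth, "freqs": freqs,
        "growth": growth, "partitions": partitions, "parentage": parentage,
        "demography": demography.set_index("id"),
    }
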