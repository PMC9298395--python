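"""Forward simulation of multi-layered cooperative breeding groups.

Groups consist of a breeder male holding one to several breeder females,
each with her own subgroup of helpers. The simulator advances in breeding
intervals: breeders are deposed by a memoryless hazard calibrated to a
median tenure and replaced either from within the group (inheritance) or by
an immigrant; subgroups recruit new members that are either broods produced
by the resident breeders (with occasional helper parentage) or immigrant
helpers. Genotypes follow Mendelian inheritance from founder allele
frequencies, and every run emits both the observable genotype dataset and
truth tables (pedigree, immigrant classes, tenures) for parameter-recovery
testing.

All randomness flows from a single generator seeded by the config; draws
happen in documented order (groups, then subgroups, then members, always in
id order), so identical configs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .demography import GrowthModel, get_size_age_cache
from .genotypes import (
    MISSING,
    AlleleFrequencyBlock,
    Call,
    GenotypeDataset,
    estimate_allele_frequencies,
)
from .kinship import KCoefficients

__all__ = [
    "SimulationConfig",
    "TruthTables",
    "simulate_population",
    "simulate_dyads",
    "inject_errors",
    "write_truth_tables",
]

HELPER_SIZE_MM = 15.0  # status boundary: larger fish are helpers, smaller offspring


@dataclass
class SimulationConfig:
    """Parameters of one simulated study population.

    Integer ranges are inclusive ``(min, max)`` tuples. ``growth_params``
    is ``(alpha, beta, s0)`` for the shared growth model;
    ``maturity_sizes`` is ``(male, female)`` in mm.
    """

    n_groups: int = 40
    subgroups_per_group: tuple[int, int] = (1, 4)
    helpers_per_subgroup: tuple[int, int] = (2, 10)
    n_loci: int = 10
    alleles_per_locus: tuple[int, int] = (6, 10)
    founder_freq_concentration: float = 2.0
    sim_days: float = 600.0
    breeding_interval: float = 30.0
    male_tenure_median: float = 257.5
    female_tenure_median: float = 191.5
    p_inherit_male: float = 0.33
    p_inherit_female: float = 0.52
    p_helper_immigrant: float = 0.17
    p_helper_paternity: float = 0.10
    p_helper_maternity: float = 0.05
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    growth_params: tuple[float, float, float] = (0.38, -0.087, 6.5)
    maturity_sizes: tuple[float, float] = (32.5, 31.5)
    seed: int = 0
    # mechanics not pinned by any printed number
    mean_recruits_per_interval: float = 1.5
    p_independent: float = 0.002

    def __post_init__(self) -> None:
        probs = {
            "p_inherit_male": self.p_inherit_male,
            "p_inherit_female": self.p_inherit_female,
            "p_helper_immigrant": self.p_helper_immigrant,
            "p_helper_paternity": self.p_helper_paternity,
            "p_helper_maternity": self.p_helper_maternity,
            "genotyping_error_rate": self.genotyping_error_rate,
            "missing_rate": self.missing_rate,
            "p_independent": self.p_independent,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name, rng_ in (("subgroups_per_group", self.subgroups_per_group),
                           ("helpers_per_subgroup", self.helpers_per_subgroup),
                           ("alleles_per_locus", self.alleles_per_locus)):
            if len(rng_) != 2 or rng_[0] > rng_[1]:
                raise ValueError(f"{name}: empty range {rng_}")
        if not (self.sim_days > self.breeding_interval > 0):
            raise ValueError("require sim_days > breeding_interval > 0")
        if self.n_groups < 1 or self.subgroups_per_group[0] < 1:
            raise ValueError("expected group size is zero")
        if self.n_loci < 1 or self.alleles_per_locus[0] < 2:
            raise ValueError("need >= 1 locus with >= 2 alleles")
        if min(self.male_tenure_median, self.female_tenure_median) <= 0:
            raise ValueError("tenure medians must be positive")
        model = self.growth_model()
        if max(self.maturity_sizes) >= model.s_inf:
            raise ValueError(
                f"maturity size {max(self.maturity_sizes)} exceeds asymptotic "
                f"size {model.s_inf:.1f}")

    def growth_model(self) -> GrowthModel:
        alpha, beta, s0 = self.growth_params
        return GrowthModel(alpha, beta, s0)


@dataclass
class TruthTables:
    """Simulator ground truth for parameter-recovery oracles.

    pedigree: offspring id -> (mother or None, father or None, birth day);
    immigrant_class_true: present individual -> "philopatric" | "immigrant";
    tenure_true: breeder id -> (start day, end day, censored);
    group_history: chronological (day, event, ids) records;
    founders: ids seeded at day 0 (immigrant by origin, but not recruits);
    founder_freqs: the allele frequencies founders were drawn from;
    clean_dataset: the emitted snapshot before genotyping-error injection.
    """

    pedigree: dict[str, tuple[Optional[str], Optional[str], float]]
    immigrant_class_true: dict[str, str]
    tenure_true: dict[str, tuple[float, float, bool]]
    group_history: list[tuple[float, str, tuple]]
    founders: set[str]
    founder_freqs: AlleleFrequencyBlock
    clean_dataset: GenotypeDataset


class _Ind:
    __slots__ = ("id", "sex", "birth_day", "genotype", "origin", "mother",
                 "father", "group", "subgroup", "role", "present")

    def __init__(self, id, sex, birth_day, genotype, origin, mother, father,
                 group, subgroup, role):
        self.id = id
        self.sex = sex
        self.birth_day = birth_day
        self.genotype = genotype  # (n_loci, 2) int array, alleles as 1-based ints
        self.origin = origin      # founder | immigrant | born
        self.mother = mother
        self.father = father
        self.group = group
        self.subgroup = subgroup
        self.role = role          # breeder_m | breeder_f | member | independent
        self.present = True


class _Sim:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.growth = config.growth_model()
        self.cache = get_size_age_cache(self.growth)
        self.inds: dict[str, _Ind] = {}
        self.serial = 0
        self.history: list[tuple[float, str, tuple]] = []
        self.tenure: dict[str, list] = {}  # id -> [start, end, censored]
        self.subgroup_targets: dict[str, int] = {}
        self.subgroups_of: dict[str, list[str]] = {}
        self.founder_freqs = self._draw_founder_freqs()
        self.allele_probs = {
            locus: np.array(list(self.founder_freqs.freqs[locus].values()))
            for locus in self.founder_freqs.loci
        }
        max_size = min(65.0, self.growth.s_inf - 2.0)
        self.size_bounds = {
            "breeder_m": (max(config.maturity_sizes[0] + 4, 45.0), max_size),
            "breeder_f": (max(config.maturity_sizes[1] + 2, 33.0), min(50.0, max_size)),
            "helper": (HELPER_SIZE_MM + 1.0, min(36.0, max_size)),
        }

    # -- primitives ----------------------------------------------------
    def _draw_founder_freqs(self) -> AlleleFrequencyBlock:
        cfg = self.cfg
        freqs = {}
        for l in range(cfg.n_loci):
            n_alleles = int(self.rng.integers(cfg.alleles_per_locus[0],
                                              cfg.alleles_per_locus[1] + 1))
            p = self.rng.dirichlet(np.full(n_alleles, cfg.founder_freq_concentration))
            p = np.maximum(p, 1e-4)
            p = p / p.sum()
            freqs[f"L{l + 1:02d}"] = {str(a + 1): float(p[a]) for a in range(n_alleles)}
        return AlleleFrequencyBlock(freqs, provenance="external")

    def _new_id(self) -> str:
        self.serial += 1
        return f"I{self.serial:05d}"

    def _founder_genotype(self) -> np.ndarray:
        geno = np.empty((self.cfg.n_loci, 2), dtype=np.int64)
        for l, locus in enumerate(self.founder_freqs.loci):
            p = self.allele_probs[locus]
            geno[l] = self.rng.choice(len(p), size=2, p=p) + 1
        return geno

    def _mendelian_genotype(self, mother: _Ind, father: _Ind) -> np.ndarray:
        picks = self.rng.integers(0, 2, size=(self.cfg.n_loci, 2))
        geno = np.empty((self.cfg.n_loci, 2), dtype=np.int64)
        geno[:, 0] = mother.genotype[np.arange(self.cfg.n_loci), picks[:, 0]]
        geno[:, 1] = father.genotype[np.arange(self.cfg.n_loci), picks[:, 1]]
        return geno

    def size_at(self, ind: _Ind, day: float) -> float:
        return self.cache.size(day - ind.birth_day)

    def _spawn_external(self, day: float, sex: str, size_range, role, group,
                        subgroup, origin) -> _Ind:
        size = float(self.rng.uniform(*size_range))
        birth_day = day - self.cache.age(size)
        ind = _Ind(self._new_id(), sex, birth_day, self._founder_genotype(),
                   origin, None, None, group, subgroup, role)
        self.inds[ind.id] = ind
        return ind

    def _mature(self, ind: _Ind, day: float) -> bool:
        threshold = self.cfg.maturity_sizes[0 if ind.sex == "M" else 1]
        return self.size_at(ind, day) >= threshold

    def _group_members(self, group: str) -> list[_Ind]:
        return [i for i in self.inds.values() if i.present and i.group == group]

    # -- stages ----------------------------------------------------------
    def found_groups(self) -> None:
        cfg = self.cfg
        for g in range(cfg.n_groups):
            group = f"G{g + 1:02d}"
            male = self._spawn_external(0.0, "M", self.size_bounds["breeder_m"],
                                        "breeder_m", group, "", "founder")
            self.tenure[male.id] = [0.0, None, None]
            n_sub = int(self.rng.integers(cfg.subgroups_per_group[0],
                                          cfg.subgroups_per_group[1] + 1))
            self.subgroups_of[group] = []
            for s in range(n_sub):
                subgroup = f"{group}s{s + 1}"
                self.subgroups_of[group].append(subgroup)
                female = self._spawn_external(0.0, "F", self.size_bounds["breeder_f"],
                                              "breeder_f", group, subgroup, "founder")
                self.tenure[female.id] = [0.0, None, None]
                self.subgroup_targets[subgroup] = int(
                    self.rng.integers(cfg.helpers_per_subgroup[0],
                                      cfg.helpers_per_subgroup[1] + 1))
            male.subgroup = self.subgroups_of[group][0]
            self.history.append((0.0, "found", (group, male.id)))

    def _breeder_of(self, group: str, subgroup: str | None, role: str) -> Optional[_Ind]:
        for ind in self._group_members(group):
            if ind.role != role:
                continue
            if subgroup is None or ind.subgroup == subgroup or role == "breeder_m":
                return ind
        return None

    def turnover(self, day: float) -> None:
        cfg = self.cfg
        h_m = 1.0 - 0.5 ** (cfg.breeding_interval / cfg.male_tenure_median)
        h_f = 1.0 - 0.5 ** (cfg.breeding_interval / cfg.female_tenure_median)
        for g in range(cfg.n_groups):
            group = f"G{g + 1:02d}"
            male = self._breeder_of(group, None, "breeder_m")
            if male is not None and self.rng.random() < h_m:
                self._replace_breeder(day, male, "M", cfg.p_inherit_male)
            for subgroup in self.subgroups_of[group]:
                female = self._breeder_of(group, subgroup, "breeder_f")
                if female is not None and self.rng.random() < h_f:
                    self._replace_breeder(day, female, "F", cfg.p_inherit_female)

    def _replace_breeder(self, day: float, old: _Ind, sex: str, p_inherit: float) -> None:
        group, subgroup = old.group, old.subgroup
        inherit = self.rng.random() < p_inherit
        new: Optional[_Ind] = None
        if inherit:
            candidates = [i for i in self._group_members(group)
                          if i.role == "member" and i.sex == sex and self._mature(i, day)]
            if not candidates:
                # inheritance drawn but no eligible heir: the breeder stays
                return
            new = max(candidates, key=lambda i: (self.size_at(i, day), i.id))
        old.present = False
        self.tenure[old.id][1:] = [day, False]
        self.history.append((day, "depose", (old.id,)))
        role = "breeder_m" if sex == "M" else "breeder_f"
        if new is not None:
            new.role = role
            new.subgroup = subgroup
            self.history.append((day, "inherit", (new.id, subgroup)))
        else:
            new = self._spawn_external(day, sex, self.size_bounds[role], role,
                                       group, subgroup, "immigrant")
            self.history.append((day, "takeover", (new.id, subgroup)))
        self.tenure[new.id] = [day, None, None]

    def recruit(self, day: float) -> None:
        cfg = self.cfg
        for g in range(cfg.n_groups):
            group = f"G{g + 1:02d}"
            members = self._group_members(group)
            for subgroup in self.subgroups_of[group]:
                current = sum(1 for i in members
                              if i.subgroup == subgroup and i.role == "member")
                room = self.subgroup_targets[subgroup] - current
                if room <= 0:
                    continue
                n_new = min(int(self.rng.poisson(cfg.mean_recruits_per_interval)), room)
                if n_new == 0:
                    continue
                flips = self.rng.random(n_new) < cfg.p_helper_immigrant
                brood_parents: Optional[tuple[_Ind, _Ind]] = None
                for is_immigrant in flips:
                    if is_immigrant:
                        sex = "M" if self.rng.random() < 0.5 else "F"
                        ind = self._spawn_external(day, sex, self.size_bounds["helper"],
                                                   "member", group, subgroup, "immigrant")
                        self.history.append((day, "immigrate", (ind.id, subgroup)))
                    else:
                        if brood_parents is None:
                            brood_parents = self._choose_brood_parents(day, group, subgroup)
                        mother, father = brood_parents
                        sex = "M" if self.rng.random() < 0.5 else "F"
                        ind = _Ind(self._new_id(), sex, day,
                                   self._mendelian_genotype(mother, father), "born",
                                   mother.id, father.id, group, subgroup, "member")
                        self.inds[ind.id] = ind
                        self.history.append((day, "birth", (ind.id, mother.id, father.id)))

    def _choose_brood_parents(self, day: float, group: str,
                              subgroup: str) -> tuple[_Ind, _Ind]:
        cfg = self.cfg
        members = self._group_members(group)
        mother = self._breeder_of(group, subgroup, "breeder_f")
        father = self._breeder_of(group, None, "breeder_m")
        helper_f = sorted((i for i in members if i.role == "member" and i.sex == "F"
                           and i.subgroup == subgroup and self._mature(i, day)),
                          key=lambda i: i.id)
        helper_m = sorted((i for i in members if i.role == "member" and i.sex == "M"
                           and self._mature(i, day)), key=lambda i: i.id)
        if helper_f and self.rng.random() < cfg.p_helper_maternity:
            mother = helper_f[int(self.rng.integers(len(helper_f)))]
        if helper_m and self.rng.random() < cfg.p_helper_paternity:
            father = helper_m[int(self.rng.integers(len(helper_m)))]
        assert mother is not None and father is not None
        return mother, father

    def emancipate(self, day: float) -> None:
        if self.cfg.p_independent <= 0:
            return
        for ind in sorted(self.inds.values(), key=lambda i: i.id):
            if (ind.present and ind.role == "member"
                    and self.size_at(ind, day) >= HELPER_SIZE_MM
                    and self.rng.random() < self.cfg.p_independent):
                ind.role = "independent"
                self.history.append((day, "independent", (ind.id,)))

    # -- emission --------------------------------------------------------
    def run(self) -> tuple[GenotypeDataset, TruthTables]:
        cfg = self.cfg
        self.found_groups()
        day = cfg.breeding_interval
        while day <= cfg.sim_days + 1e-9:
            self.turnover(day)
            self.recruit(day)
            self.emancipate(day)
            day += cfg.breeding_interval

        present = [i for i in self.inds.values() if i.present]
        present.sort(key=lambda i: i.id)
        loci = self.founder_freqs.loci
        calls = pd.DataFrame(index=pd.Index([i.id for i in present], name="id"))
        for l, locus in enumerate(loci):
            calls[locus + "_1"] = [str(i.genotype[l, 0]) for i in present]
            calls[locus + "_2"] = [str(i.genotype[l, 1]) for i in present]
        meta = pd.DataFrame(index=calls.index)
        statuses, sls = [], []
        for ind in present:
            size = self.size_at(ind, cfg.sim_days)
            sls.append(round(size, 1))
            if ind.role == "breeder_m":
                statuses.append("breeder male")
            elif ind.role == "breeder_f":
                statuses.append("breeder female")
            elif ind.role == "independent":
                statuses.append("independent")
            else:
                statuses.append("helper" if size >= HELPER_SIZE_MM else "offspring")
        meta["population"] = "SIM"
        meta["group"] = [i.group for i in present]
        meta["subgroup"] = [i.subgroup for i in present]
        meta["status"] = statuses
        meta["sex"] = [i.sex for i in present]
        meta["sl_mm"] = sls
        for col, lam in (("defence_con", 3.0), ("defence_het", 2.0),
                         ("chamber_visits", 2.0), ("maintenance", 1.5)):
            meta[col] = [int(self.rng.poisson(lam)) if s != "offspring" else 0
                         for s in statuses]
        meta["protocol"] = "single-10min"
        clean = GenotypeDataset(list(loci), calls, meta)

        pedigree = {i.id: (i.mother, i.father, float(i.birth_day))
                    for i in sorted(self.inds.values(), key=lambda x: x.id)
                    if i.origin == "born"}
        immigrant_true = {
            i.id: ("philopatric" if i.origin == "born" else "immigrant")
            for i in present
        }
        tenure_true = {}
        for bid, (start, end, censored) in self.tenure.items():
            if end is None:
                end, censored = cfg.sim_days, True
            tenure_true[bid] = (float(start), float(end), bool(censored))
        founders = {i.id for i in self.inds.values() if i.origin == "founder"}

        observed = inject_errors(clean, cfg.genotyping_error_rate, cfg.missing_rate,
                                 seed=int(self.rng.integers(2 ** 31)),
                                 freqs=self.founder_freqs)
        truth = TruthTables(pedigree, immigrant_true, tenure_true, self.history,
                            founders, self.founder_freqs, clean)
        return observed, truth


def simulate_population(config: SimulationConfig) -> tuple[GenotypeDataset, TruthTables]:
    """Forward-simulate a study population; see module docstring.

    Returns the observable dataset (after genotyping-error/missingness
    injection at the configured rates) and the matching truth tables.
    Identical config (including seed) gives identical output.
    """
    return _Sim(config).run()


# ----------------------------------------------------------------------
# Dyad simulator
# ----------------------------------------------------------------------

def simulate_dyads(hypothesis: KCoefficients, n: int, freqs: AlleleFrequencyBlock,
                   seed: int = 0) -> list[tuple[dict[str, Call], dict[str, Call]]]:
    """Draw ``n`` genotype pairs under a k-coefficient hypothesis.

    The first genotype is an HWE draw from ``freqs``; the second shares
    0/1/2 alleles identical by descent with probabilities ``(k0, k1, k2)``
    per locus, non-IBD alleles drawn from ``freqs``. Deterministic under
    ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    k = np.array([hypothesis.k0, hypothesis.k1, hypothesis.k2])
    per_locus: dict[str, tuple] = {}
    for locus in freqs.loci:
        alleles = np.array(freqs.alleles(locus))
        p = np.array([freqs.freqs[locus][a] for a in alleles])
        p = p / p.sum()
        gx = rng.choice(len(alleles), size=(n, 2), p=p)
        ibd = rng.choice(3, size=n, p=k)
        extra = rng.choice(len(alleles), size=n, p=p)
        which = rng.integers(0, 2, size=n)   # which gx allele is shared when IBD=1
        order = rng.integers(0, 2, size=n)   # shuffle gy allele order
        gy = gx.copy()
        one = ibd == 1
        shared = gx[np.arange(n), which]
        gy[one, 0] = shared[one]
        gy[one, 1] = extra[one]
        zero = ibd == 0
        gy[zero, 0] = extra[zero]
        gy[zero, 1] = rng.choice(len(alleles), size=int(zero.sum()), p=p)
        flip = order == 1
        gy[flip] = gy[flip][:, ::-1]
        per_locus[locus] = (alleles, gx, gy)
    pairs = []
    for i in range(n):
        gx_i: dict[str, Call] = {}
        gy_i: dict[str, Call] = {}
        for locus, (alleles, gx, gy) in per_locus.items():
            gx_i[locus] = (str(alleles[gx[i, 0]]), str(alleles[gx[i, 1]]))
            gy_i[locus] = (str(alleles[gy[i, 0]]), str(alleles[gy[i, 1]]))
        pairs.append((gx_i, gy_i))
    return pairs


# ----------------------------------------------------------------------
# Error injection
# ----------------------------------------------------------------------

def inject_errors(dataset: GenotypeDataset, error_rate: float, missing_rate: float,
                  seed: int = 0,
                  freqs: AlleleFrequencyBlock | None = None) -> GenotypeDataset:
    """Perturb genotype calls; the matching truth tables stay valid.

    Each allele call is independently replaced by a frequency-weighted random
    allele with probability ``error_rate``; each locus call is then set
    missing with probability ``missing_rate``.
    """
    for name, rate in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name}={rate} outside [0, 1]")
    out = dataset.copy()
    if error_rate == 0.0 and missing_rate == 0.0:
        return out
    if freqs is None and error_rate > 0.0:
        freqs = estimate_allele_frequencies(dataset, method="naive")
    rng = np.random.default_rng(seed)
    n = len(out)
    for locus in out.loci:
        if error_rate > 0.0:
            alleles = list(freqs.freqs[locus])
            p = np.array([freqs.freqs[locus][a] for a in alleles])
            p = p / p.sum()
            for col in (locus + "_1", locus + "_2"):
                vals = out.calls[col].to_numpy(copy=True)
                hit = (rng.random(n) < error_rate) & (vals != MISSING)
                if hit.any():
                    vals[hit] = rng.choice(alleles, size=int(hit.sum()), p=p)
                out.calls[col] = vals
        if missing_rate > 0.0:
            drop = rng.random(n) < missing_rate
            if drop.any():
                cols = [locus + "_1", locus + "_2"]
                out.calls.loc[drop, cols] = MISSING
    return out


def write_truth_tables(truth: TruthTables, outdir) -> None:
    """Write pedigree.csv, immigrants.csv and tenure.csv under ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    ped = pd.DataFrame(
        [(o, m or "", f or "", b) for o, (m, f, b) in sorted(truth.pedigree.items())],
        columns=["offspring", "mother", "father", "birth_day"])
    ped.to_csv(os.path.join(outdir, "pedigree.csv"), index=False, lineterminator="\n")
    imm = pd.DataFrame(
        [(i, c, i in truth.founders) for i, c in sorted(truth.immigrant_class_true.items())],
        columns=["id", "class", "founder"])
    imm.to_csv(os.path.join(outdir, "immigrants.csv"), index=False, lineterminator="\n")
    ten = pd.DataFrame(
        [(b, s, e, c) for b, (s, e, c) in sorted(truth.tenure_true.items())],
        columns=["breeder", "start_day", "end_day", "censored"])
    ten.to_csv(os.path.join(outdir, "tenure.csv"), index=False, lineterminator="\n")
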