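"""Likelihood-based dyad classification, kin-group partitioning, parentage.

Relationship hypotheses are expressed as k-coefficients ``(k0, k1, k2)``:
the probabilities that a dyad shares 0, 1 or 2 alleles identical by descent
at a locus. Presets: U = (1,0,0), HS = (0.5,0.5,0), FS = (0.25,0.5,0.25),
PO = (0,1,0).

Significance of a hypothesis against the null of no relatedness is obtained
by simulating dyads under the null and ranking the observed log-likelihood
ratio within the simulated ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencyBlock, Call, GenotypeDataset, qg_relatedness, UninformativeDyadError

__all__ = [
    "KCoefficients",
    "HYPOTHESES",
    "NEG_INF",
    "dyad_log_likelihood",
    "null_lambda_sample",
    "classify_dyad",
    "ClassificationResult",
    "KinGroupPartition",
    "split_kin_groups",
    "ParentageAssignment",
    "assign_parentage",
    "build_dyad_table",
]

logger = logging.getLogger(__name__)

#: sentinel for an impossible genotype configuration under a hypothesis;
#: it loses every comparison and is never used in arithmetic
NEG_INF = float("-inf")


@dataclass(frozen=True)
class KCoefficients:
    """Probabilities of sharing 0/1/2 alleles identical by descent."""

    k0: float
    k1: float
    k2: float
    label: str = ""

    def __post_init__(self) -> None:
        for k in (self.k0, self.k1, self.k2):
            if not (0.0 <= k <= 1.0):
                raise ValueError("k-coefficients must lie in [0, 1]")
        if abs(self.k0 + self.k1 + self.k2 - 1.0) > 1e-9:
            raise ValueError("k-coefficients must sum to 1")


HYPOTHESES: dict[str, KCoefficients] = {
    "U": KCoefficients(1.0, 0.0, 0.0, "U"),
    "HS": KCoefficients(0.5, 0.5, 0.0, "HS"),
    "FS": KCoefficients(0.25, 0.5, 0.25, "FS"),
    "PO": KCoefficients(0.0, 1.0, 0.0, "PO"),
}


def _hwe_prob(call: tuple[str, str], p: Mapping[str, float]) -> float:
    a, b = call
    return p[a] * p[a] if a == b else 2.0 * p[a] * p[b]


def _t1(gy: tuple[str, str], gx: tuple[str, str], p: Mapping[str, float]) -> float:
    """P(gy | one allele of gy is IBD to a random allele of gx)."""
    c, d = gy
    total = 0.0
    for z in gx:
        if c == d:
            total += (z == c) * p[c]
        else:
            total += (z == c) * p[d] + (z == d) * p[c]
    return 0.5 * total


def dyad_log_likelihood(gx: Mapping[str, Call], gy: Mapping[str, Call],
                        k: KCoefficients, freqs: AlleleFrequencyBlock) -> float:
    """Multilocus log-likelihood of a dyad under a k-coefficient hypothesis.

    Per locus ``L = P(gx) [k0 P(gy) + k1 T1(gy|gx) + k2 T2(gy|gx)]`` where
    ``P`` is the HWE genotype probability, ``T1`` averages over which allele
    of ``gx`` is shared, and ``T2`` is the unordered-pair indicator. Loci
    missing in either member are skipped. Returns :data:`NEG_INF` when the
    configuration is impossible under ``k`` (e.g. PO with no shared allele).
    """
    total = 0.0
    used = 0
    for locus in freqs.loci:
        cx = gx.get(locus)
        cy = gy.get(locus)
        if cx is None or cy is None:
            continue
        p = freqs.freqs[locus]
        like = k.k0 * _hwe_prob(cy, p)
        if k.k1:
            like += k.k1 * _t1(cy, cx, p)
        if k.k2:
            like += k.k2 * float(sorted(cx) == sorted(cy))
        like *= _hwe_prob(cx, p)
        if like <= 0.0:
            return NEG_INF
        total += math.log(like)
        used += 1
    if used == 0:
        raise UninformativeDyadError("no locus typed in both individuals")
    return total


def _lambda(gx, gy, primary: KCoefficients, null: KCoefficients,
            freqs: AlleleFrequencyBlock) -> float:
    lp = dyad_log_likelihood(gx, gy, primary, freqs)
    if lp == NEG_INF:
        return NEG_INF
    ln = dyad_log_likelihood(gx, gy, null, freqs)
    return lp - ln


def null_lambda_sample(primary: KCoefficients, null: KCoefficients,
                       freqs: AlleleFrequencyBlock, n_null: int,
                       seed: int) -> np.ndarray:
    """Simulate the log-likelihood-ratio distribution under the null.

    The sample does not depend on the observed dyad, so it can be computed
    once per (hypothesis pair, frequency block) and reused across many
    classifications.
    """
    from .synthetic_data import simulate_dyads

    pairs = simulate_dyads(null, n_null, freqs, seed)
    return np.array([_lambda(gx, gy, primary, null, freqs) for gx, gy in pairs])


@dataclass
class ClassificationResult:
    """Outcome of testing one relationship hypothesis against the null."""

    log_lr: float
    p_value: float
    significant: bool
    hypothesis: str
    null: str


def classify_dyad(gx: Mapping[str, Call], gy: Mapping[str, Call],
                  primary: KCoefficients, null: KCoefficients,
                  freqs: AlleleFrequencyBlock, n_null: int = 10000,
                  alpha: float = 0.05, seed: int = 0,
                  null_lambdas: Optional[np.ndarray] = None) -> ClassificationResult:
    """Likelihood-ratio test of ``primary`` vs ``null`` for one dyad.

    ``p = (1 + #{null-simulated dyads with ratio >= observed}) / (1 + n_null)``
    with dyads simulated under ``null``; significant iff ``p <= alpha``.
    A precomputed ``null_lambdas`` vector (see :func:`null_lambda_sample`)
    bypasses the simulation. Deterministic under ``seed``.
    """
    if null_lambdas is None:
        if n_null < 1:
            raise ValueError("n_null must be >= 1")
        null_lambdas = null_lambda_sample(primary, null, freqs, n_null, seed)
    lam = _lambda(gx, gy, primary, null, freqs)
    if lam == NEG_INF:
        # primary hypothesis impossible: rejected outright
        return ClassificationResult(NEG_INF, 1.0, False, primary.label, null.label)
    # exact ties count half (mid-p); with a continuous ratio they have
    # measure zero, but the degenerate primary==null case then lands at 0.5
    above = int(np.sum(null_lambdas > lam + 1e-12))
    ties = int(np.sum(np.abs(null_lambdas - lam) <= 1e-12))
    p = (1 + above + 0.5 * ties) / (1 + len(null_lambdas))
    return ClassificationResult(lam, p, p <= alpha, primary.label, null.label)


# ----------------------------------------------------------------------
# Kin-group partitioning
# ----------------------------------------------------------------------

@dataclass
class KinGroupPartition:
    """Partition of one social group's members into kin clusters."""

    assignment: dict[str, str]
    clusters: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.clusters:
            for ind, cid in self.assignment.items():
                self.clusters.setdefault(cid, []).append(ind)
        covered = sorted(m for members in self.clusters.values() for m in members)
        if covered != sorted(self.assignment):
            raise ValueError("clusters do not partition the assigned members")


def split_kin_groups(
    members: Sequence[str],
    genotypes: Mapping[str, Mapping[str, Call]],
    freqs: AlleleFrequencyBlock,
    merge_threshold: float = 5.0,
    alpha: float = 0.05,
    seed: int = 0,
    n_null: int = 2000,
    null_lambdas: Optional[np.ndarray] = None,
) -> KinGroupPartition:
    """Partition group members into kin clusters by greedy LR agglomeration.

    Starting from singletons, the cluster pair with the highest geometric
    mean pairwise FS-vs-U likelihood ratio is merged while that mean ratio
    exceeds ``merge_threshold`` (ties broken lexicographically by smallest
    member id). The geometric mean (arithmetic mean of log ratios) is used
    because the arithmetic mean of ratios is dominated by a single lucky
    pair, which pulls unrelated members into real families. Afterwards each
    member of a multi-member cluster is re-validated by an FS-vs-U
    significance test against the cluster representative and demoted to a
    singleton on rejection, so misplaced non-relatives are filtered out.
    """
    members = sorted(members)
    fs, u = HYPOTHESES["FS"], HYPOTHESES["U"]
    n = len(members)
    if n == 1:
        return KinGroupPartition({members[0]: "c1"})

    log_lr = np.full((n, n), -np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                lam = _lambda(genotypes[members[i]], genotypes[members[j]], fs, u, freqs)
            except UninformativeDyadError:
                lam = -np.inf
            log_lr[i, j] = log_lr[j, i] = lam
    log_threshold = math.log(merge_threshold) if merge_threshold > 0 else -math.inf

    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                mean_loglr = float(np.mean([log_lr[i, j]
                                            for i in clusters[a] for j in clusters[b]]))
                key = (-mean_loglr, members[min(clusters[a] + clusters[b])])
                if best is None or key < best[0]:
                    best = (key, a, b, mean_loglr)
        _, a, b, mean_loglr = best
        if mean_loglr <= log_threshold:
            break
        clusters[a] = sorted(clusters[a] + clusters[b])
        del clusters[b]

    if null_lambdas is None:
        null_lambdas = null_lambda_sample(fs, u, freqs, n_null, seed)

    final: list[list[int]] = []
    singles: list[int] = []
    for cluster in clusters:
        if len(cluster) == 1:
            singles.append(cluster[0])
            continue
        # representative: the member with the strongest total kinship signal
        rep = max(cluster, key=lambda i: (sum(log_lr[i, j] for j in cluster if j != i),
                                          members[i]))
        kept = [rep]
        for i in cluster:
            if i == rep:
                continue
            res = classify_dyad(genotypes[members[i]], genotypes[members[rep]],
                                fs, u, freqs, alpha=alpha, null_lambdas=null_lambdas)
            if res.significant:
                kept.append(i)
            else:
                logger.info("split_kin_groups: %s demoted to singleton (p=%.3f)",
                            members[i], res.p_value)
                singles.append(i)
        if len(kept) == 1:
            singles.append(kept[0])
        else:
            final.append(sorted(kept))

    final.extend([s] for s in sorted(singles))
    final.sort(key=lambda c: members[c[0]])
    assignment = {}
    for idx, cluster in enumerate(final, start=1):
        for i in cluster:
            assignment[members[i]] = f"c{idx}"
    return KinGroupPartition(assignment)


# ----------------------------------------------------------------------
# Parentage
# ----------------------------------------------------------------------

@dataclass
class ParentageAssignment:
    """One candidate parent evaluated for one potential offspring."""

    offspring: str
    parent: str
    sex_role: str  # "mother" | "father"
    mismatch_count: int
    age_feasible: bool
    accepted: bool
    log_lr: float = float("nan")


def _mismatches(gx: Mapping[str, Call], gy: Mapping[str, Call], loci) -> int:
    count = 0
    for locus in loci:
        cx, cy = gx.get(locus), gy.get(locus)
        if cx is None or cy is None:
            continue
        if not (set(cx) & set(cy)):
            count += 1
    return count


def assign_parentage(
    dataset: GenotypeDataset,
    freqs: AlleleFrequencyBlock,
    growth,
    max_mismatch: int = 1,
    min_parent_size_at_spawning: float = 31.0,
    maturity_sizes: tuple[float, float] = (32.5, 31.5),
) -> list[ParentageAssignment]:
    """Pairwise Mendelian parentage under growth-derived age constraints.

    For every group member (potential offspring), same-group adults of known
    sex that are larger than it are screened. ``mismatch_count`` is the
    number of loci at which candidate and offspring share no allele;
    ``age_feasible`` requires the candidate's back-calculated size at the
    offspring's estimated spawning date to reach
    ``min_parent_size_at_spawning``. A candidate is accepted iff
    ``mismatch_count <= max_mismatch`` and feasible; at most one mother and
    one father per offspring (fewest mismatches, then highest PO-vs-U
    likelihood ratio; exact ties leave both reported but unaccepted).

    ``maturity_sizes`` are the (male, female) adult size thresholds in mm.
    """
    from .demography import get_size_age_cache

    cache = get_size_age_cache(growth)  # interpolated transforms (<0.01 day)
    meta = dataset.meta
    po, u = HYPOTHESES["PO"], HYPOTHESES["U"]
    genotypes = {ind: dataset.genotype_of(ind) for ind in dataset.individuals}
    sizes: dict[str, float] = {}
    ages: dict[str, Optional[float]] = {}
    for ind in dataset.individuals:
        sl = meta.at[ind, "sl_mm"]
        if sl is None or (isinstance(sl, float) and math.isnan(sl)):
            ages[ind] = None
            continue
        sl = float(sl)
        sizes[ind] = sl
        ages[ind] = cache.age(max(min(sl, growth.s_inf - 0.5), growth.s0))

    male_mat, female_mat = maturity_sizes
    results: list[ParentageAssignment] = []
    for group, group_members in sorted(dataset.groups().items()):
        group_members = sorted(group_members)
        for off in group_members:
            if ages.get(off) is None:
                continue
            candidates: dict[str, list[ParentageAssignment]] = {"mother": [], "father": []}
            for cand in group_members:
                if cand == off or ages.get(cand) is None:
                    continue
                sex = str(meta.at[cand, "sex"])
                if sex not in ("M", "F"):
                    continue
                threshold = male_mat if sex == "M" else female_mat
                if sizes[cand] <= sizes[off] or sizes[cand] < threshold:
                    continue
                age_gap = ages[cand] - ages[off]
                if age_gap <= 0:
                    age_feasible = False
                else:
                    age_feasible = cache.size(age_gap) >= min_parent_size_at_spawning
                mm = _mismatches(genotypes[cand], genotypes[off], freqs.loci)
                lam = _lambda(genotypes[cand], genotypes[off], po, u, freqs)
                role = "father" if sex == "M" else "mother"
                candidates[role].append(ParentageAssignment(
                    off, cand, role, mm, age_feasible, accepted=False, log_lr=lam))
            for role, cands in candidates.items():
                eligible = [c for c in cands
                            if c.mismatch_count <= max_mismatch and c.age_feasible]
                if eligible:
                    eligible.sort(key=lambda c: (c.mismatch_count, -c.log_lr, c.parent))
                    best = eligible[0]
                    tie = [c for c in eligible[1:]
                           if c.mismatch_count == best.mismatch_count
                           and abs(c.log_lr - best.log_lr) < 1e-9]
                    if tie:
                        logger.warning(
                            "assign_parentage: %s has tied %s candidates %s; none accepted",
                            off, role, [best.parent] + [c.parent for c in tie])
                    else:
                        best.accepted = True
                results.extend(sorted(cands, key=lambda c: c.parent))
    return results


def parentage_frame(assignments: Sequence[ParentageAssignment]) -> pd.DataFrame:
    """Parentage records as the pipeline's CSV layout."""
    return pd.DataFrame(
        [{"offspring": a.offspring, "parent": a.parent, "sex_role": a.sex_role,
          "mismatches": a.mismatch_count, "age_feasible": a.age_feasible,
          "accepted": a.accepted} for a in assignments],
        columns=["offspring", "parent", "sex_role", "mismatches", "age_feasible", "accepted"],
    )


# ----------------------------------------------------------------------
# Dyad table
# ----------------------------------------------------------------------

def build_dyad_table(
    dataset: GenotypeDataset,
    freqs: AlleleFrequencyBlock,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    alpha: float = 0.05,
    n_null: int = 2000,
    seed: int = 0,
    qg_variant: str = "symmetric",
) -> pd.DataFrame:
    """Relatedness and per-hypothesis log-likelihoods for dyads.

    Defaults to all within-group pairs. Columns:
    ``id1,id2,r,loci_used,logl_po,logl_fs,logl_hs,logl_u,best,p_value`` where
    ``best`` is the highest-likelihood non-null hypothesis and ``p_value``
    its significance against U (shared null simulation per hypothesis).
    """
    genotypes = {ind: dataset.genotype_of(ind) for ind in dataset.individuals}
    if pairs is None:
        pairs = []
        for _, members in sorted(dataset.groups().items()):
            members = sorted(members)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs.append((members[i], members[j]))

    nulls = {
        label: null_lambda_sample(HYPOTHESES[label], HYPOTHESES["U"], freqs,
                                  n_null, seed + idx)
        for idx, label in enumerate(("PO", "FS", "HS"))
    }
    rows = []
    for id1, id2 in pairs:
        gx, gy = genotypes[id1], genotypes[id2]
        try:
            r = qg_relatedness(gx, gy, freqs, variant=qg_variant)
        except UninformativeDyadError:
            r = float("nan")
        loci_used = sum(1 for locus in freqs.loci
                        if gx.get(locus) is not None and gy.get(locus) is not None)
        logls = {}
        for label, k in HYPOTHESES.items():
            try:
                logls[label] = dyad_log_likelihood(gx, gy, k, freqs)
            except UninformativeDyadError:
                logls[label] = float("nan")
        best_label, best_p = "U", 1.0
        best_logl = logls["U"]
        for label in ("PO", "FS", "HS"):
            if logls[label] > best_logl:
                best_logl = logls[label]
                best_label = label
        if best_label != "U":
            res = classify_dyad(gx, gy, HYPOTHESES[best_label], HYPOTHESES["U"], freqs,
                                alpha=alpha, null_lambdas=nulls[best_label])
            best_p = res.p_value
        rows.append({
            "id1": id1, "id2": id2, "r": r, "loci_used": loci_used,
            "logl_po": logls["PO"], "logl_fs": logls["FS"],
            "logl_hs": logls["HS"], "logl_u": logls["U"],
            "best": best_label, "p_value": best_p,
        })
    return pd.DataFrame(rows, columns=["id1", "id2", "r", "loci_used", "logl_po",
                                       "logl_fs", "logl_hs", "logl_u", "best", "p_value"])
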