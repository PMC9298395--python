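"""Growth-based age estimation and group-history reconstruction.

Growth rate (mm/day) declines linearly with log body size,
``g(s) = alpha + beta * ln(s)`` with ``beta < 0``, so age at a given
standard length is the integral ``t(sl) = int_{s0}^{sl} ds / g(s)``.
All ages in this package are relative to the size-at-age-zero anchor ``s0``;
only age differences are ever used downstream.

On top of the age scale, this module reconstructs for each social group:

* immigrant classification (non-immigrant / possible immigrant / immigrant),
* breeder territory inheritance (matrilineal MLI / patrilineal PLI),
* breeder tenure intervals (midpoint of a minimum and maximum bound,
  censored when no upper bound exists).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "GrowthModel",
    "age_from_size",
    "size_at_age",
    "TenureEstimate",
    "IMMIGRANT_CLASSES",
    "classify_immigrant",
    "detect_inheritance",
    "estimate_tenure",
    "build_demography_report",
]

IMMIGRANT_CLASSES = ("non-immigrant", "possible immigrant", "immigrant")


@dataclass(frozen=True)
class GrowthModel:
    """Linear-in-log-size growth-rate model.

    alpha: rate intercept (mm/day); beta: rate slope per ln(mm), negative;
    s0: body size defining age zero (mm). The asymptotic size is
    ``s_inf = exp(-alpha/beta)``.
    """

    alpha: float = 0.38
    beta: float = -0.087
    s0: float = 6.5

    def __post_init__(self) -> None:
        if not (self.beta < 0 < self.alpha):
            raise ValueError("require beta < 0 < alpha")
        if not (0 < self.s0 < self.s_inf):
            raise ValueError(f"s0 must lie in (0, s_inf={self.s_inf:.2f})")

    @property
    def s_inf(self) -> float:
        return math.exp(-self.alpha / self.beta)

    def rate(self, sl: float) -> float:
        """Instantaneous growth rate (mm/day) at standard length ``sl``."""
        return self.alpha + self.beta * math.log(sl)


def age_from_size(sl: float, model: GrowthModel) -> float:
    """Age in days at standard length ``sl`` (adaptive quadrature).

    Strictly increasing in ``sl``; ``age_from_size(model.s0) == 0``.

    Raises
    ------
    ValueError
        If ``sl`` is outside ``[s0, s_inf)``.
    """
    if sl < model.s0 - 1e-12:
        raise ValueError(f"sl={sl} below size-at-age-zero s0={model.s0}")
    if sl >= model.s_inf:
        raise ValueError(
            f"sl={sl} at or above asymptotic size s_inf={model.s_inf:.4f}; age undefined")
    if sl <= model.s0:
        return 0.0
    val, _ = quad(lambda s: 1.0 / model.rate(s), model.s0, sl,
                  epsrel=1e-9, epsabs=0.0, limit=200)
    return val


def size_at_age(t: float, model: GrowthModel) -> float:
    """Standard length after ``t`` days of growth from ``s0`` (inverse map).

    Satisfies ``age_from_size(size_at_age(t)) == t`` to within 1e-6 days.
    """
    if t < 0:
        raise ValueError("age must be nonnegative")
    if t == 0:
        return model.s0
    hi = model.s_inf * (1.0 - 1e-12)
    if age_from_size(hi, model) <= t:
        return hi
    return brentq(lambda s: age_from_size(s, model) - t, model.s0, hi,
                  xtol=1e-10, rtol=8.9e-16)


class _SizeAgeCache:
    """Monotone spline shortcut for bulk size<->age queries (simulator use).

    Built on a dense grid of the exact quadrature; accurate to well below
    0.01 day over [s0, s_inf - 0.5]. The public API functions stay exact.
    """

    def __init__(self, model: GrowthModel, n: int = 4000):
        from scipy.interpolate import PchipInterpolator

        self.model = model
        hi = model.s_inf - 1e-3
        sizes = np.concatenate([
            np.linspace(model.s0, min(model.s0 + 2, hi), 200),
            np.linspace(min(model.s0 + 2, hi), hi, n),
        ])
        sizes = np.unique(sizes)
        ages = np.array([age_from_size(float(s), model) for s in sizes])
        self.max_age = float(ages[-1])
        self.max_size = float(sizes[-1])
        self._age = PchipInterpolator(sizes, ages)
        self._size = PchipInterpolator(ages, sizes)

    def age(self, sl: float) -> float:
        sl = min(max(sl, self.model.s0), self.max_size)
        return float(self._age(sl))

    def size(self, t: float) -> float:
        if t >= self.max_age:
            return self.max_size
        return float(self._size(max(t, 0.0)))


_CACHE_REGISTRY: dict[tuple[float, float, float], _SizeAgeCache] = {}


def get_size_age_cache(model: GrowthModel) -> _SizeAgeCache:
    key = (model.alpha, model.beta, model.s0)
    if key not in _CACHE_REGISTRY:
        _CACHE_REGISTRY[key] = _SizeAgeCache(model)
    return _CACHE_REGISTRY[key]


# ----------------------------------------------------------------------
# Reconstruction primitives
# ----------------------------------------------------------------------

@dataclass
class TenureEstimate:
    """Breeder tenure bracketed by produced and pre-existing group members.

    ``t_min`` is the age of the oldest group member the breeder produced
    (0 when none); ``t_max`` is the age of the next older non-immigrant
    member not produced by the breeder; ``tenure`` is their mean, or ``None``
    when censored (no qualifying older member exists).
    """

    breeder: str
    t_min: float
    t_max: Optional[float]
    censored: bool

    @property
    def tenure(self) -> Optional[float]:
        if self.censored:
            return None
        return 0.5 * (self.t_min + self.t_max)


def classify_immigrant(
    individual: str,
    group_members: Sequence[str],
    clusters: Mapping[str, Sequence[str]],
    parent_links: set[tuple[str, str]],
    ages: Mapping[str, float],
) -> str:
    """Classify one group member as non-/possible/assured immigrant.

    ``clusters`` maps cluster id -> member ids within the group;
    ``parent_links`` holds accepted (parent, offspring) pairs. An individual
    with evidence of *origin* inside the group — an accepted parent present,
    or co-membership in a kin cluster of size >= 2 with at least one partner
    that is not the individual's own accepted offspring (i.e. a sibling) —
    is a non-immigrant. Note the individual's own offspring do not count:
    producing young after arrival says nothing about philopatry. Otherwise
    its genotype is unique within the group: it is an assured immigrant only
    when flanked by an older and a younger kin cluster (size >= 2;
    singletons do not count), else a possible immigrant. A missing focal age
    yields "possible immigrant" with a warning.
    """
    members = set(group_members)
    own_offspring = {o for p, o in parent_links if p == individual}
    for parent, offspring in parent_links:
        if individual == offspring and parent in members:
            return "non-immigrant"
    for cluster in clusters.values():
        if individual in cluster and len(cluster) >= 2:
            partners = [m for m in cluster
                        if m != individual and m in members and m not in own_offspring]
            if partners:
                return "non-immigrant"
    focal_age = ages.get(individual)
    if focal_age is None or (isinstance(focal_age, float) and math.isnan(focal_age)):
        warnings.warn(f"{individual}: missing age; classified as possible immigrant")
        return "possible immigrant"
    older = younger = False
    for cluster in clusters.values():
        cluster_ages = [ages[m] for m in cluster
                        if m != individual and m in members and ages.get(m) is not None]
        if len(cluster_ages) < 2:
            continue
        if max(cluster_ages) > focal_age:
            older = True
        if min(cluster_ages) < focal_age:
            younger = True
    return "immigrant" if (older and younger) else "possible immigrant"


def detect_inheritance(
    breeder: str,
    sex: str,
    group_members: Sequence[str],
    clusters: Mapping[str, Sequence[str]],
    parent_links_by_role: Mapping[str, set[tuple[str, str]]],
    ages: Mapping[str, float],
    similar_age_window: float = 90.0,
) -> bool:
    """Detect matrilineal/patrilineal inheritance of a breeding position.

    True iff the group still contains the breeder's accepted other-sex
    parent, or a kin-cluster partner (full/half sib evidence) whose age is
    within ``similar_age_window`` days of the breeder's. A minimum estimate:
    sibling/parent mortality makes inheritance undetectable.
    """
    members = set(group_members)
    other_role = "father" if sex == "F" else "mother"
    for parent, offspring in parent_links_by_role.get(other_role, set()):
        if offspring == breeder and parent in members and parent != breeder:
            return True
    own_offspring = {o for links in parent_links_by_role.values()
                     for p, o in links if p == breeder}
    focal_age = ages.get(breeder)
    if focal_age is None:
        return False
    for cluster in clusters.values():
        if breeder not in cluster or len(cluster) < 2:
            continue
        for member in cluster:
            if member == breeder or member not in members or member in own_offspring:
                continue
            age = ages.get(member)
            if age is not None and abs(age - focal_age) <= similar_age_window:
                return True
    return False


def estimate_tenure(
    breeder: str,
    group_members: Sequence[str],
    own_offspring: Sequence[str],
    immigrant_class: Mapping[str, str],
    ages: Mapping[str, float],
) -> TenureEstimate:
    """Bracket a breeder's tenure by group demography.

    Minimum bound: age of the oldest group member produced by the breeder
    (zero when none). Maximum bound: age of the next older non-immigrant
    group member not produced by the breeder. Censored when no such older
    member exists.
    """
    in_group = set(group_members)
    produced = set(own_offspring) & in_group
    t_min = max((ages[o] for o in produced if ages.get(o) is not None), default=0.0)
    candidates = [
        ages[m]
        for m in in_group
        if m != breeder
        and m not in produced
        and immigrant_class.get(m) == "non-immigrant"
        and ages.get(m) is not None
        and ages[m] > t_min
    ]
    if not candidates:
        return TenureEstimate(breeder, t_min, None, censored=True)
    return TenureEstimate(breeder, t_min, min(candidates), censored=False)


# ----------------------------------------------------------------------
# Per-group driver
# ----------------------------------------------------------------------

def build_demography_report(
    dataset,
    freqs,
    growth: GrowthModel,
    partitions: Mapping[str, Mapping[str, Sequence[str]]],
    parentage: Sequence,
    similar_age_window: float = 90.0,
) -> pd.DataFrame:
    """Assemble the per-individual demography report.

    Parameters
    ----------
    partitions:
        Map group id -> (cluster id -> member ids), e.g. from
        :func:`socialkin.kinship.split_kin_groups` applied per group.
    parentage:
        Accepted/rejected :class:`socialkin.kinship.ParentageAssignment`
        records for the whole dataset.

    Returns a frame with one row per individual:
    ``id,group,subgroup,status,sex,sl_mm,age_days,immigrant_class,inherited,
    tenure_min,tenure_max,tenure_mean,censored``.
    """
    meta = dataset.meta
    ages: dict[str, Optional[float]] = {}
    for ind in dataset.individuals:
        sl = meta.at[ind, "sl_mm"]
        if sl is None or (isinstance(sl, float) and math.isnan(sl)):
            ages[ind] = None
        elif sl >= growth.s_inf:
            warnings.warn(f"{ind}: SL {sl} above asymptote; age capped")
            ages[ind] = age_from_size(growth.s_inf - 0.5, growth)
        else:
            ages[ind] = age_from_size(max(float(sl), growth.s0), growth)

    accepted = [a for a in parentage if a.accepted]
    links_all = {(a.parent, a.offspring) for a in accepted}
    links_by_role: dict[str, set[tuple[str, str]]] = {"mother": set(), "father": set()}
    for a in accepted:
        links_by_role[a.sex_role].add((a.parent, a.offspring))
    offspring_of: dict[str, list[str]] = {}
    for a in accepted:
        offspring_of.setdefault(a.parent, []).append(a.offspring)

    rows = []
    for group, members in sorted(dataset.groups().items()):
        clusters = partitions.get(group, {})
        group_links = {(p, o) for p, o in links_all if p in members and o in members}
        immigrant_class = {
            ind: classify_immigrant(ind, members, clusters, group_links, ages)
            for ind in members
        }
        for ind in sorted(members):
            status = str(meta.at[ind, "status"])
            sex = str(meta.at[ind, "sex"])
            inherited = False
            t_min = t_max = t_mean = None
            censored = None
            if status in ("breeder male", "breeder female"):
                inherited = detect_inheritance(
                    ind, "M" if status == "breeder male" else "F",
                    members, clusters, links_by_role, ages, similar_age_window)
                est = estimate_tenure(ind, members, offspring_of.get(ind, []),
                                      immigrant_class, ages)
                t_min, t_max = est.t_min, est.t_max
                t_mean, censored = est.tenure, est.censored
            rows.append({
                "id": ind,
                "group": group,
                "subgroup": str(meta.at[ind, "subgroup"]),
                "status": status,
                "sex": sex,
                "sl_mm": meta.at[ind, "sl_mm"],
                "age_days": ages[ind],
                "immigrant_class": immigrant_class[ind],
                "inherited": inherited,
                "tenure_min": t_min,
                "tenure_max": t_max,
                "tenure_mean": t_mean,
                "censored": censored,
            })
    return pd.DataFrame(rows)
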