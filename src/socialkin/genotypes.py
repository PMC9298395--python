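"""Genotype tables, allele frequencies, HWE filtering and pairwise relatedness.

The universal input of the pipeline is a :class:`GenotypeDataset`: diploid
co-dominant allele calls for a set of individuals at a set of loci, plus
per-individual social metadata (population, group, subgroup, status, sex,
standard length, behavioural counts).

Two on-disk dialects are supported:

* *pipeline CSV* — one row per individual, header
  ``id,population,group,subgroup,status,sex,sl_mm,<locus>_1,<locus>_2,...``
  with ``0`` as the missing-allele code and optional behaviour columns;
* *GenePop* (4-digit alleles, ``0000`` = missing) for import only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "MISSING",
    "STATUSES",
    "SEXES",
    "GenotypeDataset",
    "AlleleFrequencyBlock",
    "UninformativeDyadError",
    "load_dataset",
    "write_dataset",
    "estimate_allele_frequencies",
    "hwe_test",
    "hwe_filter",
    "qg_relatedness",
    "pairwise_relatedness_matrix",
]

MISSING = "0"
STATUSES = ("breeder male", "breeder female", "helper", "offspring", "independent")
SEXES = ("M", "F", "unknown")

#: metadata columns recognised in the pipeline CSV, in canonical order
META_COLUMNS = ("population", "group", "subgroup", "status", "sex", "sl_mm")
BEHAVIOR_COLUMNS = ("defence_con", "defence_het", "chamber_visits", "maintenance", "protocol")

Call = Optional[tuple[str, str]]


class UninformativeDyadError(ValueError):
    """All shared loci of a dyad are uninformative (zero denominator sum)."""


@dataclass
class GenotypeDataset:
    """Individuals x loci diploid allele calls plus social metadata.

    Parameters
    ----------
    loci:
        Locus identifiers, in column order.
    calls:
        DataFrame indexed by individual id with two string columns per locus,
        ``<locus>_1`` and ``<locus>_2``; the missing code is ``"0"`` and a
        missing call sets both columns to ``"0"``.
    meta:
        DataFrame indexed by individual id. Only ``id`` is mandatory; the
        canonical columns of :data:`META_COLUMNS` are created (empty) when
        absent so downstream code can rely on them.
    """

    loci: list[str]
    calls: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.loci = list(self.loci)
        if self.calls.index.has_duplicates:
            dups = self.calls.index[self.calls.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate individual ids: {dups}")
        for locus in self.loci:
            for suffix in ("_1", "_2"):
                col = locus + suffix
                if col not in self.calls.columns:
                    raise ValueError(f"calls table lacks column {col!r}")
        self.calls = self.calls.astype(str)
        # half-missing calls are not representable: demote them to missing
        for locus in self.loci:
            a, b = self.calls[locus + "_1"], self.calls[locus + "_2"]
            half = (a == MISSING) ^ (b == MISSING)
            if half.any():
                self.calls.loc[half, [locus + "_1", locus + "_2"]] = MISSING
        self.meta = self.meta.reindex(self.calls.index)
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                self.meta[col] = "" if col != "sl_mm" else np.nan
        bad_status = set(self.meta["status"].dropna()) - set(STATUSES) - {""}
        if bad_status:
            raise ValueError(f"unknown status label(s): {sorted(bad_status)}")
        sl = pd.to_numeric(self.meta["sl_mm"], errors="coerce")
        if (sl <= 0).any():
            raise ValueError("sl_mm must be positive where present")
        self.meta["sl_mm"] = sl
        # every subgroup id must live inside exactly one group
        sub = self.meta[["group", "subgroup"]].astype(str)
        sub = sub[(sub["subgroup"] != "") & (sub["subgroup"] != "nan")]
        n_groups = sub.groupby("subgroup")["group"].nunique()
        if (n_groups > 1).any():
            bad = n_groups[n_groups > 1].index.tolist()
            raise ValueError(f"subgroup id(s) mapped to multiple groups: {bad}")

    # ------------------------------------------------------------------
    @property
    def individuals(self) -> list[str]:
        return list(self.calls.index)

    def __len__(self) -> int:
        return len(self.calls)

    def get_call(self, individual: str, locus: str) -> Call:
        a = self.calls.at[individual, locus + "_1"]
        b = self.calls.at[individual, locus + "_2"]
        if a == MISSING or b == MISSING:
            return None
        return (a, b)

    def genotype_of(self, individual: str) -> dict[str, Call]:
        """All calls of one individual as a mapping locus -> pair or None."""
        return {locus: self.get_call(individual, locus) for locus in self.loci}

    def subset(self, individuals: Sequence[str] | None = None,
               loci: Sequence[str] | None = None) -> "GenotypeDataset":
        ids = list(individuals) if individuals is not None else self.individuals
        keep_loci = list(loci) if loci is not None else list(self.loci)
        cols = [locus + s for locus in keep_loci for s in ("_1", "_2")]
        return GenotypeDataset(keep_loci, self.calls.loc[ids, cols].copy(),
                               self.meta.loc[ids].copy())

    def alleles_at(self, locus: str) -> list[str]:
        a = self.calls[locus + "_1"]
        b = self.calls[locus + "_2"]
        vals = set(a[a != MISSING]) | set(b[b != MISSING])
        return sorted(vals)

    def groups(self) -> dict[str, list[str]]:
        """Map group id -> member ids (rows with a non-empty group label)."""
        g = self.meta["group"].astype(str)
        out: dict[str, list[str]] = {}
        for ind, grp in g.items():
            if grp and grp != "nan":
                out.setdefault(grp, []).append(ind)
        return out

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(list(self.loci), self.calls.copy(), self.meta.copy())

    def equals(self, other: "GenotypeDataset") -> bool:
        return (self.loci == other.loci
                and self.calls.equals(other.calls)
                and self.meta.fillna("").astype(str).equals(other.meta.fillna("").astype(str)))


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def load_dataset(path, format: str = "pipeline-csv") -> GenotypeDataset:
    """Read a genotype table.

    ``format`` is one of ``"pipeline-csv"`` or ``"genepop"``. Round-tripping
    through :func:`write_dataset` is the identity for the pipeline dialect.
    """
    if format == "pipeline-csv":
        return _load_pipeline_csv(path)
    if format == "genepop":
        return _load_genepop(path)
    raise ValueError(f"unknown format {format!r}")


def _load_pipeline_csv(path) -> GenotypeDataset:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise ValueError("pipeline CSV requires an 'id' column")
    df = df.set_index("id")
    allele_cols = [c for c in df.columns if c.endswith("_1") or c.endswith("_2")]
    loci: list[str] = []
    for c in allele_cols:
        locus = c[:-2]
        if locus not in loci:
            loci.append(locus)
    for locus in loci:
        if (locus + "_1" not in df.columns) or (locus + "_2" not in df.columns):
            raise ValueError(f"locus {locus!r}: allele column count is not even")
    calls = df[[l + s for l in loci for s in ("_1", "_2")]].copy()
    meta_cols = [c for c in df.columns if c not in calls.columns]
    meta = df[meta_cols].copy()
    if "sl_mm" in meta.columns:
        meta["sl_mm"] = pd.to_numeric(meta["sl_mm"].replace("", np.nan))
    for col in BEHAVIOR_COLUMNS[:-1]:
        if col in meta.columns:
            meta[col] = pd.to_numeric(meta[col].replace("", np.nan))
    return GenotypeDataset(loci, calls, meta)


def write_dataset(dataset: GenotypeDataset, path) -> None:
    """Write in the pipeline CSV dialect (inverse of :func:`load_dataset`)."""
    meta = dataset.meta.copy()
    lead = [c for c in META_COLUMNS if c in meta.columns]
    trail = [c for c in meta.columns if c not in lead]
    out = pd.concat([meta[lead + trail], dataset.calls], axis=1)
    out.index.name = "id"
    with _open_write(path) as fh:
        out.to_csv(fh, lineterminator="\n")


def _open_write(path):
    if hasattr(path, "write"):
        return _NullCtx(path)
    return open(path, "w", newline="")


class _NullCtx:
    def __init__(self, fh):
        self.fh = fh

    def __enter__(self):
        return self.fh

    def __exit__(self, *exc):
        return False


def _load_genepop(path) -> GenotypeDataset:
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    if not lines:
        raise ValueError("empty GenePop file")
    body = lines[1:]  # first line is a title
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        # locus names: one per line, or several comma-separated
        loci.extend(tok.strip() for tok in body[i].split(",") if tok.strip())
        i += 1
    if i == len(body):
        raise ValueError("GenePop file has no 'Pop' separator")
    records: list[tuple[str, str, list[str]]] = []
    pop_idx = 0
    for line in body[i:]:
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in stripped:
            raise ValueError(f"malformed GenePop sample line: {line!r}")
        name, geno = stripped.split(",", 1)
        fields = geno.split()
        if len(fields) != len(loci):
            raise ValueError(
                f"individual {name.strip()!r}: {len(fields)} genotype fields for {len(loci)} loci")
        records.append((name.strip(), f"pop{pop_idx}", fields))
    ids = [r[0] for r in records]
    calls = pd.DataFrame(index=pd.Index(ids, name="id"))
    for j, locus in enumerate(loci):
        a_col, b_col = [], []
        for _, _, fields in records:
            token = fields[j]
            if len(token) not in (4, 6) or not token.isdigit():
                raise ValueError(f"bad GenePop genotype token {token!r} at locus {locus}")
            half = len(token) // 2
            a, b = token[:half], token[half:]
            if int(a) == 0 or int(b) == 0:
                a = b = MISSING
            else:
                a, b = str(int(a)), str(int(b))
            a_col.append(a)
            b_col.append(b)
        calls[locus + "_1"] = a_col
        calls[locus + "_2"] = b_col
    meta = pd.DataFrame(index=calls.index)
    meta["population"] = [r[1] for r in records]
    return GenotypeDataset(loci, calls, meta)


# ----------------------------------------------------------------------
# Allele frequencies
# ----------------------------------------------------------------------

@dataclass
class AlleleFrequencyBlock:
    """Per-locus allele frequency vectors.

    ``freqs[locus][allele]`` is the population frequency of ``allele``.
    ``provenance`` records how the block was obtained: ``"naive"`` counting,
    relatedness-``"corrected"`` reweighting, or an ``"external"`` file.
    """

    freqs: dict[str, dict[str, float]]
    provenance: str = "naive"

    def __post_init__(self) -> None:
        for locus, table in self.freqs.items():
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"locus {locus}: frequencies sum to {total}, not 1")
            if any(p <= 0 for p in table.values()):
                raise ValueError(f"locus {locus}: non-positive frequency")

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)

    def alleles(self, locus: str) -> list[str]:
        return list(self.freqs[locus])

    def p(self, locus: str, allele: str) -> float:
        return self.freqs[locus][allele]

    def to_frame(self) -> pd.DataFrame:
        rows = [(locus, allele, p)
                for locus, table in self.freqs.items()
                for allele, p in table.items()]
        return pd.DataFrame(rows, columns=["locus", "allele", "freq"])

    def write_csv(self, path) -> None:
        with _open_write(path) as fh:
            self.to_frame().to_csv(fh, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "AlleleFrequencyBlock":
        df = pd.read_csv(path, dtype={"locus": str, "allele": str, "freq": float})
        freqs: dict[str, dict[str, float]] = {}
        for _, row in df.iterrows():
            freqs.setdefault(row["locus"], {})[row["allele"]] = float(row["freq"])
        return cls(freqs, provenance="external")


def _floor_frequencies(table: dict[str, float], floor: float) -> dict[str, float]:
    """Raise every frequency to at least ``floor``, preserving the total.

    The mass added to rare alleles is taken from the others proportionally
    to their spare capacity, with each donation capped at ``floor`` — so no
    reported frequency moves by more than the floor value. If the donors
    cannot absorb the deficit (degenerate: nearly all alleles rare) the
    distribution is renormalised instead, with a warning.
    """
    raised = {a: max(p, floor) for a, p in table.items()}
    deficit = sum(raised.values()) - sum(table.values())
    if deficit <= 0:
        return dict(table)
    capacity = {a: min(floor, p - floor) for a, p in table.items() if p > floor}
    total_capacity = sum(capacity.values())
    if deficit <= total_capacity:
        scale = deficit / total_capacity
        out = dict(raised)
        for a, cap in capacity.items():
            out[a] = raised[a] - cap * scale
        return out
    warnings.warn("frequency floor deficit exceeds donor capacity; renormalising")
    total = sum(raised.values())
    return {a: p / total for a, p in raised.items()}


def estimate_allele_frequencies(
    dataset: GenotypeDataset,
    method: str = "naive",
    population: str | None = None,
    floor: float | None = None,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> AlleleFrequencyBlock:
    """Estimate per-locus allele frequencies from a genotype table.

    ``method="naive"`` counts alleles; ``method="corrected"`` iteratively
    down-weights each individual by ``1 / (1 + mean pairwise r to others)``
    so over-represented families do not dominate the background frequencies,
    re-estimating until the largest frequency change falls below ``tol``.

    Frequencies are floored at ``floor`` (default ``1/(2N+1)`` for N sampled
    individuals) and renormalised, which keeps every likelihood finite.

    Raises
    ------
    ValueError
        If a locus has zero non-missing calls in the selected population
        (reported explicitly, never silently dropped).
    """
    if method not in ("naive", "corrected"):
        raise ValueError(f"unknown method {method!r}")
    ds = dataset
    if population is not None:
        ids = [i for i in ds.individuals if str(ds.meta.at[i, "population"]) == population]
        if not ids:
            raise ValueError(f"no individuals in population {population!r}")
        ds = ds.subset(ids)
    n = len(ds)
    if floor is None:
        floor = 1.0 / (2 * n + 1)

    empty = [locus for locus in ds.loci
             if (ds.calls[locus + "_1"] == MISSING).all()]
    if empty:
        raise ValueError(f"locus/loci with zero non-missing calls: {empty}")

    weights = np.ones(n)
    block = _weighted_frequencies(ds, weights, floor)
    if method == "naive":
        return block

    for _ in range(max_iter):
        r_matrix, _ = pairwise_relatedness_matrix(ds, block)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean_r = np.nanmean(np.where(np.eye(n, dtype=bool), np.nan, r_matrix), axis=1)
        mean_r = np.nan_to_num(mean_r, nan=0.0)
        weights = 1.0 / (1.0 + np.clip(mean_r, -0.5, None))
        new_block = _weighted_frequencies(ds, weights, floor)
        delta = max(
            abs(new_block.freqs[l].get(a, 0.0) - block.freqs[l].get(a, 0.0))
            for l in block.loci for a in block.freqs[l]
        )
        block = new_block
        if delta < tol:
            break
    return AlleleFrequencyBlock(block.freqs, provenance="corrected")


def _weighted_frequencies(ds: GenotypeDataset, weights: np.ndarray,
                          floor: float) -> AlleleFrequencyBlock:
    freqs: dict[str, dict[str, float]] = {}
    for locus in ds.loci:
        a = ds.calls[locus + "_1"].to_numpy()
        b = ds.calls[locus + "_2"].to_numpy()
        typed = a != MISSING
        counts: dict[str, float] = {}
        for col in (a, b):
            for allele, w in zip(col[typed], weights[typed]):
                counts[allele] = counts.get(allele, 0.0) + w
        total = sum(counts.values())
        table = {allele: c / total for allele, c in sorted(counts.items())}
        freqs[locus] = _floor_frequencies(table, floor)
    return AlleleFrequencyBlock(freqs, provenance="naive")


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte-Carlo)
# ----------------------------------------------------------------------

def _genotype_table_logprob(codes: np.ndarray, het: np.ndarray,
                            allele_counts: np.ndarray, n: int) -> float:
    """Log-probability of a genotype table conditional on its allele counts."""
    genotype_counts = np.bincount(codes)
    return float(
        gammaln(n + 1)
        - gammaln(genotype_counts + 1).sum()
        + het.sum() * np.log(2.0)
        + gammaln(allele_counts + 1).sum()
        - gammaln(2 * n + 1)
    )


def hwe_test(dataset: GenotypeDataset, locus: str, n_mc: int = 10000,
             seed: int = 0, population: str | None = None) -> float:
    """Monte-Carlo exact Hardy-Weinberg test for one locus.

    Alleles are shuffled ``n_mc`` times conditional on the observed allele
    counts; the p-value is ``(1 + #{tables at most as probable as observed})
    / (1 + n_mc)``. Deterministic under ``seed``. A monomorphic locus returns
    p = 1 with a warning.
    """
    ds = dataset
    if population is not None:
        ids = [i for i in ds.individuals if str(ds.meta.at[i, "population"]) == population]
        ds = ds.subset(ids)
    a = ds.calls[locus + "_1"].to_numpy()
    b = ds.calls[locus + "_2"].to_numpy()
    typed = a != MISSING
    a, b = a[typed], b[typed]
    n = len(a)
    if n < 5:
        raise ValueError(f"locus {locus}: fewer than 5 typed individuals")
    labels = sorted(set(a) | set(b))
    if len(labels) < 2:
        warnings.warn(f"locus {locus} is monomorphic; HWE p-value set to 1")
        return 1.0
    idx = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    ai = np.array([idx[x] for x in a])
    bi = np.array([idx[x] for x in b])
    lo, hi = np.minimum(ai, bi), np.maximum(ai, bi)
    codes = lo * k + hi
    alleles = np.concatenate([ai, bi])
    allele_counts = np.bincount(alleles, minlength=k)
    obs_logp = _genotype_table_logprob(codes, lo != hi, allele_counts, n)

    rng = np.random.default_rng(seed)
    count = 0
    chunk = 2000
    done = 0
    while done < n_mc:
        m = min(chunk, n_mc - done)
        keys = rng.random((m, 2 * n))
        order = np.argsort(keys, axis=1)
        perm = alleles[order]
        pa, pb = perm[:, ::2], perm[:, 1::2]
        plo, phi = np.minimum(pa, pb), np.maximum(pa, pb)
        pcodes = plo * k + phi
        phet = (plo != phi).sum(axis=1)
        gl = gammaln(np.arange(n + 2) + 1.0)  # gl[c] = log(c!)
        base = float(gammaln(n + 1) + gammaln(allele_counts + 1).sum() - gammaln(2 * n + 1))
        for row in range(m):
            gcounts = np.bincount(pcodes[row], minlength=k * k)
            logp = base - gl[gcounts].sum() + phet[row] * np.log(2.0)
            if logp <= obs_logp + 1e-9:
                count += 1
        done += m
    return (1 + count) / (1 + n_mc)


def hwe_filter(dataset: GenotypeDataset, alpha: float = 0.05, n_mc: int = 10000,
               seed: int = 0, population: str | None = None,
               exclude: Iterable[str] = ()) -> tuple[list[str], dict[str, float]]:
    """Locus exclusion policy: drop HWE-deviating and explicitly flagged loci.

    Returns the list of retained loci and the per-locus p-values (flagged
    loci get ``nan``). Monomorphic and thin loci are retained with p = 1.
    """
    flagged = set(exclude)
    keep: list[str] = []
    pvals: dict[str, float] = {}
    for i, locus in enumerate(dataset.loci):
        if locus in flagged:
            pvals[locus] = float("nan")
            continue
        try:
            p = hwe_test(dataset, locus, n_mc=n_mc, seed=seed + i, population=population)
        except ValueError:
            p = 1.0
        pvals[locus] = p
        if p >= alpha:
            keep.append(locus)
    return keep, pvals


# ----------------------------------------------------------------------
# Queller-Goodnight relatedness
# ----------------------------------------------------------------------

def qg_relatedness(gx: Mapping[str, Call], gy: Mapping[str, Call],
                   freqs: AlleleFrequencyBlock, variant: str = "symmetric") -> float:
    """Queller-Goodnight pairwise relatedness of two multilocus genotypes.

    For locus ``l`` with ``gx = (a, b)`` and ``gy = (c, d)``::

        num_l(x|y) = 0.5 (d_ac + d_ad + d_bc + d_bd) - p_a - p_b
        den_l(x)   = 1 + d_ab - p_a - p_b

    The default ``"symmetric"`` variant is the ratio of sums over both
    reference directions,
    ``r = (sum num(x|y) + sum num(y|x)) / (sum den(x) + sum den(y))``;
    ``"directional-mean"`` averages the two directional ratios instead.
    Loci missing in either member are skipped.

    Raises
    ------
    UninformativeDyadError
        If the denominator sum vanishes (no informative shared locus).
    """
    if variant not in ("symmetric", "directional-mean"):
        raise ValueError(f"unknown QG variant {variant!r}")
    num_xy = num_yx = den_x = den_y = 0.0
    used = 0
    for locus in freqs.loci:
        cx = gx.get(locus)
        cy = gy.get(locus)
        if cx is None or cy is None:
            continue
        nxy, dx = _qg_terms(cx, cy, freqs.freqs[locus])
        nyx, dy = _qg_terms(cy, cx, freqs.freqs[locus])
        num_xy += nxy
        num_yx += nyx
        den_x += dx
        den_y += dy
        used += 1
    if used == 0:
        raise UninformativeDyadError("no locus typed in both individuals")
    if variant == "symmetric":
        den = den_x + den_y
        if abs(den) < 1e-12:
            raise UninformativeDyadError("all shared loci uninformative")
        return (num_xy + num_yx) / den
    if abs(den_x) < 1e-12 or abs(den_y) < 1e-12:
        raise UninformativeDyadError("all shared loci uninformative")
    return 0.5 * (num_xy / den_x + num_yx / den_y)


def _qg_terms(cx: tuple[str, str], cy: tuple[str, str],
              p: Mapping[str, float]) -> tuple[float, float]:
    a, b = cx
    c, d = cy
    sim = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
    num = sim - p[a] - p[b]
    den = 1.0 + (a == b) - p[a] - p[b]
    return num, den


def pairwise_relatedness_matrix(
    dataset: GenotypeDataset, freqs: AlleleFrequencyBlock,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised symmetric QG relatedness for all pairs of a dataset.

    Returns ``(r, loci_used)`` square arrays ordered like
    ``dataset.individuals``; entries with no informative shared locus are
    ``nan``. The diagonal is not meaningful.
    """
    n = len(dataset)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    used = np.zeros((n, n), dtype=int)
    for locus in freqs.loci:
        if locus + "_1" not in dataset.calls.columns:
            continue
        a = dataset.calls[locus + "_1"].to_numpy()
        b = dataset.calls[locus + "_2"].to_numpy()
        typed = a != MISSING
        table = freqs.freqs[locus]
        pa = np.array([table.get(x, 0.0) for x in a])
        pb = np.array([table.get(x, 0.0) for x in b])
        sim = 0.5 * (
            (a[:, None] == a[None, :]).astype(float)
            + (a[:, None] == b[None, :])
            + (b[:, None] == a[None, :])
            + (b[:, None] == b[None, :])
        )
        den_i = 1.0 + (a == b) - pa - pb
        pair_ok = typed[:, None] & typed[None, :]
        num += np.where(pair_ok, 2.0 * sim - (pa + pb)[:, None] - (pa + pb)[None, :], 0.0)
        den += np.where(pair_ok, den_i[:, None] + den_i[None, :], 0.0)
        used += pair_ok
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(np.abs(den) > 1e-12, num / den, np.nan)
    return r, used
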