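"""End-to-end pipeline: input/simulate -> frequencies -> relatedness ->
kinship -> demography -> statistics, with a reproducible report bundle.

Every stage is a pure function of (inputs, config, seed); the manifest
written alongside the artifacts suffices to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .demography import GrowthModel, build_demography_report
from .genotypes import (
    AlleleFrequencyBlock,
    GenotypeDataset,
    estimate_allele_frequencies,
    hwe_filter,
    load_dataset,
    pairwise_relatedness_matrix,
    write_dataset,
)
from .kinship import (
    assign_parentage,
    build_dyad_table,
    null_lambda_sample,
    parentage_frame,
    split_kin_groups,
    HYPOTHESES,
)
from .social_stats import (
    bootstrap_category_comparison,
    comparison_frame,
    summarize_structure,
)
from .synthetic_data import SimulationConfig, simulate_population, write_truth_tables

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One reproducible run: exactly one input mode plus all thresholds."""

    input_path: Optional[str] = None
    input_format: str = "pipeline-csv"
    simulation: Optional[SimulationConfig] = None
    freqs_path: Optional[str] = None
    exclude_loci: tuple[str, ...] = ()
    hwe_alpha: float = 0.05
    hwe_n_mc: int = 2000
    frequency_method: str = "corrected"
    qg_variant: str = "symmetric"
    alpha: float = 0.05
    n_null: int = 2000
    n_reps: int = 100
    growth_params: tuple[float, float, float] = (0.38, -0.087, 6.5)
    max_mismatch: int = 1
    min_parent_size_at_spawning: float = 31.0
    maturity_sizes: tuple[float, float] = (32.5, 31.5)
    similar_age_window: float = 90.0
    merge_threshold: float = 5.0
    max_nongroup_dyads: int = 2000
    seed: int = 0
    outdir: str = "socialkin_out"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one input mode: input_path or simulation")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = open(path, "rb").read()
        if str(path).endswith(".toml"):
            import tomllib

            raw = tomllib.loads(text.decode())
        else:
            import yaml

            raw = yaml.safe_load(text)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None:
            for key in ("subgroups_per_group", "helpers_per_subgroup",
                        "alleles_per_locus", "growth_params", "maturity_sizes"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        for key in ("growth_params", "maturity_sizes", "exclude_loci"):
            if key in raw:
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(simulation=sim, **raw)

    def to_canonical_json(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # bundle location is not part of its content
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        return json.dumps(d, sort_keys=True, default=list)


def _write_csv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    with open(path, "w", newline="") as fh:
        df.to_csv(fh, index=index, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute all stages and write the report bundle under ``config.outdir``.

    Returns a map artifact-name -> file path. Identical config (incl. seed)
    produces byte-identical bundles.
    """
    os.makedirs(config.outdir, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(config.outdir, name)
        _write_csv(df, path)
        artifacts[name] = path

    # --- stage: input -------------------------------------------------
    try:
        if config.simulation is not None:
            dataset, truth = simulate_population(config.simulation)
            write_dataset(dataset, os.path.join(config.outdir, "dataset.csv"))
            artifacts["dataset.csv"] = os.path.join(config.outdir, "dataset.csv")
            write_truth_tables(truth, config.outdir)
            for name in ("pedigree.csv", "immigrants.csv", "tenure.csv"):
                artifacts[name] = os.path.join(config.outdir, name)
        else:
            dataset = load_dataset(config.input_path, format=config.input_format)
    except Exception as exc:
        raise RuntimeError(f"stage 'input' failed: {exc}") from exc
    logger.info("input: %d individuals, %d loci", len(dataset), len(dataset.loci))

    # --- stage: frequencies -------------------------------------------
    try:
        keep, hwe_p = hwe_filter(dataset, alpha=config.hwe_alpha,
                                 n_mc=config.hwe_n_mc, seed=config.seed,
                                 exclude=config.exclude_loci)
        dataset = dataset.subset(loci=keep)
        if config.freqs_path is not None:
            freqs = AlleleFrequencyBlock.from_csv(config.freqs_path)
        else:
            freqs = estimate_allele_frequencies(dataset, method=config.frequency_method)
        freqs.write_csv(os.path.join(config.outdir, "frequencies.csv"))
        artifacts["frequencies.csv"] = os.path.join(config.outdir, "frequencies.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'frequencies' failed: {exc}") from exc
    logger.info("frequencies: %d loci retained (%s)", len(keep), freqs.provenance)

    growth = GrowthModel(*config.growth_params)

    # --- stage: relatedness / dyads -----------------------------------
    try:
        dyads = build_dyad_table(dataset, freqs, alpha=config.alpha,
                                 n_null=config.n_null, seed=config.seed,
                                 qg_variant=config.qg_variant)
        emit("dyads.csv", dyads)
    except Exception as exc:
        raise RuntimeError(f"stage 'relatedness' failed: {exc}") from exc

    # --- stage: kinship -----------------------------------------------
    try:
        null_fs = null_lambda_sample(HYPOTHESES["FS"], HYPOTHESES["U"], freqs,
                                     config.n_null, config.seed + 101)
        genotypes = {i: dataset.genotype_of(i) for i in dataset.individuals}
        partitions = {}
        part_rows = []
        for group, members in sorted(dataset.groups().items()):
            part = split_kin_groups(members, genotypes, freqs,
                                    merge_threshold=config.merge_threshold,
                                    alpha=config.alpha, null_lambdas=null_fs)
            partitions[group] = part.clusters
            for ind, cid in sorted(part.assignment.items()):
                part_rows.append({"group": group, "id": ind, "cluster": cid})
        emit("partition.csv", pd.DataFrame(part_rows, columns=["group", "id", "cluster"]))
        parentage = assign_parentage(
            dataset, freqs, growth, max_mismatch=config.max_mismatch,
            min_parent_size_at_spawning=config.min_parent_size_at_spawning,
            maturity_sizes=config.maturity_sizes)
        emit("parentage.csv", parentage_frame(parentage))
    except Exception as exc:
        raise RuntimeError(f"stage 'kinship' failed: {exc}") from exc

    # --- stage: demography --------------------------------------------
    try:
        demography = build_demography_report(
            dataset, freqs, growth, partitions, parentage,
            similar_age_window=config.similar_age_window)
        emit("demography.csv", demography)
    except Exception as exc:
        raise RuntimeError(f"stage 'demography' failed: {exc}") from exc

    # --- stage: statistics --------------------------------------------
    try:
        immigration, skew = summarize_structure(demography, parentage_frame(parentage),
                                                dataset)
        emit("immigration.csv", immigration)
        emit("skew.csv", skew)
        comparisons = _category_comparisons(dataset, freqs, config)
        emit("comparisons.csv", comparisons)
    except Exception as exc:
        raise RuntimeError(f"stage 'statistics' failed: {exc}") from exc

    manifest = {
        "config": json.loads(config.to_canonical_json()),
        "config_sha256": hashlib.sha256(config.to_canonical_json().encode()).hexdigest(),
        "seed": config.seed,
        "socialkin_version": __version__,
        "hwe_p_values": {k: (None if v != v else v) for k, v in sorted(hwe_p.items())},
        "artifacts": sorted(artifacts),
    }
    path = os.path.join(config.outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["manifest.json"] = path
    return artifacts


def _category_comparisons(dataset: GenotypeDataset, freqs: AlleleFrequencyBlock,
                          config: PipelineConfig) -> pd.DataFrame:
    """Per-status relatedness comparison across membership categories.

    Categories per dyad: same subgroup, same group but different subgroup,
    or non-group members. Non-group dyads are subsampled (seeded) to
    ``max_nongroup_dyads`` per status to bound the table.
    """
    r, _ = pairwise_relatedness_matrix(dataset, freqs)
    ids = dataset.individuals
    meta = dataset.meta
    status = meta["status"].astype(str).to_numpy()
    group = meta["group"].astype(str).to_numpy()
    subgroup = meta["subgroup"].astype(str).to_numpy()
    frames = []
    statuses = ("breeder male", "breeder female", "helper", "independent")
    rng = np.random.default_rng(config.seed + 777)
    for st in statuses:
        rows = []
        focal_idx = [i for i in range(len(ids)) if status[i] == st]
        nongroup: list[tuple[int, int]] = []
        for i in focal_idx:
            for j in range(len(ids)):
                if j <= i and status[j] == st:
                    continue  # count each same-status dyad once
                if j == i or np.isnan(r[i, j]):
                    continue
                if group[i] == group[j]:
                    cat = ("subgroup" if subgroup[i] == subgroup[j] and subgroup[i]
                           else "group_other_subgroup")
                    rows.append({"value": r[i, j], "category": cat})
                else:
                    nongroup.append((i, j))
        if nongroup:
            take = min(len(nongroup), config.max_nongroup_dyads)
            sel = rng.choice(len(nongroup), size=take, replace=False)
            for idx in sorted(sel):
                i, j = nongroup[idx]
                rows.append({"value": r[i, j], "category": "non_group"})
        table = pd.DataFrame(rows)
        if table.empty:
            continue
        counts = table["category"].value_counts()
        usable = counts[counts >= 2].index
        table = table[table["category"].isin(usable)]
        if table["category"].nunique() < 2:
            continue
        results = bootstrap_category_comparison(
            table, n_reps=config.n_reps, alpha=config.alpha,
            seed=config.seed + statuses.index(st))
        frames.append(comparison_frame(results, status=st))
    if not frames:
        return pd.DataFrame(columns=["status", "cat_i", "cat_j", "mean_diff",
                                     "avg_p", "avg_lo", "avg_hi", "significant"])
    return pd.concat(frames, ignore_index=True)
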