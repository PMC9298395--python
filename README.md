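# socialkin

Kinship and social-structure reconstruction for multi-layered cooperatively
breeding groups, from co-dominant (microsatellite-style) genotype tables.

The pipeline covers:

* **genotypes** — pipeline-CSV and GenePop input, naive and
  relatedness-corrected allele frequencies with a rare-allele floor,
  Monte-Carlo exact Hardy–Weinberg locus filtering, and Queller–Goodnight
  pairwise relatedness (symmetric ratio-of-sums; a directional-mean variant
  is available via `--qg-variant`).
* **kinship** — k-coefficient dyad likelihoods (U/HS/FS/PO), likelihood-ratio
  classification with simulated null significance, greedy likelihood-ratio
  agglomeration of social groups into kin clusters, and pairwise Mendelian
  parentage under growth-derived age/maturity constraints.
* **demography** — age-from-size transforms by integrating a linear
  rate-vs-ln(size) growth model, plus the threefold reconstruction:
  immigrant classification (non-immigrant / possible / assured), breeder
  territory-inheritance detection (MLI/PLI), and tenure bracketing with
  censoring.
* **social_stats** — workload composite, 2×2 Pearson chi-square and
  one-sample t, Dunnett's C pairwise intervals, the 100-repetition bootstrap
  ANOVA with averaged p-values/CI bounds, Kaplan–Meier/Gehan tenure
  comparison (via `lifelines`), and immigration/reproductive-skew summary
  tables.
* **synthetic_data** — a forward simulator of polygynous groups (breeder
  male, 1–4 female subgroups, helpers) with Mendelian genotypes, breeder
  turnover, inheritance vs takeover, immigrant recruitment, genotyping-error
  injection and full truth tables (pedigree, immigrant classes, tenures),
  so every downstream stage is testable without field data.
* **pipeline / cli** — one reproducible run with a config hash manifest;
  identical config + seed gives byte-identical artifact bundles.

## CLI

```bash
# simulate a population with truth tables
socialkin simulate -c examples/sim.yaml -o out/

# full pipeline from a config file (simulation or file input mode)
socialkin run -c config.yaml

# single stages on a genotype CSV
socialkin relatedness -i data.csv -o out/
socialkin kinship     -i data.csv -o out/
socialkin demography  -i data.csv -o out/
socialkin stats       -i data.csv -o out/

# worked-example statistics straight from count tables
socialkin stats-only --chi2 109,231,18,137 --t 0.135,0.125,81,0
```

A config file (YAML or TOML) holds either an `input_path` or a
`simulation:` section plus thresholds (`alpha`, `n_null`, `n_reps`,
`max_mismatch`, `min_parent_size_at_spawning`, `maturity_sizes`,
`similar_age_window`, `merge_threshold`, `growth_params`, `seed`, …).
Example:

```yaml
simulation:
  n_groups: 30
  n_loci: 13
  seed: 7
n_reps: 100
alpha: 0.05
outdir: out
```

The bundle contains `dataset.csv`, truth tables (simulation mode),
`frequencies.csv`, `dyads.csv`, `partition.csv`, `parentage.csv`,
`demography.csv`, `immigration.csv`, `skew.csv`, `comparisons.csv` and a
`manifest.json` with the config hash and seed.

## Genotype table dialect

```
id,population,group,subgroup,status,sex,sl_mm,<locus>_1,<locus>_2,...
```

`0` is the missing-allele code; statuses are `breeder male`,
`breeder female`, `helper`, `offspring`, `independent`; optional behaviour
columns `defence_con,defence_het,chamber_visits,maintenance,protocol`.
GenePop files (4- or 6-digit genotypes, `0000` missing) can be imported
with `--format genepop`. Allele-frequency blocks are CSV
(`locus,allele,freq`).

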