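# Simulation-mode pipeline config: 30 polygynous groups, 13 loci.
simulation:
  n_groups: 30
  subgroups_per_group: [1, 4]
  helpers_per_subgroup: [2, 10]
  n_loci: 13
  alleles_per_locus: [8, 14]
  founder_freq_concentration: 5.0
  sim_days: 600.0
  breeding_interval: 30.0
  male_tenure_median: 450.0
  female_tenure_median: 330.0
  p_inherit_male: 0.33
  p_inherit_female: 0.52
  p_helper_immigrant: 0.17
  p_helper_paternity: 0.05
  p_helper_maternity: 0.05
  genotyping_error_rate: 0.0
  missing_rate: 0.0
  seed: 7

frequency_method: corrected
alpha: 0.05
n_null: 2000
n_reps: 100
seed: 7
outdir: socialkin_out
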