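# Full-pipeline configuration for `perimb pipeline run --config ... --out DIR`.
# Either `cohort` (simulate) or `input_dir` (load a written cohort) is required.
cohort:
  n_families: 20
  twin_fraction: 0.5
  twin_effect: 2.0
  family_effect: 0.5
  depth_mean: 1500.0
  seed: 4
rarefaction_depth: 600    # the source study used 5000 at full scale
decontam_threshold: 0.1
decontam_method: combined
permanova_permutations: 199
ancom_rank: 6             # genus
twin_bootstrap: 1000
twin_confidence: 0.95
shared_random_pairs: 1000
seed: 7
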