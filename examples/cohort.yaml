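# Synthetic cohort parameters for `perimb simulate --config examples/cohort.yaml`.
# Omitted keys fall back to CohortConfig defaults.
n_families: 30            # mothers; each delivers 1 neonate (2 when twins)
twin_fraction: 0.25       # probability a pregnancy is a twin pregnancy
mono_fraction_of_twins: 0.2
n_negative_controls: 9    # blanks, spread round-robin over batches
n_batches: 3
n_features: 80            # taxa, including contaminants
depth_mean: 2000.0        # Poisson mean sequencing depth per sample
# site_effect: a single Dirichlet concentration, or a per-site mapping to
# tune site richness, e.g.:
site_effect:
  GL: 8.0
  AF: 3.0
  M: 1.2
  CB: 0.5
  VD: 0.15
family_effect: 0.5        # shrink family members toward a shared draw
twin_effect: 2.0          # extra shrinkage within twin pairs
n_contaminants: 8
contamination_strength: 2.0   # contaminant mass ~ strength / concentration
batch_effect: 0.4         # per-batch log-normal abundance factor
subject_sigma: 1.0        # per-subject compositional noise scale
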