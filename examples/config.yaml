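# Example pipeline configuration for `sectornet analyze`.
# Either point `inputs` at CSVs (roster, two adjacency matrices, outcome
# items) or keep a `synthetic` block to generate them; not both.
synthetic:
  # Any GeneratorConfig field can be overridden here, e.g.:
  # n_members: 38
  # reciprocity_boost: 0.54
  outcome_model:
    focal: intersectoral_out_degree
    beta_focal: 0.15
params:
  n_perms: 10000
  seed: 7
  reciprocity_method: dyad      # or: arc
  permutation_scheme: y         # or: freedman_lane
  city_reference: Boston
  sector_reference: Researcher
  collinearity_threshold: 0.70
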