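# Column documentation for every TSV the pipeline writes.
# All tables start with a comment line "# config_hash=... seed=...".

stems.tsv:
  stem_id: integer stem identifier, unique within the dataset
  x_m: stem x coordinate in metres, 0 <= x < plot_x_m
  y_m: stem y coordinate in metres, 0 <= y < plot_y_m
  species: species label

topography.tsv:
  col: quadrat column index (x // quadrat_m)
  row: quadrat row index (y // quadrat_m)
  elevation_m: mean of the quadrat's four corner elevations (m)
  slope_deg: mean angular slope of the four corner-triple planes (degrees)
  convexity_m: quadrat elevation minus mean rook-neighbour elevation (m)

habitatmap.tsv:
  col: quadrat column index
  row: quadrat row index
  habitat: ordered habitat label, one of V, LS, HG, RT, HS

taxonomy.tsv:
  species: species label (matches tree tips and stems)
  genus: genus label
  family: family label

habitat_summary.tsv:
  habitat: habitat label
  n_quadrats: quadrats carrying this label
  area_ha: n_quadrats x quadrat area
  n_species: species with at least one stem in the habitat
  n_stems: stems in the habitat
  density_per_ha: n_stems / area_ha (computed quotient)

associations.tsv:
  species: tested species (abundance strictly above min_stems)
  habitat: habitat tested
  observed: stems of the species in the habitat under the true map
  p_pos: fraction of null maps with count >= observed
  p_neg: fraction of null maps with count <= observed
  verdict: '+', '-' (two-tailed at alpha) or 'ns'

association_summary.tsv:
  habitat: habitat label, plus a Total row
  n_positive: significant positive associations
  n_negative: significant negative associations

signal.tsv:
  K: Blomberg's K of the median ordered habitat score
  n_perm: tip-shuffle permutations
  p_two_tailed: doubled smaller tail with +1 continuity, capped at 1
  k_above_null_median: whether K exceeds the null median (signal direction)

ses_<source>_<scale>m.tsv:
  assemblage: quadrat (q<i>) or coarse-cell (c<factor>_<i>) identifier
  richness: species count of the assemblage
  mpd_obs / mmpd_obs: observed mean pairwise / nearest-relative distance
  rnd_mpd_mean / rnd_mpd_sd: swap-null moments of MPD
  rnd_mmpd_mean / rnd_mmpd_sd: swap-null moments of MMPD
  nri / nti: negated standardized effect sizes (positive = clustering)
  degenerate: richness < 2 or null sd at rounding-noise level

habitat_pool_<source>.tsv: same columns as ses tables, one row per habitat
  (habitat species list vs the whole-plot pool)

habitat_means.tsv:
  source: phylogeny source (molecular or taxonomy)
  metric: nri or nti
  habitat: habitat label
  mean / se: SAR-GLS estimate of the habitat mean and its standard error
  t / p: test of mean != 0 (df = n - habitats)
  lambda: fitted spatial dependence (shared within source x metric)

phylogeny_comparison.tsv:
  metric: nri or nti
  group: habitat label or 'all'
  n: complete pairs used
  mean_diff / se_diff: mean and SE of (molecular - taxonomy) differences
  t / df / p: paired t-test

framework_labels.tsv:
  habitat: habitat label
  label: Habitat Filtering | Limiting Similarity | Neutrality | Indeterminate
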