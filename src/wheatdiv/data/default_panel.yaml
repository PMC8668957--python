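# Default study-panel emulation recipe.
#
# 199 Central European winter wheat landraces from 6 countries plus 67
# modern cultivars (27 of them Western), ~15.8K biallelic markers on the 21
# wheat chromosomes. Six ancestral populations under Balding-Nichols drift
# (F = 0.25): landrace countries draw admixture mainly from four groups
# (q1, q3, q4, q6, with a country-specific gradient), modern material is
# dominated by the remaining two (q2, q5). Residual heterozygosity and
# missingness are injected at post-QC array levels.
K_true: 6
F: 0.25
n_markers: 15808
missing_rate: 0.02
het_rate: 0.01
seed: 0
regions:
  - name: Hungary
    n_accessions: 60
    alpha: [0.4, 0.02, 0.3, 0.1, 0.02, 1.6]
    chrono_class: landrace
    year_range: [1950, 1960]
  - name: Yugoslavia
    n_accessions: 40
    alpha: [0.5, 0.02, 0.6, 0.9, 0.02, 0.3]
    chrono_class: landrace
    year_range: [1950, 1960]
  - name: Bulgaria
    n_accessions: 30
    alpha: [0.4, 0.02, 0.7, 0.7, 0.02, 0.3]
    chrono_class: landrace
    year_range: [1950, 1960]
  - name: Romania
    n_accessions: 25
    alpha: [0.6, 0.02, 0.9, 0.3, 0.02, 0.3]
    chrono_class: landrace
    year_range: [1950, 1960]
  - name: Czechoslovakia
    n_accessions: 24
    alpha: [1.0, 0.02, 0.5, 0.1, 0.02, 0.5]
    chrono_class: landrace
    year_range: [1950, 1960]
  - name: Austria
    n_accessions: 20
    alpha: [0.9, 0.05, 0.3, 0.05, 0.3, 0.4]
    chrono_class: landrace
    year_range: [1950, 1960]
  - name: modern_central
    n_accessions: 40
    alpha: [0.05, 0.9, 0.05, 0.02, 1.2, 0.05]
    chrono_class: modern
    country: mixed_central
    year_range: [1970, 2015]
  - name: modern_west
    n_accessions: 27
    alpha: [0.02, 0.4, 0.02, 0.02, 1.8, 0.02]
    chrono_class: modern
    country: mixed_western
    western_flag: true
    year_range: [1970, 2015]
block_spec:
  n_blocks: 20
  min_markers: 4
  max_markers: 8
  pool_size: 4
  within_gap_bp: [50000, 500000]
  between_gap_bp: [5000000, 10000000]
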