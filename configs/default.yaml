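# Default scenario: NNN pentapeptide library sorted into a 4% unstable bin.
scheme_name: NNN
num_codon_positions: 5
n_variants: 50000
abundance_model: lognormal
abundance_sigma: 1.0

rule:
  base_rate: 0.008          # 1/min; stable reporter baseline
  stop_rate: 0.06           # truncations treated as unstable
  position_effects:
    "1:I": 8.0              # planted degron: Ile/Leu at position 1
    "1:L": 8.0

tft:
  m_gfp: 0.115              # 1/min, fast-maturing GFP
  m_cherry: 0.0173          # 1/min, slow-maturing mCherry
  cell_noise_cv: 0.3
  nonfluorescent_fraction: 0.05
  dead_fraction: 0.05

sort:
  unstable_bin_fraction: 0.04
  n_cells: 100000

reads:
  amplicon_length: 217
  reads_per_sample: 100000
  substitution_error_rate: 0.001
  quality_mean: 32.0
  quality_sd: 3.0

layout:
  variable_length: 15
  max_anchor_mismatches: 1
  min_mean_quality: 20.0

enrich:
  pseudocount_vs_input: 0.5
  pseudocount_vs_null: 0.0
  top_k_candidates: 20

outdir: results
seed: 0
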