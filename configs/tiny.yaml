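# Minimal scenario for quick checks and CLI smoke runs.
scheme_name: NNN
n_variants: 400
sort:
  unstable_bin_fraction: 0.04
  n_cells: 4000
reads:
  reads_per_sample: 4000
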