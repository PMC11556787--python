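# Methods

## The screen being modelled

A sort-seq (FACS-seq) degron screen couples three measurements: a
randomized peptide library fused to a stability reporter, fluorescence-
activated sorting of cells into stability bins, and deep amplicon
sequencing of the sorted bins and the input pool. The reporter is a
tandem fluorescent timer (tFT): a fast-maturing GFP fused to a
slow-maturing mCherry. Fast protein turnover removes molecules before the
slow red fluorophore matures, so the per-cell mCherry/GFP ratio falls
monotonically with the degradation rate, and the low-ratio tail of the
sorted population is enriched for destabilizing (degron-bearing)
variants. The analysis question is then positional: which amino acids are
over-represented at which positions of the randomized window in the
unstable bin, relative to (a) the degenerate-codon null and (b) the input
library.

## Codon null model

A library built with degenerate codons has a known expected amino-acid
composition absent selection: under NNN each position draws uniformly
from 64 codons, so `E[freq(aa)] = (# codons encoding aa)/64` — 3/64 for
Ile, 6/64 for Leu, 3/64 for stops. These fractions are computed by exact
enumeration of the scheme's codon product with `fractions.Fraction`, so
equality tests against rationals are exact. Stops are carried in the
distribution (the 64-codon denominators include them); conditioning on
sense codons is a separate explicit operation
(`AminoAcidDistribution.sense_renormalized`), used when comparing against
stop-free peptide tallies. The standard nuclear genetic code is the
default; any 64-codon map can be injected.

## Simulator

The generator's defaults are the screen's stated conditions: five NNN
codons in a 15-nt variable region inside a 217-bp amplicon, an unstable
bin of 4% of gated cells, and substitution-only sequencing error.

- **Library.** Inserts are drawn i.i.d. per nucleotide from the scheme's
  per-position alphabets. Abundances model uneven transformation:
  lognormal with σ = 1 by default (Dirichlet and uniform available). An
  exhaustive mode enumerates the full codon product for small schemes
  (guarded at 2×10⁶ inserts) for oracle tests.
- **Stability rule.** The planted ground truth is a pure function of the
  peptide: a base rate of 0.008 min⁻¹ (half-life ≈ 87 min, a stable
  reporter) times multiplicative per-(position, amino-acid) factors. The
  default plants an 8× destabilization for Ile or Leu at position 1
  (effective half-life ≈ 11 min). Stop-containing peptides — truncations
  whose behaviour the screen does not constrain — get their own rate
  class, default 0.06 min⁻¹ (unstable); they are tallied separately and
  never enter the 20×5 matrices (an include-stops switch exists at the
  counts level via the stop table).
- **Timer readout.** With constant synthesis, first-order maturation and
  first-order degradation, the steady-state mature-fluorophore ratio
  normalized to 1 at k = 0 is R(k) = m_c(m_g + k)/(m_g(m_c + k)). This is
  the simplest closed form that reproduces the monotone ratio–stability
  relationship the sort relies on; defaults m_g = 0.115 min⁻¹ (~6-min
  maturation) and m_c = 0.0173 min⁻¹ (~40 min) are typical literature
  maturation scales for the two fluorophores. Per-cell observed log-ratio
  is log R(k) plus Gaussian noise (SD 0.3 by default); 5% of cells fail
  each of the live and fluorescence gates.
- **Sorting.** The unstable bin is the lowest `round(f·n_gated)` cells by
  observed log-ratio (a sharp empirical quantile with stable tie-break,
  so the bin size is exact). The input-pool sample is the full gated
  population.
- **Reads.** Each read is upstream flank + insert + downstream flank
  (101 + 15 + 101 = 217 nt; the upstream flank ends in-frame with
  GCT TCT so the translated junction reads Ala-Ser before the randomized
  window). Substitution errors are i.i.d. per base (default 10⁻³),
  replacing the base with one of the other three uniformly; qualities are
  clipped-Gaussian Phred+33 (mean 32, SD 3). Indels, PCR cycle bias,
  paired-end merging, and post-sort regrowth are not simulated —
  extraction is anchored at fixed spacing and would drop indel reads
  anyway, and regrowth bias is unknowable without data.

All randomness flows from one top-level seed fanned out deterministically
per stage; identical config + seed reproduces outputs byte for byte.

What passing tests on this generator show — and do not show: recovery
results demonstrate that the statistic identifies a planted positional
signal at realistic depths under multiplicative rate rules, lognormal
abundance skew, Gaussian ratio noise and substitution error. Real
libraries additionally have PCR duplicates, indels, context-dependent
error, gate drift, and growth competition, none of which are emulated;
conclusions about those failure modes cannot be drawn from these tests.

## Extraction

Reads pass a mean-Phred filter (default ≥ 20; a mean filter rather than
per-base masking because a single low-quality base is handled by the
downstream anchor/translation checks), then both 15-nt anchors must match
at Hamming distance ≤ 1 at exactly 15 nt separation, at a unique offset;
zero or multiple placements drop the read. Variable regions with
non-ACGT characters are dropped as ambiguous; stop-containing
translations go to the stop table. The five accounting categories are
disjoint and must sum to the input read count (validated). A vectorized
sliding-window scanner processes batches of equal-length reads and is
unit-tested to agree exactly with the per-read reference implementation.

## Enrichment

Frequencies are read-weighted (each sequenced read counts once; a
unique-peptide mode exists for diagnostics): `freq(aa,p) = Σ counts with
aa at p / Σ counts`. Fold enrichment divides by the codon null
(`codon_null` panel) or by the input-library frequency (`input_library`
panel). Smoothing adds a configurable pseudocount of reads per (aa,
position) cell before forming frequencies — default 0.5 for the
input-relative panel (protects against empty input cells at desk scale)
and 0 for the codon-null panel (the null is never zero under NNN, and raw
mode reproduces printed large-count worked examples). At pseudocount 0 a
cell absent from both samples is NaN, and a bin-observed amino acid
missing from the input is an error directing the user to a pseudocount.
Heatmaps display log2 fold on a diverging scale centred at 0; the TSV
stores the log2 values and round-trips losslessly.

Candidate ranking scores each bin peptide by Σ_p log fold(aa_p, p) with
count-then-lexicographic tie-breaks. It is explicitly a heuristic
ordering (the quantity has no calibrated null) and is labelled as such in
the report.

## Kinetics

Half-lives are fit by least squares on log intensity vs time (k =
−slope, t½ = ln2/k, with R² and the slope's standard error); log-linear
fitting is the right tool for 3–5 point chase series and matches
band-densitometry practice. A fitted k ≤ 0 is reported as stable with
infinite half-life rather than an error. A nonlinear option with plateau
term `c + (I₀−c)·exp(−kt)` (scipy `curve_fit`, non-negative bounds)
handles substrates with a stable fraction; it is off by default because
it is under-determined at 3–4 points. Ratio summaries are geometric
(mean of log-ratios exponentiated, SD on the log scale) since flow ratios
are approximately log-normal; an arithmetic mode is provided for
comparison.

## Recovery benchmarks and problem sizes

`degronscreen.experiments` packages two benchmarks used by the analysis
drivers and the acceptance script:

- **Planted-rule recovery** — 200,000 variants, 600,000 cells, 500,000
  reads per sample, 4% bin, noise SD 0.3, 8× Ile/Leu-at-P1 rule. The
  600,000-cell draw puts ≈23,000 cells in the bin, comfortably more than
  the read depth can resolve, and keeps a full run around two minutes on
  one core. P1 fold CIs are percentile bootstrap (200 multinomial
  resamples of both samples' read counts). Off-position deviation from
  fold 1 is scored as z = log fold / SE where the SE combines the two
  independent sampling layers on each side: sorted cells (the independent
  units) and reads (a second multinomial drawn from the cells). The
  no-spurious-signal criterion is max |z| < 4.5 across the 80
  position-2–5 cells, chosen a priori as a familywise bound (P(max of 80
  |z| > 4.5) < 10⁻³ under the null).
- **Hard-threshold selection oracle** — zero noise, uniform abundance,
  bin fraction set to the realized prevalence of the destabilized class.
  The analytic input-relative fold at P1 is (1−q\*)/(q_I+q_L) = 61/9 for
  both Ile and Leu under NNN; the estimate must sit within 3 SDs of the
  combined library- and cell-sampling noise.

## Known limitations

- The per-position independence of the enrichment model cannot represent
  pairwise couplings or motif effects beyond whole-peptide multipliers in
  the simulator's rule.
- Enrichment cells carry no significance test; the z-envelope used in
  benchmarks is a sampling-noise diagnostic, not inference about real
  biology.
- The timer model is steady-state; it does not capture induction
  transients or maturation-corrected rate inference from the ratio
  itself.
- Extraction assumes substitution-only error at fixed amplicon geometry;
  indel-rich platforms would need an aligner-based front end.
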