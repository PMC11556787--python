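"""Synthetic FACS-seq data with planted ground truth.

This module generates everything a sort-seq degron screen produces, with the
true answer known: a degenerate-codon pentapeptide library, a degradation
rate planted per peptide by a configurable stability rule, a
tandem-fluorescent-timer (tFT) mCherry/GFP readout per cell, sorting of the
low-ratio ("unstable") tail of the gated population, and amplicon FASTQ
reads with substitution sequencing error for both the input pool and the
sorted bin.  Every downstream stage (extraction, enrichment, kinetics) can
therefore be tested against exact ground truth without any external data.

The tFT readout model: with constant synthesis, first-order maturation
(rates ``m_g`` for the fast GFP, ``m_c`` for the slow mCherry) and
first-order degradation ``k``, the steady-state mature-fluorophore ratio,
normalized to 1 at ``k = 0``, is

    R(k) = m_c (m_g + k) / (m_g (m_c + k)),

strictly decreasing in ``k`` whenever ``m_c < m_g``: the lower the ratio,
the less stable the protein.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .codons import (
    DegenerateCodonScheme,
    GeneticCode,
    STOP,
    standard_code,
    translate_dna,
)
from .errors import ConfigurationError, InsufficientDataError

logger = logging.getLogger(__name__)

# Default constant flanks realizing the 217-bp amplicon geometry
# (101 + 15 + 101).  The upstream flank ends in-frame with GCT TCT so the
# translated reporter context reads Ala-Ser before the five randomized
# codons (the "ASXXXXX" junction); the sequences themselves are arbitrary.
DEFAULT_UPSTREAM_FLANK = (
    "GCCCTCTCCACCGGGGGTGGGCATGTGAGGTAAATCAAAAGTACGGGCATTATCATCTGC"
    "ATGCACGGATTCGTACGTCGTACCAAGTAGAGTAAGCTTCT"
)
DEFAULT_DOWNSTREAM_FLANK = (
    "TCACGGTCTAGTTAGTATAGGCCGCCGCGAAGGAACCCGCTGCCCTTTGTACTGGTACGT"
    "ATCCACTTGCTACACGAGGTTTGCGATCGCTCGTGACCTGT"
)

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class VariantGroundTruth:
    """One simulated library member."""

    dna_insert: str
    peptide: str
    k_deg: float          # 1/min
    input_abundance: float

    def __post_init__(self) -> None:
        if self.k_deg < 0:
            raise ConfigurationError("k_deg must be non-negative")


@dataclass(frozen=True)
class StabilityRule:
    """Planted map peptide -> degradation rate (pure function of sequence).

    ``position_effects`` maps (1-based position, amino acid) to a
    multiplicative factor on ``base_rate``; ``motif_effects`` maps whole
    peptides to an extra factor; stop-containing peptides get their own
    rate class ``stop_rate`` (truncations; default unstable).
    """

    base_rate: float = 0.008          # 1/min, t1/2 ~ 87 min: a stable reporter
    position_effects: Mapping[Tuple[int, str], float] = field(
        default_factory=dict
    )
    motif_effects: Mapping[str, float] = field(default_factory=dict)
    stop_rate: float = 0.06           # 1/min, t1/2 ~ 12 min

    def __post_init__(self) -> None:
        if self.base_rate <= 0 or self.stop_rate <= 0:
            raise ConfigurationError("rates must be positive")
        factors = list(self.position_effects.values()) + list(
            self.motif_effects.values()
        )
        if any(f <= 0 for f in factors):
            raise ConfigurationError("all rule factors must be > 0")

    @classmethod
    def ile_leu_p1(cls, fold: float = 8.0, **kwargs) -> "StabilityRule":
        """Default planted rule: Ile/Leu at position 1 destabilize."""
        return cls(
            position_effects={(1, "I"): fold, (1, "L"): fold}, **kwargs
        )

    def rate(self, peptide: str) -> float:
        if STOP in peptide:
            return self.stop_rate
        k = self.base_rate
        for pos, aa in enumerate(peptide, start=1):
            k *= self.position_effects.get((pos, aa), 1.0)
        k *= self.motif_effects.get(peptide, 1.0)
        return k

    def rates(self, peptides: Sequence[str]) -> np.ndarray:
        return np.array([self.rate(p) for p in peptides], dtype=float)


@dataclass(frozen=True)
class TFTParameters:
    """Timer maturation rates and per-cell noise/gating probabilities."""

    m_gfp: float = 0.115       # 1/min, superfast GFP, t-mature ~ 6 min
    m_cherry: float = 0.0173   # 1/min, mCherry, t-mature ~ 40 min
    cell_noise_cv: float = 0.3  # SD of per-cell log-ratio noise
    nonfluorescent_fraction: float = 0.05
    dead_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.m_gfp <= 0 or self.m_cherry <= 0:
            raise ConfigurationError("maturation rates must be positive")
        if self.m_cherry >= self.m_gfp:
            raise ConfigurationError(
                "mCherry must be the slower-maturing partner (m_cherry < m_gfp)"
            )
        for frac in (self.nonfluorescent_fraction, self.dead_fraction):
            if not 0 <= frac < 1:
                raise ConfigurationError("gate-failure fractions must be in [0,1)")
        if self.cell_noise_cv < 0:
            raise ConfigurationError("noise CV must be non-negative")


@dataclass(frozen=True)
class SortConfig:
    """How many cells to draw and how deep the unstable gate cuts."""

    unstable_bin_fraction: float = 0.04
    n_cells: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.unstable_bin_fraction < 1:
            raise ConfigurationError("bin fraction must be in (0, 1)")
        if self.n_cells <= 0:
            raise ConfigurationError("n_cells must be positive")


@dataclass(frozen=True)
class ReadSimConfig:
    """Amplicon read generation: flanks, depth, substitution error, quality."""

    upstream_flank: str = DEFAULT_UPSTREAM_FLANK
    downstream_flank: str = DEFAULT_DOWNSTREAM_FLANK
    amplicon_length: int = 217
    reads_per_sample: int = 100_000
    substitution_error_rate: float = 0.001
    quality_mean: float = 32.0
    quality_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.upstream_flank) + len(self.downstream_flank) + 15 != (
            self.amplicon_length
        ):
            raise ConfigurationError(
                "flank lengths + 15 must equal amplicon_length"
            )
        if not 0 <= self.substitution_error_rate < 1:
            raise ConfigurationError("error rate must be in [0, 1)")
        if self.reads_per_sample < 0:
            raise ConfigurationError("reads_per_sample must be >= 0")


class Library(Sequence):
    """A simulated library held as parallel arrays.

    Behaves as a sequence of :class:`VariantGroundTruth`; the arrays are
    exposed for vectorized downstream simulation.
    """

    def __init__(
        self,
        dna_inserts: List[str],
        peptides: List[str],
        k_deg: np.ndarray,
        input_abundance: np.ndarray,
    ) -> None:
        if not (
            len(dna_inserts) == len(peptides) == len(k_deg)
            == len(input_abundance)
        ):
            raise ConfigurationError("library arrays must have equal length")
        if abs(input_abundance.sum() - 1.0) > 1e-9:
            raise ConfigurationError("abundances must sum to 1")
        self.dna_inserts = dna_inserts
        self.peptides = peptides
        self.k_deg = np.asarray(k_deg, dtype=float)
        self.input_abundance = np.asarray(input_abundance, dtype=float)

    def __len__(self) -> int:
        return len(self.dna_inserts)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        return VariantGroundTruth(
            dna_insert=self.dna_inserts[i],
            peptide=self.peptides[i],
            k_deg=float(self.k_deg[i]),
            input_abundance=float(self.input_abundance[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": np.arange(len(self)),
                "dna_insert": self.dna_inserts,
                "peptide": self.peptides,
                "k_deg": self.k_deg,
                "input_abundance": self.input_abundance,
            }
        )


def _translate_inserts(inserts: List[str], code: GeneticCode) -> List[str]:
    # memoize codon lookups; inserts share few distinct codons
    table = code.codon_to_aa
    out = []
    for ins in inserts:
        out.append(
            "".join(table[ins[i : i + 3]] for i in range(0, len(ins), 3))
        )
    return out


EXHAUSTIVE_LIMIT = 2_000_000


def sample_library(
    n_variants: int,
    scheme: DegenerateCodonScheme | None = None,
    rule: StabilityRule | None = None,
    seed: int = 0,
    abundance_model: str = "lognormal",
    abundance_sigma: float = 1.0,
    exhaustive: bool = False,
    code: GeneticCode | None = None,
) -> Library:
    """Draw a library of variable-region inserts with planted rates.

    Inserts are drawn i.i.d. per nucleotide position from the scheme's
    alphabets; abundances model uneven transformation efficiency
    (lognormal or Dirichlet, configurable).  With ``exhaustive=True`` the
    full codon product of the scheme is enumerated once (uniform
    abundance), which is only feasible for small schemes.
    """
    scheme = scheme or DegenerateCodonScheme.from_name("NNN")
    rule = rule or StabilityRule()
    code = code or standard_code()
    rng = np.random.default_rng(seed)

    if exhaustive:
        total = scheme.codons_per_position ** scheme.num_codon_positions
        if total > EXHAUSTIVE_LIMIT:
            raise ConfigurationError(
                f"exhaustive enumeration of {total} inserts exceeds the "
                f"{EXHAUSTIVE_LIMIT} limit; use sampling instead"
            )
        codon_set = list(scheme.codons())
        inserts = [
            "".join(combo)
            for combo in itertools.product(
                codon_set, repeat=scheme.num_codon_positions
            )
        ]
        abundance = np.full(len(inserts), 1.0 / len(inserts))
    else:
        if n_variants <= 0:
            raise ConfigurationError("n_variants must be positive")
        length = 3 * scheme.num_codon_positions
        cols = []
        for j in range(length):
            alpha = sorted(scheme.position_alphabets[j % 3])
            idx = rng.integers(0, len(alpha), size=n_variants)
            cols.append(np.frombuffer(
                "".join(alpha).encode(), dtype=np.uint8
            )[idx])
        mat = np.column_stack(cols)
        inserts = [row.tobytes().decode() for row in mat]
        if abundance_model == "lognormal":
            w = np.exp(rng.normal(0.0, abundance_sigma, size=n_variants))
        elif abundance_model == "dirichlet":
            w = rng.gamma(abundance_sigma, size=n_variants)
        elif abundance_model == "uniform":
            w = np.ones(n_variants)
        else:
            raise ConfigurationError(
                f"unknown abundance model {abundance_model!r}"
            )
        abundance = w / w.sum()

    peptides = _translate_inserts(inserts, code)
    k_deg = rule.rates(peptides)
    return Library(inserts, peptides, k_deg, abundance)


def tft_ratio(
    k_deg: float | np.ndarray, params: TFTParameters
) -> float | np.ndarray:
    """Normalized steady-state mCherry/GFP ratio for degradation rate k.

    R(k) = m_c (m_g + k) / (m_g (m_c + k)); R(0) = 1 and R -> m_c/m_g as
    k -> infinity.
    """
    k = np.asarray(k_deg, dtype=float)
    if np.any(k < 0):
        raise ConfigurationError("k_deg must be non-negative")
    mc, mg = params.m_cherry, params.m_gfp
    r = (mc * (mg + k)) / (mg * (mc + k))
    return float(r) if np.isscalar(k_deg) else r


def simulate_cells(
    library: Library, params: TFTParameters, sort: SortConfig
) -> pd.DataFrame:
    """Per-cell table: variant id, observed log-ratio, gate flags.

    Cells are drawn by input abundance; each observed log-ratio is
    log R(k) plus Gaussian noise of SD ``cell_noise_cv``.  Dead and
    non-fluorescent cells are flagged (they fail the live / mCherry-GFP
    positive gates) and excluded from sorting.
    """
    if len(library) == 0:
        raise InsufficientDataError("library is empty")
    rng = np.random.default_rng(sort.seed)
    n = sort.n_cells
    variant_id = rng.choice(
        len(library), size=n, p=library.input_abundance
    )
    true_log_ratio = np.log(tft_ratio(library.k_deg, params))[variant_id]
    observed = true_log_ratio + rng.normal(0.0, params.cell_noise_cv, size=n)
    dead = rng.random(n) < params.dead_fraction
    nonfl = rng.random(n) < params.nonfluorescent_fraction
    return pd.DataFrame(
        {
            "variant_id": variant_id,
            "log_ratio": observed,
            "dead": dead,
            "nonfluorescent": nonfl,
            "gated": ~(dead | nonfl),
        }
    )


def sort_unstable_bin(
    cell_table: pd.DataFrame, sort: SortConfig
) -> Tuple[pd.Series, pd.Series]:
    """Collect the low-ratio tail of the gated cells.

    Returns (unstable-bin multiset, input-pool multiset) as variant-id ->
    cell-count Series.  The bin holds the ``unstable_bin_fraction``
    quantile's worth of gated cells with the lowest observed log-ratio
    (ties broken by table order so the bin size is exact).
    """
    gated = cell_table.loc[cell_table["gated"]]
    n_gated = len(gated)
    if n_gated < 1 / sort.unstable_bin_fraction:
        raise InsufficientDataError(
            f"{n_gated} gated cells cannot fill a "
            f"{sort.unstable_bin_fraction:.3f} bin"
        )
    n_bin = int(round(sort.unstable_bin_fraction * n_gated))
    order = np.argsort(gated["log_ratio"].to_numpy(), kind="stable")
    bin_ids = gated["variant_id"].to_numpy()[order[:n_bin]]
    bin_counts = pd.Series(bin_ids).value_counts().sort_index()
    pool_counts = gated["variant_id"].value_counts().sort_index()
    bin_counts.index.name = pool_counts.index.name = "variant_id"
    return bin_counts, pool_counts


def _phred_string(rng: np.random.Generator, n: int, length: int,
                  mean: float, sd: float) -> np.ndarray:
    q = rng.normal(mean, sd, size=(n, length))
    q = np.clip(np.rint(q), 2, 41).astype(np.uint8) + 33
    return q


def emit_amplicon_reads(
    multiset: Mapping[int, int] | pd.Series,
    library: Library,
    cfg: ReadSimConfig,
    fastq_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write amplicon FASTQ reads for a variant multiset (plus truth TSV).

    Each read is upstream_flank + insert + downstream_flank with i.i.d.
    substitution errors at ``substitution_error_rate`` per base and
    Phred+33 qualities from a clipped Gaussian model.  ``truth_path``
    records read id -> variant id.
    """
    counts = pd.Series(multiset).astype(int)
    counts = counts[counts > 0]
    fastq_path = Path(fastq_path)
    if counts.empty or cfg.reads_per_sample == 0:
        warnings.warn(
            f"no reads to emit; writing empty FASTQ to {fastq_path}",
            stacklevel=2,
        )
        fastq_path.write_text("")
        if truth_path is not None:
            Path(truth_path).write_text("read_id\tvariant_id\n")
        return

    rng = np.random.default_rng(cfg.seed)
    n = cfg.reads_per_sample
    ids = counts.index.to_numpy()
    p = counts.to_numpy() / counts.sum()
    chosen = rng.choice(ids, size=n, p=p)

    up = np.frombuffer(cfg.upstream_flank.encode(), dtype=np.uint8)
    down = np.frombuffer(cfg.downstream_flank.encode(), dtype=np.uint8)
    insert_mat = np.vstack([
        np.frombuffer(library.dna_inserts[v].encode(), dtype=np.uint8)
        for v in chosen
    ])
    reads = np.hstack([
        np.broadcast_to(up, (n, len(up))),
        insert_mat,
        np.broadcast_to(down, (n, len(down))),
    ]).copy()

    if cfg.substitution_error_rate > 0:
        mask = rng.random(reads.shape) < cfg.substitution_error_rate
        # substitute with one of the three OTHER bases, uniformly
        base_idx = np.searchsorted(_NT, reads[mask])
        shift = rng.integers(1, 4, size=mask.sum())
        reads[mask] = _NT[(base_idx + shift) % 4]

    quals = _phred_string(rng, n, reads.shape[1], cfg.quality_mean,
                          cfg.quality_sd)

    try:
        with open(fastq_path, "w") as fh:
            chunks = []
            for i in range(n):
                chunks.append(
                    f"@read_{i}\n{reads[i].tobytes().decode()}\n+\n"
                    f"{quals[i].tobytes().decode()}\n"
                )
                if len(chunks) == 10_000:
                    fh.write("".join(chunks))
                    chunks = []
            fh.write("".join(chunks))
    except OSError as exc:
        raise OSError(f"failed writing FASTQ to {fastq_path}: {exc}") from exc

    if truth_path is not None:
        try:
            with open(truth_path, "w") as fh:
                fh.write("read_id\tvariant_id\n")
                fh.writelines(
                    f"read_{i}\t{v}\n" for i, v in enumerate(chosen)
                )
        except OSError as exc:
            raise OSError(
                f"failed writing ground truth to {truth_path}: {exc}"
            ) from exc
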