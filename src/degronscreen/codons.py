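"""Genetic-code arithmetic for degenerate-codon libraries.

A randomized library built with degenerate primers (NNN, NNK, ...) has a
known amino-acid composition under the null hypothesis of no selection:
each amino acid's expected frequency at a randomized position equals the
number of codons in the degenerate set that encode it, divided by the size
of the set (e.g. Ile = 3/64 under NNN, Met = 1/32 under NNK).  These null
frequencies are the denominator of the fold-enrichment statistic computed
downstream, so they are carried as exact rationals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, Iterator, Mapping, Tuple

from Bio.Data import CodonTable

from .errors import AlphabetError, ConfigurationError, LengthError

NUCLEOTIDES = "ACGT"
STOP = "*"
#: Fixed display order for the 20 proteinogenic amino acids (alphabetical
#: one-letter codes); used for every matrix/TSV the package writes.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: IUPAC degenerate-nucleotide codes, used to parse scheme names like "NNK".
IUPAC_NT: Dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"), "K": frozenset("GT"),
    "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class GeneticCode:
    """A total map from the 64 DNA triplets to amino acids or ``*``."""

    codon_to_aa: Mapping[str, str]

    def __post_init__(self) -> None:
        codons = set(self.codon_to_aa)
        if len(codons) != 64 or any(
            len(c) != 3 or set(c) - set(NUCLEOTIDES) for c in codons
        ):
            raise ConfigurationError(
                "genetic code must map exactly the 64 ACGT triplets"
            )
        symbols = set(self.codon_to_aa.values())
        if not symbols <= set(AA_ALPHABET + STOP):
            raise ConfigurationError(f"unexpected symbols in code: {symbols}")

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard nuclear genetic code (NCBI table 1)."""
        table = CodonTable.unambiguous_dna_by_id[1]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = STOP
        return cls(codon_to_aa=mapping)

    def __getitem__(self, codon: str) -> str:
        return self.codon_to_aa[codon]


_STANDARD_CODE: GeneticCode | None = None


def standard_code() -> GeneticCode:
    """Memoized standard genetic code."""
    global _STANDARD_CODE
    if _STANDARD_CODE is None:
        _STANDARD_CODE = GeneticCode.standard()
    return _STANDARD_CODE


def translate_dna(seq: str, code: GeneticCode | None = None) -> str:
    """Translate a DNA string codon-by-codon; stops appear as ``*``.

    Only {A,C,G,T} are accepted: IUPAC ambiguity codes are the extraction
    stage's problem and are rejected here.
    """
    code = code or standard_code()
    if not seq or len(seq) % 3 != 0:
        raise LengthError(
            f"sequence length {len(seq)} is not a positive multiple of 3"
        )
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise AlphabetError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return "".join(code[seq[i : i + 3]] for i in range(0, len(seq), 3))


@dataclass(frozen=True)
class DegenerateCodonScheme:
    """A degenerate codon (three per-position nucleotide alphabets).

    ``num_codon_positions`` is the number of consecutive randomized codons
    in the variable region (5 for a pentapeptide library).
    """

    name: str
    position_alphabets: Tuple[frozenset, frozenset, frozenset]
    num_codon_positions: int = 5

    def __post_init__(self) -> None:
        if len(self.position_alphabets) != 3:
            raise ConfigurationError("a codon has exactly 3 positions")
        for alpha in self.position_alphabets:
            if not alpha or set(alpha) - set(NUCLEOTIDES):
                raise ConfigurationError(
                    "each codon-position alphabet must be a non-empty "
                    "subset of {A,C,G,T}"
                )
        if self.num_codon_positions < 1:
            raise ConfigurationError("num_codon_positions must be positive")

    @classmethod
    def from_name(
        cls, name: str, num_codon_positions: int = 5
    ) -> "DegenerateCodonScheme":
        """Build a scheme from a 3-letter IUPAC string such as "NNN" or "NNK"."""
        if len(name) != 3 or any(ch not in IUPAC_NT for ch in name.upper()):
            raise ConfigurationError(f"not a 3-letter IUPAC codon: {name!r}")
        alphabets = tuple(IUPAC_NT[ch] for ch in name.upper())
        return cls(name=name.upper(), position_alphabets=alphabets,
                   num_codon_positions=num_codon_positions)

    @property
    def codons_per_position(self) -> int:
        n = 1
        for alpha in self.position_alphabets:
            n *= len(alpha)
        return n

    def codons(self) -> Iterator[str]:
        """All codons in the set, in a fixed sorted order."""
        for triple in itertools.product(
            *(sorted(a) for a in self.position_alphabets)
        ):
            yield "".join(triple)


@dataclass(frozen=True)
class AminoAcidDistribution:
    """Null amino-acid distribution of one randomized codon position.

    Probabilities are exact :class:`fractions.Fraction` values over the 21
    symbols (20 amino acids plus ``*``); the stop mass is kept, because the
    library null counts stop codons among the 64 (renormalization over
    sense codons is an explicit, separate operation).
    """

    probs: Mapping[str, Fraction]
    scheme_name: str = ""

    def __post_init__(self) -> None:
        if set(self.probs) != set(AA_ALPHABET + STOP):
            raise ConfigurationError("distribution must cover 20 AAs + '*'")
        total = sum(self.probs.values())
        if not all(0 <= p <= 1 for p in self.probs.values()):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if abs(total - 1) > Fraction(1, 10**12):
            raise ConfigurationError(f"probabilities sum to {total}, not 1")

    def prob(self, symbol: str) -> Fraction:
        return self.probs[symbol]

    def sense_renormalized(self) -> "AminoAcidDistribution":
        """Distribution conditioned on not hitting a stop codon."""
        sense = 1 - self.probs[STOP]
        if sense == 0:
            raise ConfigurationError("all codons are stops; cannot condition")
        probs = {aa: self.probs[aa] / sense for aa in AA_ALPHABET}
        probs[STOP] = Fraction(0)
        return AminoAcidDistribution(
            probs=probs, scheme_name=self.scheme_name + "|sense"
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("symbol\tprobability\n")
            for sym in AA_ALPHABET + STOP:
                fh.write(f"{sym}\t{float(self.probs[sym]):.12g}\n")


def position_null_distribution(
    scheme: DegenerateCodonScheme, code: GeneticCode | None = None
) -> AminoAcidDistribution:
    """Expected amino-acid frequencies of one randomized codon position.

    prob(aa) = (# codons in the scheme's set encoding aa) / |set|, computed
    with exact rational arithmetic.  Under NNN this is the classic
    codon-count table over 64 (Ile 3/64, Leu 6/64, stop 3/64).
    """
    code = code or standard_code()
    counts: Dict[str, int] = {sym: 0 for sym in AA_ALPHABET + STOP}
    total = 0
    for codon in scheme.codons():
        counts[code[codon]] += 1
        total += 1
    if total == 0:
        raise ConfigurationError("scheme has an empty codon set")
    probs = {sym: Fraction(n, total) for sym, n in counts.items()}
    return AminoAcidDistribution(probs=probs, scheme_name=scheme.name)


def theoretical_diversity(num_positions: int, alphabet_size: int) -> int:
    """Number of distinct sequences: alphabet_size ** num_positions.

    For a pentapeptide library over 20 amino acids this is 20^5 = 3.2
    million.  Exact integer arithmetic.
    """
    if num_positions <= 0 or alphabet_size <= 0:
        raise ConfigurationError("both arguments must be positive integers")
    return alphabet_size ** num_positions
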