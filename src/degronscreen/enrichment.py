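"""Position-wise amino-acid enrichment of a sorted bin.

The screen's central statistic: tally how often each amino acid occurs at
each randomized position in a sample (read-weighted — each sequenced read
counts once), then divide by a reference to get fold-enrichment.  Two
references are supported, matching the two panels a sort-seq heatmap
usually shows: the degenerate-codon null (how often the amino acid is
expected from codon counts alone) and the input library (what was actually
present before sorting).  E.g. isoleucine at 17.7% of position 1 against
an NNN null of 3/64 = 4.7% is a 3.8-fold enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .codons import AA_ALPHABET, AminoAcidDistribution
from .errors import ConfigurationError, InsufficientDataError
from .extract import PeptideCounts

AA_ORDER = list(AA_ALPHABET)


def _position_labels(n: int) -> list:
    return [f"P{i}" for i in range(1, n + 1)]


@dataclass
class PositionFrequencyMatrix:
    """20 amino acids x P positions of relative frequencies."""

    freqs: pd.DataFrame
    n_peptides: int
    sample_label: str

    def __post_init__(self) -> None:
        if list(self.freqs.index) != AA_ORDER:
            raise ConfigurationError("rows must be the 20 AAs in fixed order")
        if (self.freqs.to_numpy() < 0).any():
            raise ConfigurationError("frequencies must be non-negative")

    @property
    def n_positions(self) -> int:
        return self.freqs.shape[1]


@dataclass
class EnrichmentMatrix:
    """Fold-enrichment values relative to a recorded reference."""

    folds: pd.DataFrame
    reference: str          # "codon_null" | "input_library"
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.reference not in ("codon_null", "input_library"):
            raise ConfigurationError(f"unknown reference {self.reference!r}")
        if self.pseudocount > 0 and (self.folds.to_numpy() <= 0).any():
            raise ConfigurationError(
                "folds must be positive when a pseudocount is used"
            )


def _aa_position_counts(counts: PeptideCounts) -> pd.DataFrame:
    """Read-weighted tally: occurrences of each AA at each position."""
    length = counts.peptide_length
    mat = pd.DataFrame(
        0.0, index=AA_ORDER, columns=_position_labels(length)
    )
    peps = np.array([list(p) for p in counts.counts], dtype="U1")
    weights = np.fromiter(counts.counts.values(), dtype=float,
                          count=len(counts.counts))
    for j, col in enumerate(mat.columns):
        tallies = pd.Series(weights).groupby(peps[:, j]).sum()
        mat.loc[tallies.index, col] = tallies.to_numpy()
    return mat


def position_frequencies(
    counts: PeptideCounts, unique_peptides: bool = False
) -> PositionFrequencyMatrix:
    """Relative AA frequency per position: freq(aa, p) = count(aa at p) / n.

    Read-weighted by default; ``unique_peptides=True`` switches to
    counting each distinct peptide once (diagnostic mode).
    """
    if not counts.counts:
        raise InsufficientDataError(f"no peptides in {counts.sample_label!r}")
    if unique_peptides:
        counts = PeptideCounts(
            sample_label=counts.sample_label,
            counts={p: 1 for p in counts.counts},
        )
    tally = _aa_position_counts(counts)
    n = counts.total()
    return PositionFrequencyMatrix(
        freqs=tally / n, n_peptides=n, sample_label=counts.sample_label
    )


def _smoothed(freqs: PositionFrequencyMatrix, pseudocount: float) -> pd.DataFrame:
    """Add ``pseudocount`` reads to every (aa, position) cell."""
    if pseudocount == 0:
        return freqs.freqs
    n = freqs.n_peptides
    return (freqs.freqs * n + pseudocount) / (n + 20 * pseudocount)


def enrichment_vs_null(
    freqs: PositionFrequencyMatrix,
    null: AminoAcidDistribution,
    pseudocount: float = 0.0,
) -> EnrichmentMatrix:
    """fold(aa, p) = freq(aa, p) / null(aa).

    The null must give every amino acid positive probability (schemes that
    cannot encode some residue have no defined enrichment for it).
    """
    null_vec = np.array([float(null.prob(aa)) for aa in AA_ORDER])
    if (null_vec <= 0).any():
        missing = [aa for aa, p in zip(AA_ORDER, null_vec) if p <= 0]
        raise ConfigurationError(
            f"null assigns zero probability to {missing}; enrichment undefined"
        )
    folds = _smoothed(freqs, pseudocount).div(null_vec, axis=0)
    return EnrichmentMatrix(
        folds=folds, reference="codon_null", pseudocount=pseudocount
    )


def enrichment_vs_input(
    bin_freqs: PositionFrequencyMatrix,
    input_freqs: PositionFrequencyMatrix,
    pseudocount: float = 0.5,
) -> EnrichmentMatrix:
    """fold(aa, p) = bin frequency / input-library frequency.

    The default half-read pseudocount keeps the ratio finite when an
    amino acid is unobserved in the (finite) input sample; raw mode
    (pseudocount 0) reproduces printed large-count numbers but can divide
    by zero, which is rejected.
    """
    if bin_freqs.freqs.shape != input_freqs.freqs.shape:
        raise ConfigurationError(
            f"shape mismatch: bin {bin_freqs.freqs.shape} vs "
            f"input {input_freqs.freqs.shape}"
        )
    denom = _smoothed(input_freqs, pseudocount)
    numer = _smoothed(bin_freqs, pseudocount)
    zero_denom = denom.to_numpy() == 0
    if (zero_denom & (numer.to_numpy() > 0)).any():
        raise ConfigurationError(
            "bin-observed amino acids missing from the input library; "
            "use a pseudocount > 0"
        )
    with np.errstate(invalid="ignore"):
        folds = numer / denom   # cells absent from BOTH samples become NaN
    return EnrichmentMatrix(
        folds=folds, reference="input_library", pseudocount=pseudocount
    )


def rank_candidates(
    counts: PeptideCounts, enr: EnrichmentMatrix, top_k: int = 20
) -> pd.DataFrame:
    """Heuristic candidate ranking by additive log-fold score.

    score(peptide) = sum over positions of log fold(aa_p, p); ties broken
    by read count (descending) then peptide (lexicographic).  This is a
    convenience ordering of bin members by how well they embody the
    position-wise enrichment trends, not a calibrated statistic.
    """
    if top_k < 1:
        raise ConfigurationError("top_k must be >= 1")
    with np.errstate(divide="ignore"):
        # a zero fold gives a -inf score: ranked last, which is intended
        log_folds = np.log(enr.folds.to_numpy())
    aa_index = {aa: i for i, aa in enumerate(AA_ORDER)}
    rows = []
    for pep, n in counts.counts.items():
        score = sum(
            log_folds[aa_index[aa], p] for p, aa in enumerate(pep)
        )
        rows.append((pep, score, n))
    out = pd.DataFrame(rows, columns=["peptide", "score", "count"])
    out = out.sort_values(
        ["score", "count", "peptide"], ascending=[False, False, True]
    ).head(top_k)
    return out.reset_index(drop=True)


def export_heatmap(
    enr: EnrichmentMatrix,
    tsv_path: str | Path,
    figure_path: Optional[str | Path] = None,
) -> None:
    """Write the log2 fold matrix as TSV and optionally render a heatmap."""
    with np.errstate(divide="ignore"):
        log2 = np.log2(enr.folds)
    try:
        log2.to_csv(tsv_path, sep="\t", index_label="amino_acid",
                    float_format="%.10g")
    except OSError as exc:
        raise OSError(f"failed writing heatmap TSV to {tsv_path}: {exc}") from exc
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import seaborn as sns

        fig, ax = plt.subplots(
            figsize=(2 + 0.6 * enr.folds.shape[1], 7)
        )
        # unobserved cells (fold 0 at pseudocount 0) render as blank
        shown = log2.replace([-np.inf, np.inf], np.nan)
        finite = shown.to_numpy()[np.isfinite(shown.to_numpy())]
        vmax = float(np.max(np.abs(finite))) if finite.size else 1.0
        vmax = vmax or 1.0
        sns.heatmap(
            shown, cmap="RdBu_r", center=0.0, vmin=-vmax, vmax=vmax,
            cbar_kws={"label": "log2 fold enrichment"}, ax=ax,
        )
        ax.set_title(f"enrichment vs {enr.reference}")
        ax.set_ylabel("amino acid")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)


def read_heatmap_tsv(path: str | Path) -> pd.DataFrame:
    """Read a log2-fold TSV back into a fold matrix (2 ** values)."""
    log2 = pd.read_csv(path, sep="\t", index_col="amino_acid")
    return 2.0 ** log2
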