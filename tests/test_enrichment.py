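"""Position frequencies, fold enrichment, ranking, and heatmap export."""

import numpy as np
import pandas as pd
import pytest

from degronscreen.codons import DegenerateCodonScheme, position_null_distribution
from degronscreen.enrichment import (
    AA_ORDER,
    enrichment_vs_input,
    enrichment_vs_null,
    export_heatmap,
    position_frequencies,
    rank_candidates,
    read_heatmap_tsv,
)
from degronscreen.errors import ConfigurationError, InsufficientDataError
from degronscreen.extract import PeptideCounts
from degronscreen.simulate import sample_library


@pytest.fixture(scope="module")
def nnn_null():
    return position_null_distribution(DegenerateCodonScheme.from_name("NNN"))


class TestPositionFrequencies:
    def test_single_peptide(self):
        freqs = position_frequencies(PeptideCounts("s", {"IHPYW": 3}))
        assert freqs.freqs.loc["I", "P1"] == 1.0
        assert freqs.freqs.loc["H", "P2"] == 1.0
        assert freqs.freqs.to_numpy().sum() == pytest.approx(5.0)

    def test_two_peptide_split(self):
        freqs = position_frequencies(
            PeptideCounts("s", {"IAAAA": 1, "LAAAA": 1})
        )
        assert freqs.freqs.loc["I", "P1"] == 0.5
        assert freqs.freqs.loc["L", "P1"] == 0.5

    def test_read_weighting(self):
        freqs = position_frequencies(
            PeptideCounts("s", {"IAAAA": 3, "LAAAA": 1})
        )
        assert freqs.freqs.loc["I", "P1"] == 0.75
        unique = position_frequencies(
            PeptideCounts("s", {"IAAAA": 3, "LAAAA": 1}),
            unique_peptides=True,
        )
        assert unique.freqs.loc["I", "P1"] == 0.5

    def test_exhaustive_library_recovers_codon_null(self, nnn_null):
        """Oracle: tallying the full 2-position NNN codon product (each
        DNA combination once) must give freq(aa, p) = codon count / 64."""
        scheme = DegenerateCodonScheme.from_name("NNN", 2)
        lib = sample_library(1, scheme, exhaustive=True)
        tally = {}
        for pep in lib.peptides:
            if "*" in pep:
                continue
            tally[pep] = tally.get(pep, 0) + 1
        freqs = position_frequencies(PeptideCounts("x", tally))
        sense = nnn_null.sense_renormalized()
        for aa in AA_ORDER:
            for col in ("P1", "P2"):
                # positions are independent, so conditioning on stop-free
                # peptides leaves exactly the sense-codon fractions
                assert freqs.freqs.loc[aa, col] == pytest.approx(
                    float(sense.prob(aa)), abs=1e-12
                )

    def test_columns_sum_to_one(self):
        counts = PeptideCounts(
            "s", {"IHPYW": 2, "LHPYW": 5, "AAAAA": 1}
        )
        freqs = position_frequencies(counts)
        assert np.allclose(freqs.freqs.sum(axis=0), 1.0, atol=1e-9)

    def test_empty_counts_rejected(self):
        with pytest.raises(InsufficientDataError):
            position_frequencies(PeptideCounts("s", {}))


class TestEnrichmentVsNull:
    def test_printed_worked_examples(self, nnn_null):
        """17.7% Ile over 3/64 is 3.8-fold; 14.8% Leu over 6/64 is 1.6-fold."""
        counts = PeptideCounts(
            "bin", {"IAAAA": 177, "LAAAA": 148, "GAAAA": 675}
        )
        freqs = position_frequencies(counts)
        enr = enrichment_vs_null(freqs, nnn_null, pseudocount=0.0)
        assert round(enr.folds.loc["I", "P1"], 1) == 3.8
        assert round(enr.folds.loc["L", "P1"], 1) == 1.6

    def test_identity_when_freq_equals_null(self, nnn_null):
        sense = nnn_null.sense_renormalized()
        data = {aa: [float(sense.prob(aa))] * 5 for aa in AA_ORDER}
        freqs = position_frequencies(PeptideCounts("s", {"IHPYW": 1}))
        freqs.freqs = pd.DataFrame(data).T.set_axis(
            freqs.freqs.columns, axis=1
        )
        enr = enrichment_vs_null(freqs, sense)
        expected = 1.0
        assert np.allclose(enr.folds.to_numpy(), expected, atol=1e-12)

    def test_fold_times_null_sums_to_one(self, nnn_null):
        """Reconstruction invariant: sum_aa fold(aa,p) * null(aa) = 1 at
        pseudocount 0 (stop-free samples against the sense null)."""
        counts = PeptideCounts("s", {"IHPYW": 7, "LHPYW": 2, "AWCYK": 4})
        sense = nnn_null.sense_renormalized()
        enr = enrichment_vs_null(position_frequencies(counts), sense, 0.0)
        null_vec = np.array([float(sense.prob(aa)) for aa in AA_ORDER])
        recon = (enr.folds.to_numpy() * null_vec[:, None]).sum(axis=0)
        assert np.allclose(recon, 1.0, atol=1e-9)

    def test_zero_null_probability_rejected(self):
        # the single codon AGG encodes only Arg: everything else gets zero
        null = position_null_distribution(
            DegenerateCodonScheme.from_name("AGG")
        )
        freqs = position_frequencies(PeptideCounts("s", {"IHPYW": 1}))
        with pytest.raises(ConfigurationError):
            enrichment_vs_null(freqs, null)


class TestEnrichmentVsInput:
    def test_self_comparison_is_identity(self):
        counts = PeptideCounts("s", {"IHPYW": 6, "AAAAA": 4})
        freqs = position_frequencies(counts)
        enr = enrichment_vs_input(freqs, freqs, pseudocount=0.5)
        assert np.allclose(enr.folds.to_numpy(), 1.0)

    def test_forced_arithmetic(self):
        bin_freqs = position_frequencies(
            PeptideCounts("b", {"IAAAA": 2, "GAAAA": 8})
        )
        input_freqs = position_frequencies(
            PeptideCounts("i", {"IAAAA": 1, "GAAAA": 9})
        )
        enr = enrichment_vs_input(bin_freqs, input_freqs, pseudocount=0.0)
        assert enr.folds.loc["I", "P1"] == pytest.approx(2.0)

    def test_shape_mismatch_rejected(self):
        a = position_frequencies(PeptideCounts("a", {"IHPYW": 1}))
        b = position_frequencies(PeptideCounts("b", {"IH": 1}))
        with pytest.raises(ConfigurationError):
            enrichment_vs_input(a, b)

    def test_zero_input_cell_needs_pseudocount(self):
        bin_freqs = position_frequencies(PeptideCounts("b", {"IHPYW": 1}))
        input_freqs = position_frequencies(PeptideCounts("i", {"AAAAA": 1}))
        with pytest.raises(ConfigurationError):
            enrichment_vs_input(bin_freqs, input_freqs, pseudocount=0.0)
        enr = enrichment_vs_input(bin_freqs, input_freqs, pseudocount=0.5)
        assert np.isfinite(enr.folds.to_numpy()).all()


class TestRankCandidates:
    def test_single_enriched_peptide_ranks_first(self, nnn_null):
        counts = PeptideCounts(
            "b", {"IHPYW": 50, "AAAAA": 50, "GGGGG": 50}
        )
        # bin heavily enriched for IHPYW's residues
        bin_counts = PeptideCounts("b", {"IHPYW": 900, "AAAAA": 50,
                                         "GGGGG": 50})
        enr = enrichment_vs_null(
            position_frequencies(bin_counts), nnn_null, pseudocount=0.5
        )
        ranked = rank_candidates(counts, enr, top_k=3)
        assert ranked.peptide.iloc[0] == "IHPYW"

    def test_neutral_folds_reduce_to_count_order(self):
        counts = PeptideCounts("b", {"CCCCC": 7, "AAAAA": 9, "DDDDD": 7})
        folds = pd.DataFrame(
            1.0, index=AA_ORDER, columns=[f"P{i}" for i in range(1, 6)]
        )
        from degronscreen.enrichment import EnrichmentMatrix
        enr = EnrichmentMatrix(folds=folds, reference="codon_null",
                               pseudocount=0.5)
        ranked = rank_candidates(counts, enr, top_k=3)
        assert list(ranked.peptide) == ["AAAAA", "CCCCC", "DDDDD"]

    def test_score_is_sum_of_log_folds(self, nnn_null):
        counts = PeptideCounts("b", {"IHPYW": 3})
        freqs = position_frequencies(
            PeptideCounts("b", {"IHPYW": 5, "AAAAA": 5})
        )
        enr = enrichment_vs_null(freqs, nnn_null, pseudocount=0.5)
        ranked = rank_candidates(counts, enr, top_k=1)
        expected = sum(
            np.log(enr.folds.loc[aa, f"P{p}"])
            for p, aa in enumerate("IHPYW", start=1)
        )
        assert ranked.score.iloc[0] == pytest.approx(expected, rel=1e-12)


class TestHeatmapExport:
    def test_identity_folds_give_all_zero_log2_tsv(self, tmp_path):
        from degronscreen.enrichment import EnrichmentMatrix
        folds = pd.DataFrame(
            1.0, index=AA_ORDER, columns=[f"P{i}" for i in range(1, 6)]
        )
        enr = EnrichmentMatrix(folds=folds, reference="codon_null",
                               pseudocount=0.5)
        path = tmp_path / "h.tsv"
        export_heatmap(enr, path)
        values = pd.read_csv(path, sep="\t", index_col=0)
        assert (values.to_numpy() == 0).all()
        assert values.shape == (20, 5)

    def test_tsv_roundtrip(self, tmp_path, nnn_null):
        counts = PeptideCounts("b", {"IHPYW": 9, "LAAAA": 4, "WCKYM": 2})
        enr = enrichment_vs_null(
            position_frequencies(counts), nnn_null, pseudocount=0.5
        )
        path = tmp_path / "h.tsv"
        export_heatmap(enr, path)
        back = read_heatmap_tsv(path)
        assert np.allclose(back.to_numpy(), enr.folds.to_numpy(), rtol=1e-9)

    def test_figure_rendering(self, tmp_path, nnn_null):
        counts = PeptideCounts("b", {"IHPYW": 9, "LAAAA": 4})
        enr = enrichment_vs_null(
            position_frequencies(counts), nnn_null, pseudocount=0.0
        )
        tsv, png = tmp_path / "h.tsv", tmp_path / "h.png"
        export_heatmap(enr, tsv, png)
        assert png.stat().st_size > 0
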