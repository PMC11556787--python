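"""Simulator ground truth: library sampling, tFT readout, sorting, reads."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from degronscreen.codons import DegenerateCodonScheme, translate_dna
from degronscreen.errors import ConfigurationError, InsufficientDataError
from degronscreen.simulate import (
    ReadSimConfig,
    SortConfig,
    StabilityRule,
    TFTParameters,
    emit_amplicon_reads,
    sample_library,
    simulate_cells,
    sort_unstable_bin,
    tft_ratio,
)


class TestSampleLibrary:
    def test_peptides_match_translation(self, small_library):
        for v in small_library[:50]:
            assert v.peptide == translate_dna(v.dna_insert)

    def test_abundances_normalized(self, small_library):
        assert abs(small_library.input_abundance.sum() - 1.0) < 1e-9

    def test_neutral_rule_gives_uniform_rates(self):
        lib = sample_library(
            500, rule=StabilityRule(base_rate=0.01, stop_rate=0.01), seed=1
        )
        assert np.allclose(lib.k_deg, 0.01)

    def test_determinism(self):
        a = sample_library(300, seed=9)
        b = sample_library(300, seed=9)
        assert a.dna_inserts == b.dna_inserts
        assert np.array_equal(a.input_abundance, b.input_abundance)

    @pytest.mark.parametrize(
        "name,n_pos,ile_codons", [("NNN", 2, 3), ("NNK", 1, 1)]
    )
    def test_exhaustive_mode_hits_null_frequencies_exactly(
        self, name, n_pos, ile_codons
    ):
        """Exhaustive enumeration: every codon combination appears once,
        so per-position AA frequencies equal the codon-count null exactly
        (Ile: 3/64 under NNN, 1/32 under NNK where only ATT encodes it)."""
        scheme = DegenerateCodonScheme.from_name(name, n_pos)
        lib = sample_library(1, scheme, exhaustive=True, seed=0)
        assert len(lib) == scheme.codons_per_position ** n_pos
        for pos in range(n_pos):
            ile = sum(1 for p in lib.peptides if p[pos] == "I")
            assert ile / len(lib) == ile_codons / scheme.codons_per_position

    def test_exhaustive_guard(self):
        with pytest.raises(ConfigurationError):
            sample_library(
                1, DegenerateCodonScheme.from_name("NNN", 5),
                exhaustive=True,
            )

    def test_planted_rule_multiplies_rates(self):
        rule = StabilityRule.ile_leu_p1(fold=8.0, base_rate=0.01)
        lib = sample_library(2000, rule=rule, seed=3)
        for v in lib[:500]:
            if "*" in v.peptide:
                assert v.k_deg == rule.stop_rate
            elif v.peptide[0] in "IL":
                assert v.k_deg == pytest.approx(0.08)
            else:
                assert v.k_deg == pytest.approx(0.01)


class TestTftRatio:
    def test_normalized_at_zero(self):
        assert tft_ratio(0.0, TFTParameters()) == pytest.approx(1.0)

    def test_limit_at_large_k(self):
        p = TFTParameters()
        assert tft_ratio(1e9, p) == pytest.approx(
            p.m_cherry / p.m_gfp, rel=1e-6
        )

    def test_closed_form_value(self):
        """Oracle: evaluate R(k) = m_c(m_g+k) / (m_g(m_c+k)) by hand."""
        p = TFTParameters(m_cherry=0.01, m_gfp=0.1)
        k = np.log(2) / 30
        expected = (0.01 * (0.1 + k)) / (0.1 * (0.01 + k))
        assert tft_ratio(k, p) == pytest.approx(expected, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            tft_ratio(-0.1, TFTParameters())

    @given(
        mc=st.floats(1e-4, 1.0),
        ratio=st.floats(1.01, 100.0),
        k1=st.floats(0.0, 10.0),
        dk=st.floats(1e-6, 10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_decreasing_in_k(self, mc, ratio, k1, dk):
        """The timer ratio falls monotonically with degradation rate
        whenever mCherry matures slower than GFP."""
        p = TFTParameters(m_cherry=mc, m_gfp=mc * ratio)
        assert tft_ratio(k1 + dk, p) < tft_ratio(k1, p)

    def test_slow_cherry_enforced(self):
        with pytest.raises(ConfigurationError):
            TFTParameters(m_cherry=0.2, m_gfp=0.1)


class TestSimulateCells:
    def test_zero_noise_neutral_rule_collapses_ratio(self):
        lib = sample_library(
            200, rule=StabilityRule(base_rate=0.01, stop_rate=0.01), seed=5
        )
        params = TFTParameters(cell_noise_cv=0.0)
        cells = simulate_cells(lib, params, SortConfig(n_cells=2000, seed=1))
        gated = cells[cells.gated]
        assert gated.log_ratio.nunique() == 1

    def test_gated_count_within_binomial_interval(self, small_library):
        """Oracle: gate survival is Bernoulli(0.5) per cell at
        dead_fraction 0.5, nonfluorescent 0."""
        params = TFTParameters(dead_fraction=0.5,
                               nonfluorescent_fraction=0.0)
        n = 100_000
        cells = simulate_cells(
            small_library, params, SortConfig(n_cells=n, seed=2)
        )
        lo, hi = stats.binom.interval(0.99, n, 0.5)
        assert lo <= cells.gated.sum() <= hi

    def test_determinism(self, small_library):
        params = TFTParameters()
        sort = SortConfig(n_cells=5000, seed=77)
        a = simulate_cells(small_library, params, sort)
        b = simulate_cells(small_library, params, sort)
        assert a.equals(b)


class TestSortUnstableBin:
    def test_bin_size_is_quantile_arithmetic(self, small_library):
        cells = simulate_cells(
            small_library, TFTParameters(dead_fraction=0.0,
                                         nonfluorescent_fraction=0.0),
            SortConfig(n_cells=10_000, seed=3),
        )
        bin_counts, pool_counts = sort_unstable_bin(
            cells, SortConfig(unstable_bin_fraction=0.04, n_cells=10_000)
        )
        assert bin_counts.sum() == 400
        assert pool_counts.sum() == 10_000

    def test_noiseless_hard_threshold_bin_is_pure(self):
        """Oracle: with zero noise and only Ile-P1 peptides destabilized,
        a bin cut at exactly that class's prevalence contains only it."""
        rule = StabilityRule(
            base_rate=0.005, stop_rate=0.005,
            position_effects={(1, "I"): 20.0},
        )
        lib = sample_library(3000, rule=rule, seed=8)
        cells = simulate_cells(
            lib, TFTParameters(cell_noise_cv=0.0, dead_fraction=0.0,
                               nonfluorescent_fraction=0.0),
            SortConfig(n_cells=50_000, seed=4),
        )
        # the destabilized class: Ile at P1 and no stop (stop-containing
        # peptides take stop_rate, equal to base_rate here)
        destab = np.array(
            [p[0] == "I" and "*" not in p for p in lib.peptides]
        )
        prevalence = destab[cells.variant_id].mean()
        bin_counts, _ = sort_unstable_bin(
            cells, SortConfig(unstable_bin_fraction=prevalence,
                              n_cells=50_000)
        )
        assert all(destab[v] for v in bin_counts.index)

    def test_bin_mean_below_complement_mean(self, small_library):
        cells = simulate_cells(
            small_library, TFTParameters(), SortConfig(n_cells=8000, seed=6)
        )
        gated = cells[cells.gated]
        thr = gated.log_ratio.quantile(0.5)
        low, high = gated[gated.log_ratio <= thr], gated[gated.log_ratio > thr]
        assert low.log_ratio.mean() < high.log_ratio.mean()

    def test_too_few_cells_rejected(self, small_library):
        cells = simulate_cells(
            small_library, TFTParameters(), SortConfig(n_cells=10, seed=1)
        )
        with pytest.raises(InsufficientDataError):
            sort_unstable_bin(
                cells, SortConfig(unstable_bin_fraction=0.01, n_cells=10)
            )


class TestEmitReads:
    def test_noiseless_reads_translate_to_truth(self, small_library, tmp_path):
        multiset = {0: 5, 1: 3}
        cfg = ReadSimConfig(reads_per_sample=50,
                            substitution_error_rate=0.0, seed=1)
        fq, truth = tmp_path / "r.fastq", tmp_path / "t.tsv"
        emit_amplicon_reads(multiset, small_library, cfg, fq, truth)
        lines = fq.read_text().splitlines()
        assert len(lines) == 200
        truth_map = dict(
            row.split("\t") for row in truth.read_text().splitlines()[1:]
        )
        up = len(cfg.upstream_flank)
        for i in range(0, 200, 4):
            rid, seq = lines[i][1:], lines[i + 1]
            assert len(seq) == 217
            vid = int(truth_map[rid])
            assert translate_dna(seq[up : up + 15]) == (
                small_library.peptides[vid]
            )

    def test_error_rate_matches_binomial_expectation(self, small_library,
                                                     tmp_path):
        """Oracle: mean mutated bases per 217-bp read = 217 * e."""
        cfg = ReadSimConfig(reads_per_sample=2000,
                            substitution_error_rate=0.01, seed=2)
        fq = tmp_path / "e.fastq"
        emit_amplicon_reads({0: 1}, small_library, cfg, fq)
        clean = (
            cfg.upstream_flank + small_library.dna_inserts[0]
            + cfg.downstream_flank
        )
        lines = fq.read_text().splitlines()
        diffs = [
            sum(a != b for a, b in zip(lines[i + 1], clean))
            for i in range(0, len(lines), 4)
        ]
        n_bases = 2000 * 217
        lo, hi = stats.binom.interval(0.999, n_bases, 0.01)
        assert lo <= sum(diffs) <= hi

    def test_empty_multiset_writes_empty_fastq(self, small_library, tmp_path):
        fq = tmp_path / "empty.fastq"
        with pytest.warns(UserWarning):
            emit_amplicon_reads({}, small_library,
                                ReadSimConfig(reads_per_sample=10), fq)
        assert fq.read_text() == ""

    def test_determinism(self, small_library, tmp_path):
        cfg = ReadSimConfig(reads_per_sample=100, seed=5)
        a, b = tmp_path / "a.fastq", tmp_path / "b.fastq"
        emit_amplicon_reads({0: 1, 2: 4}, small_library, cfg, a)
        emit_amplicon_reads({0: 1, 2: 4}, small_library, cfg, b)
        assert a.read_bytes() == b.read_bytes()


class TestConfigValidation:
    def test_flank_geometry_enforced(self):
        with pytest.raises(ConfigurationError):
            ReadSimConfig(upstream_flank="ACGT", downstream_flank="ACGT",
                          amplicon_length=217)

    def test_bin_fraction_bounds(self):
        with pytest.raises(ConfigurationError):
            SortConfig(unstable_bin_fraction=1.5)

    def test_rule_factors_positive(self):
        with pytest.raises(ConfigurationError):
            StabilityRule(position_effects={(1, "I"): -2.0})
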