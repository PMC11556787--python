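"""Canned study-scale experiments: planted-rule recovery and half-life
recovery.

These functions run the full pipeline on simulator output at the scale the
screen operates (hundreds of thousands of variants and reads) and quantify
how well the enrichment analysis recovers the planted ground truth.  They
are shared by the analysis drivers, the acceptance checks, and anyone who
wants a one-call benchmark of the method.
"""

from __future__ import annotations

import math
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import extract as ext
from . import simulate as sim
from .codons import DegenerateCodonScheme, position_null_distribution
from .kinetics import ChaseSeries, fit_decay_halflife

AA_P1 = ["I", "L"]


def _cells_to_counts(
    multiset: pd.Series, library: sim.Library, label: str
) -> Tuple[ext.PeptideCounts, Dict[str, int]]:
    """Cell-level peptide tallies for a sorted multiset (no sequencing)."""
    counts: Dict[str, int] = {}
    stops: Dict[str, int] = {}
    for vid, n in multiset.items():
        pep = library.peptides[vid]
        target = stops if "*" in pep else counts
        target[pep] = target.get(pep, 0) + int(n)
    return ext.PeptideCounts(sample_label=label, counts=counts), stops


@dataclass
class RecoveryResult:
    """Outcome of one planted-rule recovery run."""

    fold_vs_input: pd.DataFrame          # 20 x 5, read-level pipeline folds
    fold_vs_null: pd.DataFrame
    ci_low: Dict[str, float]             # 95% bootstrap CI for P1 I/L folds
    ci_high: Dict[str, float]
    offposition_max_abs_z: float         # positions 2-5, vs input, z-scores
    offposition_max_abs_log2: float
    n_valid_bin_reads: int
    n_valid_input_reads: int
    n_bin_cells_nonstop: int
    seed: int


def planted_rule_recovery(
    seed: int,
    n_variants: int = 200_000,
    n_cells: int = 600_000,
    reads_per_sample: int = 500_000,
    planted_fold: float = 8.0,
    bin_fraction: float = 0.04,
    noise_cv: float = 0.3,
    n_bootstrap: int = 200,
    workdir: str | Path | None = None,
) -> RecoveryResult:
    """Simulate the screen with Ile/Leu-at-P1 planted 8x destabilization,
    run extraction + enrichment on the emitted FASTQ, and quantify
    recovery.

    Bootstrap CIs for the P1 Ile/Leu input-relative folds resample the
    read-level peptide counts of both samples (multinomial).  The
    off-position z-scores compare each position-2..5 log fold against the
    sampling noise expected from the number of independent cells and reads
    behind each sample — under a P1-only selection rule those folds should
    be noise around 1.
    """
    seed = int(seed) % 2**31
    rule = sim.StabilityRule.ile_leu_p1(fold=planted_fold)
    tft = sim.TFTParameters(cell_noise_cv=noise_cv)
    sort = sim.SortConfig(
        unstable_bin_fraction=bin_fraction, n_cells=n_cells,
        seed=(seed * 7 + 1) % 2**31,
    )
    library = sim.sample_library(n_variants, rule=rule, seed=seed)
    cells = sim.simulate_cells(library, tft, sort)
    bin_cells, pool_cells = sim.sort_unstable_bin(cells, sort)

    def _extract(multiset: pd.Series, label: str, sub_seed: int):
        cfg = sim.ReadSimConfig(
            reads_per_sample=reads_per_sample, seed=sub_seed
        )
        fq = Path(tmp) / f"{label}.fastq"
        sim.emit_amplicon_reads(multiset, library, cfg, fq)
        counts, _, report = ext.extract_and_classify(fq)
        counts.sample_label = label
        return counts, report

    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        bin_counts, bin_report = _extract(
            bin_cells, "bin", (seed * 7 + 2) % 2**31
        )
        input_counts, input_report = _extract(
            pool_cells, "input", (seed * 7 + 3) % 2**31
        )

    bin_freqs = enr.position_frequencies(bin_counts)
    input_freqs = enr.position_frequencies(input_counts)
    null = position_null_distribution(DegenerateCodonScheme.from_name("NNN"))
    vs_input = enr.enrichment_vs_input(bin_freqs, input_freqs, 0.5)
    vs_null = enr.enrichment_vs_null(
        bin_freqs, null.sense_renormalized(), 0.0
    )

    ci_low, ci_high = _bootstrap_p1_fold_ci(
        bin_counts, input_counts, n_bootstrap,
        np.random.default_rng((seed * 7 + 4) % 2**31),
    )

    # effective sample sizes: sorted cells are the independent units;
    # reads resample them, adding a second (smaller) multinomial layer
    bin_cell_counts, _ = _cells_to_counts(bin_cells, library, "bin_cells")
    pool_cell_counts, _ = _cells_to_counts(pool_cells, library, "pool_cells")
    nb_c, ni_c = bin_cell_counts.total(), pool_cell_counts.total()
    nb_r, ni_r = bin_counts.total(), input_counts.total()

    off_cols = [c for c in vs_input.folds.columns if c != "P1"]
    pb = bin_freqs.freqs[off_cols].to_numpy()
    pi = input_freqs.freqs[off_cols].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        var_log = (
            (1 - pb) / np.maximum(pb, 1e-12) * (1 / nb_c + 1 / nb_r)
            + (1 - pi) / np.maximum(pi, 1e-12) * (1 / ni_c + 1 / ni_r)
        )
        log_fold = np.log(vs_input.folds[off_cols].to_numpy())
        z = log_fold / np.sqrt(var_log)
    observed = (pb > 0) | (pi > 0)
    max_z = float(np.nanmax(np.abs(z[observed])))
    max_log2 = float(np.nanmax(np.abs(np.log2(
        vs_input.folds[off_cols].to_numpy()[observed]
    ))))

    return RecoveryResult(
        fold_vs_input=vs_input.folds,
        fold_vs_null=vs_null.folds,
        ci_low=ci_low,
        ci_high=ci_high,
        offposition_max_abs_z=max_z,
        offposition_max_abs_log2=max_log2,
        n_valid_bin_reads=nb_r,
        n_valid_input_reads=ni_r,
        n_bin_cells_nonstop=nb_c,
        seed=seed,
    )


def _bootstrap_p1_fold_ci(
    bin_counts: ext.PeptideCounts,
    input_counts: ext.PeptideCounts,
    n_bootstrap: int,
    rng: np.random.Generator,
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """95% percentile CI for the P1 Ile/Leu input-relative folds by
    multinomial resampling of both samples' read counts."""
    def p1_vector(counts: ext.PeptideCounts) -> np.ndarray:
        # per-peptide indicator of I/L at position 1
        out = np.zeros((len(counts.counts), 3))
        for i, (pep, n) in enumerate(counts.counts.items()):
            out[i] = (n, pep[0] == "I", pep[0] == "L")
        return out

    vb, vi = p1_vector(bin_counts), p1_vector(input_counts)
    nb, ni = int(vb[:, 0].sum()), int(vi[:, 0].sum())
    stats = {aa: [] for aa in AA_P1}
    for _ in range(n_bootstrap):
        wb = rng.multinomial(nb, vb[:, 0] / nb)
        wi = rng.multinomial(ni, vi[:, 0] / ni)
        for j, aa in enumerate(AA_P1, start=1):
            fb = (wb @ vb[:, j] + 0.5) / (nb + 10)
            fi = (wi @ vi[:, j] + 0.5) / (ni + 10)
            stats[aa].append(fb / fi)
    ci_low = {aa: float(np.percentile(stats[aa], 2.5)) for aa in AA_P1}
    ci_high = {aa: float(np.percentile(stats[aa], 97.5)) for aa in AA_P1}
    return ci_low, ci_high


@dataclass
class SelectionOracleResult:
    """Hard-threshold selection vs the analytic class-probability oracle."""

    fold_estimates: Dict[str, float]     # pipeline estimate, (aa, P1)
    fold_analytic: Dict[str, float]
    z_scores: Dict[str, float]
    n_bin_cells: int


def hard_threshold_selection_oracle(
    seed: int,
    n_variants: int = 100_000,
    n_cells: int = 400_000,
) -> SelectionOracleResult:
    """Noise-free selection against the analytic P(aa|selected)/P(aa).

    With zero cell noise and a rule destabilizing only Ile/Leu at P1, a
    bin cut at exactly that class's prevalence selects the class and
    nothing else.  The analytic input-relative fold is then, for Ile at
    P1, [q_I/(q_I+q_L)] / [q_I/(1-q_*)] = (1-q_*)/(q_I+q_L) = 61/9 under
    NNN (and identically for Leu); off-positions have fold 1.  The
    pipeline's cell-level estimate must match within binomial noise from
    the finite library and cell sample.
    """
    seed = int(seed) % 2**31
    rule = sim.StabilityRule(
        base_rate=0.008, stop_rate=0.06,
        position_effects={(1, "I"): 8.0, (1, "L"): 8.0},
    )
    library = sim.sample_library(
        n_variants, rule=rule, seed=seed, abundance_model="uniform"
    )
    tft = sim.TFTParameters(
        cell_noise_cv=0.0, dead_fraction=0.0, nonfluorescent_fraction=0.0
    )
    destab = np.array(
        [p[0] in "IL" and "*" not in p for p in library.peptides]
    )
    sort = sim.SortConfig(
        unstable_bin_fraction=0.5, n_cells=n_cells, seed=(seed + 9) % 2**31
    )
    cells = sim.simulate_cells(library, tft, sort)
    prevalence = destab[cells.variant_id].mean()
    bin_cells, pool_cells = sim.sort_unstable_bin(
        cells, replace(sort, unstable_bin_fraction=float(prevalence))
    )
    bin_counts, _ = _cells_to_counts(bin_cells, library, "bin")
    pool_counts, _ = _cells_to_counts(pool_cells, library, "input")
    vs_input = enr.enrichment_vs_input(
        enr.position_frequencies(bin_counts),
        enr.position_frequencies(pool_counts),
        pseudocount=0.0,
    )

    analytic = 61.0 / 9.0
    nb = bin_counts.total()
    n_lib_destab = int(
        sum("*" not in p and p[0] in "IL" for p in library.peptides)
    )
    estimates, zs = {}, {}
    bin_f = enr.position_frequencies(bin_counts).freqs
    pool_f = enr.position_frequencies(pool_counts).freqs
    for aa in AA_P1:
        est = float(vs_input.folds.loc[aa, "P1"])
        pb, pi = float(bin_f.loc[aa, "P1"]), float(pool_f.loc[aa, "P1"])
        # library sampling + cell sampling, bin and pool sides
        var_log = (
            (1 - pb) / pb * (1 / n_lib_destab + 1 / nb)
            + (1 - pi) / pi / pool_counts.total()
        )
        zs[aa] = float((math.log(est) - math.log(analytic))
                       / math.sqrt(var_log))
        estimates[aa] = est
    return SelectionOracleResult(
        fold_estimates=estimates,
        fold_analytic={aa: analytic for aa in AA_P1},
        z_scores=zs,
        n_bin_cells=nb,
    )


def halflife_recovery(
    seed: int,
    true_halflife_min: float = 30.0,
    noise_cv: float = 0.10,
    n_replicates: int = 200,
) -> Tuple[float, float]:
    """(exact-series half-life, median noisy-recovery half-life).

    The exact series halves every 30 min over 0/30/60/90; the noisy
    series multiply each intensity by lognormal noise of the given CV.
    """
    t = np.array([0.0, 30.0, 60.0, 90.0])
    exact = fit_decay_halflife(
        ChaseSeries("exact", t, [100.0, 50.0, 25.0, 12.5])
    ).half_life

    rng = np.random.default_rng(int(seed) % 2**31)
    k = math.log(2) / true_halflife_min
    halves = []
    for _ in range(n_replicates):
        y = np.exp(-k * t) * np.exp(rng.normal(0.0, noise_cv, len(t)))
        halves.append(
            fit_decay_halflife(ChaseSeries("noisy", t, y)).half_life
        )
    return float(exact), float(np.median(halves))
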