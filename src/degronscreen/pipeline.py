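"""Pipeline orchestration: simulate -> extract -> enrich -> report.

One YAML config drives every stage; all randomness fans out from a single
top-level seed (stage seeds are derived deterministically), every stage
writes a manifest entry, and reruns with the same config+seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import enrichment as enr_mod
from . import extract as ext_mod
from . import kinetics as kin_mod
from . import simulate as sim_mod
from .codons import DegenerateCodonScheme, position_null_distribution
from .errors import ConfigurationError, ParseError

logger = logging.getLogger(__name__)

# exit codes for the CLI: validation / data / IO problems
EXIT_VALIDATION, EXIT_DATA, EXIT_IO = 2, 3, 4


@dataclass(frozen=True)
class EnrichmentOptions:
    pseudocount_vs_input: float = 0.5
    pseudocount_vs_null: float = 0.0
    top_k_candidates: int = 20
    include_stops: bool = False


@dataclass
class PipelineConfig:
    """All stage configs plus output directory and the master seed."""

    scheme_name: str = "NNN"
    #: optional explicit per-codon-position alphabets, e.g. ["ACGT",
    #: "ACGT", "GT"]; overrides the IUPAC name when set
    scheme_alphabets: Optional[Tuple[str, str, str]] = None
    num_codon_positions: int = 5
    n_variants: int = 50_000
    abundance_model: str = "lognormal"
    abundance_sigma: float = 1.0
    rule: sim_mod.StabilityRule = field(
        default_factory=sim_mod.StabilityRule.ile_leu_p1
    )
    tft: sim_mod.TFTParameters = field(default_factory=sim_mod.TFTParameters)
    sort: sim_mod.SortConfig = field(default_factory=sim_mod.SortConfig)
    reads: sim_mod.ReadSimConfig = field(
        default_factory=sim_mod.ReadSimConfig
    )
    layout: ext_mod.AmpliconLayout = field(
        default_factory=ext_mod.AmpliconLayout
    )
    enrich: EnrichmentOptions = field(default_factory=EnrichmentOptions)
    outdir: str = "results"
    seed: int = 0

    def scheme(self) -> DegenerateCodonScheme:
        if self.scheme_alphabets is not None:
            return DegenerateCodonScheme(
                name=self.scheme_name,
                position_alphabets=tuple(
                    frozenset(a) for a in self.scheme_alphabets
                ),
                num_codon_positions=self.num_codon_positions,
            )
        return DegenerateCodonScheme.from_name(
            self.scheme_name, self.num_codon_positions
        )

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Fan the master seed out to the per-stage configs."""
        cfg = replace(
            self,
            seed=seed,
            sort=replace(self.sort, seed=(seed * 1_000_003 + 1) % 2**31),
            reads=replace(self.reads, seed=(seed * 1_000_003 + 2) % 2**31),
        )
        return cfg

    def to_dict(self) -> Dict:
        d = asdict(self)
        # dict keys of position/motif effects must be JSON-serializable
        d["rule"]["position_effects"] = {
            f"{pos}:{aa}": v
            for (pos, aa), v in self.rule.position_effects.items()
        }
        d["layout"] = asdict(self.layout)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Dict) -> "PipelineConfig":
        try:
            kwargs: Dict = {}
            for key in (
                "scheme_name", "num_codon_positions", "n_variants",
                "abundance_model", "abundance_sigma", "outdir", "seed",
            ):
                if key in raw:
                    kwargs[key] = raw[key]
            if raw.get("scheme_alphabets") is not None:
                kwargs["scheme_alphabets"] = tuple(raw["scheme_alphabets"])
            if "rule" in raw:
                r = dict(raw["rule"])
                pos_eff = {}
                for k, v in r.pop("position_effects", {}).items():
                    pos_s, aa = str(k).split(":")
                    pos_eff[(int(pos_s), aa)] = float(v)
                kwargs["rule"] = sim_mod.StabilityRule(
                    position_effects=pos_eff, **r
                )
            if "tft" in raw:
                kwargs["tft"] = sim_mod.TFTParameters(**raw["tft"])
            if "sort" in raw:
                kwargs["sort"] = sim_mod.SortConfig(**raw["sort"])
            if "reads" in raw:
                kwargs["reads"] = sim_mod.ReadSimConfig(**raw["reads"])
            if "layout" in raw:
                kwargs["layout"] = ext_mod.AmpliconLayout(**raw["layout"])
            if "enrich" in raw:
                kwargs["enrich"] = EnrichmentOptions(**raw["enrich"])
            return cls(**kwargs)
        except (TypeError, ValueError, KeyError) as exc:
            raise ConfigurationError(f"invalid pipeline config: {exc}") from exc


def _log_stage(outdir: Path, stage: str, seed: int, t0: float,
               extra: Optional[Dict] = None) -> None:
    entry = {
        "stage": stage, "seed": seed,
        "wall_time_s": round(time.monotonic() - t0, 3),
    }
    if extra:
        entry.update(extra)
    with open(outdir / "pipeline.log.jsonl", "a") as fh:
        fh.write(json.dumps(entry) + "\n")
    logger.info("stage %s finished in %.1fs", stage, entry["wall_time_s"])


def _update_manifest(outdir: Path, config: PipelineConfig,
                     files: Dict[str, str]) -> None:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "config_hash": config.config_hash(), "seed": config.seed,
        "files": {},
    }
    manifest["config_hash"] = config.config_hash()
    manifest["seed"] = config.seed
    manifest["files"].update(files)
    path.write_text(json.dumps(manifest, indent=2) + "\n")


def run_simulate(config: PipelineConfig) -> Dict[str, str]:
    """Simulate the screen: library, cells, sort, and FASTQ for both samples."""
    t0 = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.with_seed(config.seed)

    library = sim_mod.sample_library(
        cfg.n_variants, cfg.scheme(), cfg.rule, seed=cfg.seed,
        abundance_model=cfg.abundance_model,
        abundance_sigma=cfg.abundance_sigma,
    )
    cells = sim_mod.simulate_cells(library, cfg.tft, cfg.sort)
    bin_counts, pool_counts = sim_mod.sort_unstable_bin(cells, cfg.sort)

    files = {}
    lib_path = outdir / "library_truth.tsv"
    library.to_frame().to_csv(lib_path, sep="\t", index=False)
    files["library_truth"] = lib_path.name

    for label, counts in (("input", pool_counts), ("bin", bin_counts)):
        fq = outdir / f"{label}.fastq"
        truth = outdir / f"{label}.truth.tsv"
        reads_cfg = sim_mod.ReadSimConfig(
            **{**asdict(cfg.reads),
               "seed": (cfg.reads.seed + (0 if label == "input" else 1))
               % 2**31}
        )
        sim_mod.emit_amplicon_reads(counts, library, reads_cfg, fq, truth)
        files[f"{label}_fastq"] = fq.name
        files[f"{label}_truth"] = truth.name

    _update_manifest(outdir, cfg, files)
    _log_stage(outdir, "simulate", cfg.seed, t0,
               {"n_variants": len(library), "n_cells": cfg.sort.n_cells})
    return files


def run_extract(
    config: PipelineConfig, fastq_paths: Dict[str, str | Path]
) -> Dict[str, str]:
    """Extract pentapeptide counts from each sample's FASTQ."""
    t0 = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for label, fq in fastq_paths.items():
        fq = Path(fq)
        if not fq.exists():
            raise FileNotFoundError(f"FASTQ not found: {fq}")
        counts, stops, report = ext_mod.extract_and_classify(
            fq, config.layout
        )
        counts.sample_label = label
        cpath = outdir / f"{label}.counts.tsv"
        spath = outdir / f"{label}.stop_counts.tsv"
        ext_mod.write_counts(counts, cpath)
        ext_mod.write_counts(stops, spath)
        with open(outdir / "extraction_reports.jsonl", "a") as fh:
            fh.write(json.dumps({"sample": label, **report.__dict__}) + "\n")
        files[f"{label}_counts"] = cpath.name
        files[f"{label}_stop_counts"] = spath.name
    _update_manifest(outdir, config, files)
    _log_stage(outdir, "extract", config.seed, t0)
    return files


def run_enrich(
    config: PipelineConfig,
    counts_paths: Dict[str, str | Path],
) -> Dict[str, str]:
    """Frequencies, both enrichment panels, candidates, and the heatmaps."""
    t0 = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if "input" not in counts_paths or "bin" not in counts_paths:
        raise ConfigurationError(
            "enrichment needs both 'input' and 'bin' counts tables"
        )
    bin_counts = ext_mod.read_counts(counts_paths["bin"], "bin")
    input_counts = ext_mod.read_counts(counts_paths["input"], "input")

    null = position_null_distribution(config.scheme())
    bin_freqs = enr_mod.position_frequencies(bin_counts)
    input_freqs = enr_mod.position_frequencies(input_counts)

    files = {}
    for label, freqs in (("bin", bin_freqs), ("input", input_freqs)):
        p = outdir / f"{label}.frequencies.tsv"
        freqs.freqs.to_csv(p, sep="\t", index_label="amino_acid")
        files[f"{label}_frequencies"] = p.name

    vs_null = enr_mod.enrichment_vs_null(
        bin_freqs, null, config.enrich.pseudocount_vs_null
    )
    vs_input = enr_mod.enrichment_vs_input(
        bin_freqs, input_freqs, config.enrich.pseudocount_vs_input
    )
    for tag, matrix in (("vs_codon_null", vs_null), ("vs_input", vs_input)):
        tsv = outdir / f"enrichment_{tag}.tsv"
        fig = outdir / f"enrichment_{tag}.png"
        enr_mod.export_heatmap(matrix, tsv, fig)
        files[f"enrichment_{tag}"] = tsv.name
        files[f"heatmap_{tag}"] = fig.name

    candidates = enr_mod.rank_candidates(
        bin_counts, vs_null, config.enrich.top_k_candidates
    )
    cpath = outdir / "candidates.tsv"
    candidates.to_csv(cpath, sep="\t", index=False)
    files["candidates"] = cpath.name

    _update_manifest(outdir, config, files)
    _log_stage(outdir, "enrich", config.seed, t0)
    return files


def run_kinetics(
    config: PipelineConfig, chase_tsv: str | Path
) -> Dict[str, str]:
    """Fit half-lives for a tidy chase table."""
    t0 = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(chase_tsv, sep="\t")
    fits = kin_mod.fit_many(kin_mod.chase_series_from_tidy(df))
    path = outdir / "halflife_fits.tsv"
    fits.to_csv(path, sep="\t", index=False)
    files = {"halflife_fits": path.name}
    _update_manifest(outdir, config, files)
    _log_stage(outdir, "kinetics", config.seed, t0)
    return files


def run_report(outdir: str | Path) -> Path:
    """Assemble a Markdown report from whatever stage outputs exist.

    Missing stages are listed as absent; the report is still produced and
    regeneration is idempotent.
    """
    outdir = Path(outdir)
    sections: List[str] = ["# Degron screen pipeline report\n"]
    missing: List[str] = []

    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        sections.append(
            f"Config hash `{manifest['config_hash']}`, seed "
            f"{manifest['seed']}.\n"
        )
    else:
        missing.append("manifest")

    reports_path = outdir / "extraction_reports.jsonl"
    if reports_path.exists():
        sections.append("## Extraction accounting\n")
        sections.append("| sample | reads | quality fail | anchor fail | "
                        "ambiguous | stop | valid |")
        sections.append("|---|---|---|---|---|---|---|")
        seen = {}
        for line in reports_path.read_text().splitlines():
            r = json.loads(line)
            seen[r["sample"]] = r    # idempotent: last entry per sample wins
        for r in seen.values():
            sections.append(
                f"| {r['sample']} | {r['n_reads']} | {r['n_quality_fail']} "
                f"| {r['n_anchor_fail']} | {r['n_ambiguous_base']} "
                f"| {r['n_stop_containing']} | {r['n_valid']} |"
            )
        sections.append("")
    else:
        missing.append("extraction")

    if (outdir / "enrichment_vs_codon_null.tsv").exists():
        sections.append("## Enrichment heatmaps\n")
        for tag in ("vs_codon_null", "vs_input"):
            if (outdir / f"enrichment_{tag}.png").exists():
                sections.append(f"![enrichment {tag}](enrichment_{tag}.png)")
        sections.append("")
    else:
        missing.append("enrichment")

    cpath = outdir / "candidates.tsv"
    if cpath.exists():
        sections.append("## Candidate pentapeptides (heuristic ranking)\n")
        sections.append("```")
        sections.append(cpath.read_text().strip())
        sections.append("```\n")
    else:
        missing.append("candidates")

    kpath = outdir / "halflife_fits.tsv"
    if kpath.exists():
        sections.append("## Half-life fits\n")
        sections.append("```")
        sections.append(kpath.read_text().strip())
        sections.append("```\n")
    else:
        missing.append("kinetics")

    truth_path = outdir / "library_truth.tsv"
    if truth_path.exists() and cpath.exists():
        sections.append("## Ground-truth recovery\n")
        truth = pd.read_csv(truth_path, sep="\t")
        cand = pd.read_csv(cpath, sep="\t")
        merged = cand.merge(
            truth.groupby("peptide")["k_deg"].mean().rename("true_k_deg"),
            left_on="peptide", right_index=True, how="left",
        )
        frac_unstable = (
            merged["true_k_deg"] > truth["k_deg"].median()
        ).mean()
        sections.append(
            f"{frac_unstable:.0%} of ranked candidates have above-median "
            "true degradation rates.\n"
        )

    if missing:
        sections.append(
            "## Missing stages\n\n" + ", ".join(missing) + "\n"
        )

    report_path = outdir / "report.md"
    report_path.write_text("\n".join(sections))
    return report_path


def run_all(config: PipelineConfig,
            chase_tsv: Optional[str | Path] = None) -> Path:
    outdir = Path(config.outdir)
    run_simulate(config)
    run_extract(config, {
        "input": outdir / "input.fastq", "bin": outdir / "bin.fastq",
    })
    run_enrich(config, {
        "input": outdir / "input.counts.tsv",
        "bin": outdir / "bin.counts.tsv",
    })
    if chase_tsv is not None:
        run_kinetics(config, chase_tsv)
    return run_report(outdir)
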