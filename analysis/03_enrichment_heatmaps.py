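#!/usr/bin/env python
"""Position-wise enrichment of the unstable bin, both reference panels.

Computes amino-acid frequencies per position for the bin and the input
pool, divides by the NNN codon null and by the input frequencies, renders
the two log2 heatmaps, ranks candidate pentapeptides, and assembles the
Markdown report.
"""

from pathlib import Path

import pandas as pd

from degronscreen.pipeline import PipelineConfig, run_enrich, run_report

cfg = PipelineConfig.from_yaml("configs/default.yaml")
cfg.outdir = "results/screen"
outdir = Path(cfg.outdir)
run_enrich(cfg, {"input": outdir / "input.counts.tsv",
                 "bin": outdir / "bin.counts.tsv"})

for tag in ("vs_codon_null", "vs_input"):
    log2 = pd.read_csv(outdir / f"enrichment_{tag}.tsv", sep="\t",
                       index_col=0)
    top = (2.0 ** log2["P1"]).nlargest(3)
    print(f"{tag}: top P1 folds " + ", ".join(
        f"{aa}={fold:.2f}" for aa, fold in top.items()
    ))
print("report:", run_report(outdir))
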