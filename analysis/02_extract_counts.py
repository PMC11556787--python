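#!/usr/bin/env python
"""Extract pentapeptide counts from the simulated amplicon FASTQ.

Reads are mean-quality filtered, anchored on the constant flanks, and the
15-nt variable region is translated; stop-containing peptides go to their
own table and the per-sample accounting is appended to
extraction_reports.jsonl.
"""

import json
from pathlib import Path

from degronscreen.pipeline import PipelineConfig, run_extract

cfg = PipelineConfig.from_yaml("configs/default.yaml")
cfg.outdir = "results/screen"
outdir = Path(cfg.outdir)
run_extract(cfg, {"input": outdir / "input.fastq",
                  "bin": outdir / "bin.fastq"})
for line in (outdir / "extraction_reports.jsonl").read_text().splitlines():
    r = json.loads(line)
    print(
        f"{r['sample']}: {r['n_valid']}/{r['n_reads']} valid reads, "
        f"{r['n_stop_containing']} stop-containing"
    )
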