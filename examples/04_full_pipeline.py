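"""One-command reproducible run: design -> codebook -> simulate ->
preprocess -> spots -> decode -> count, from a single config.

Outputs (probe TSV, codebook CSV, TIFF stacks, spot/call CSVs, the MTX
count matrix and a JSON manifest with per-stage hashes and timings) are
written under the configured output directory.
"""

import json
from pathlib import Path

import fishcoder as fc

cfg = fc.RunConfig(
    rng_seed=3,
    outdir="scratch/example_run",
    n_genes=10,
    codebook={"n_rounds": 6, "n_channels": 2},
    fieldspec={"height": 192, "width": 192, "n_cells": 6, "cell_radius_range": (8, 12)},
)
manifest = fc.run_pipeline(cfg)

for stage in manifest.stages:
    extra = {k: v for k, v in stage.items() if k not in ("stage", "seconds", "shifts")}
    print(f"{stage['stage']:>10}  {stage['seconds']:6.2f}s  {extra}")

metrics = json.loads((Path(cfg.outdir) / "decode_metrics.json").read_text())
print(f"\ndecode metrics vs simulated truth: recall {metrics['recall']:.3f}, "
      f"precision {metrics['precision']:.3f}, per-gene r {metrics['gene_correlation']:.3f}")
print(f"rerunning with the same config reproduces every output byte-for-byte "
      f"(config hash {manifest.config_hash}).")
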