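#!/usr/bin/env python
"""Per-metabolite bootstrap effect estimates (BCa intervals) and Mann-Whitney
tests for CD vs nonIBD and UC vs nonIBD, BH-adjusted within contrast.

Writes da_results.tsv and prints the number of significant
(metabolite, contrast) results at q <= 0.05.
"""

from pathlib import Path

from gutlink.pipeline import run_all, validate_config

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "pipeline"

if __name__ == "__main__":
    cfg = validate_config(None)
    manifest = run_all(cfg, OUTDIR, stages=["da"])
    s = manifest["stages"]["da"]
    print(f"differential abundance: {s['n_significant']} of {s['n_rows']} "
          "(metabolite, contrast) rows significant at q <= 0.05")
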