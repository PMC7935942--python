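#!/usr/bin/env python
"""Differential expression of biopsy counts under ~ diagnosis * is_ileum:
median-of-ratios normalization, per-gene negative-binomial Wald tests,
BH adjustment per contrast.

Writes de_results.tsv and the DEG-set summary (per contrast + intersection).
"""

import json
from pathlib import Path

from gutlink.pipeline import run_all, validate_config

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "pipeline"

if __name__ == "__main__":
    cfg = validate_config(None)
    run_all(cfg, OUTDIR, stages=["de"])
    summary = json.loads((OUTDIR / "de_summary.json").read_text())
    n = summary["n_deg"]
    print(
        f"DEGs: CD {n['CD_vs_nonIBD']}, UC {n['UC_vs_nonIBD']}, "
        f"shared {n['intersection']}, union {summary['n_union']}"
    )
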