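#!/usr/bin/env python
"""Fuse screened pairs with differential abundance, differential expression
and keyword-filtered genetic evidence into the final directed table with
co-directionality classes.

Writes linked_evidence.tsv, directed_pairs.tsv and the integration summary.
"""

import json
from pathlib import Path

from gutlink.pipeline import run_all, validate_config

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "pipeline"

if __name__ == "__main__":
    cfg = validate_config(None)
    run_all(cfg, OUTDIR, stages=["integrate"])
    summary = json.loads((OUTDIR / "integration_summary.json").read_text())
    print(
        f"integrated: {summary['total_unique_pairs']} unique pairs, "
        f"{summary['directed_pairs']} with known direction, "
        f"{summary['pairs_with_genetic_evidence']} with genetic evidence; "
        f"co-directionality classes: {summary['by_codirectionality']}"
    )
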