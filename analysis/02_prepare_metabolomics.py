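#!/usr/bin/env python
"""Normalize the per-method peak tables (participant filter, total sum
scaling, centered log-ratio transform, cross-method averaging, PCA outlier
removal) into one metabolite-by-sample matrix.

Reads the simulate-stage artifacts; writes abundance.tsv and the
preprocessing provenance record.
"""

from pathlib import Path

from gutlink.pipeline import run_all, validate_config

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "pipeline"

if __name__ == "__main__":
    cfg = validate_config(None)
    manifest = run_all(cfg, OUTDIR, stages=["prep"])
    import json

    prov = json.loads((OUTDIR / "prep_provenance.json").read_text())
    print(
        f"transformed matrix: {manifest['stages']['prep']['n_metabolites']} metabolites x "
        f"{manifest['stages']['prep']['n_samples']} samples "
        f"(PCA removed {len(prov['pca_removed_samples'])} outlier sample(s))"
    )
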