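#!/usr/bin/env python
"""Generate the synthetic IBD cohort: stool metabolomics over four LC/MS
methods, biopsy RNA-seq counts, a compound library with planted analogs, and
GWAS-like gene evidence — all with a known ground truth written alongside.

Writes results/pipeline/{peaks_*.tsv, samples.tsv, counts.tsv, ...,
ground_truth.json}.
"""

from pathlib import Path

from gutlink.pipeline import run_all, validate_config

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "pipeline"

if __name__ == "__main__":
    cfg = validate_config(None)
    manifest = run_all(cfg, OUTDIR, stages=["simulate"])
    counts = manifest["stages"]["simulate"]
    print(
        f"simulated {counts['n_samples']} stool samples across {counts['n_methods']} methods, "
        f"{counts['n_genes']} genes, {counts['n_compounds']} library compounds "
        f"-> {Path('results') / 'pipeline'}"
    )
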