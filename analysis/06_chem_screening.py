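#!/usr/bin/env python
"""Screen metabolite structures against the compound library (Tanimoto >=
0.85 or Tversky(alpha=0.05) >= 0.95 on 2048-bit path fingerprints), join
assay records (functional, pxC50 >= 5.5), and prune pleiotropic metabolites
and targets (degree >= 20).

Writes pairs.tsv and screening diagnostics.
"""

from pathlib import Path

from gutlink.pipeline import run_all, validate_config

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "pipeline"

if __name__ == "__main__":
    cfg = validate_config(None)
    manifest = run_all(cfg, OUTDIR, stages=["screen"])
    s = manifest["stages"]["screen"]
    print(f"screening: {s['n_hits']} similarity hits -> {s['n_pairs']} "
          "potency-filtered metabolite-target pairs")
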