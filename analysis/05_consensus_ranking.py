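#!/usr/bin/env python
"""Rank metabolites by the six-component consensus score: scaled Mann-Whitney
significance plus gain / split-count / SHAP attributions of the grid-tuned
XGBoost model and the mixed-effects XGBoost model; select the top quartile
per disease state.

Writes consensus.tsv and model_report.json (zoo F1 scores, chosen grid
point, random-intercept SD).
"""

import json
from pathlib import Path

from gutlink.pipeline import run_all, validate_config

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "pipeline"

if __name__ == "__main__":
    cfg = validate_config(None)
    manifest = run_all(cfg, OUTDIR, stages=["rank"])
    report = json.loads((OUTDIR / "model_report.json").read_text())
    best = max(report["zoo_weighted_f1"], key=report["zoo_weighted_f1"].get)
    print(
        f"best zoo model: {best} (weighted F1 {report['zoo_weighted_f1'][best]:.3f}); "
        f"grid choice {report['best_grid_point']}; "
        f"{manifest['stages']['rank']['n_candidates']} top-quartile (metabolite, state) rows"
    )
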