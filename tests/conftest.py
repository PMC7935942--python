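import json
from pathlib import Path

import pandas as pd
import pytest

from gutlink.metabolomics import PeakAreaTable, prepare_metabolomics
from gutlink.pipeline import validate_config, run_all
from gutlink.synthetic import SyntheticConfig, simulate_all


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Scaled-down cohort for unit tests."""
    return SyntheticConfig(
        n_participants=24,
        samples_min=3,
        samples_max=4,
        n_metabolites=40,
        n_methods=2,
        n_planted_da=6,
        n_genes=150,
        n_planted_deg=12,
        n_library_compounds=60,
        n_planted_analogs=6,
        n_targets=20,
        seed=17,
    )


@pytest.fixture(scope="session")
def default_bundle():
    """Full-size synthetic cohort at the default study conditions."""
    return simulate_all(SyntheticConfig())


@pytest.fixture(scope="session")
def prepared_default(default_bundle):
    tables = [PeakAreaTable(k, v) for k, v in default_bundle.peak_tables.items()]
    matrix, tss, prov = prepare_metabolomics(tables, default_bundle.sample_metadata)
    return matrix, tss, prov


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Two independent full pipeline runs with the default config and seed.

    Returns (manifest1, manifest2, outdir1). Shared by the end-to-end and
    recovery tests to keep the suite runtime bounded.
    """
    cfg = validate_config(None)
    out1 = tmp_path_factory.mktemp("run1")
    out2 = tmp_path_factory.mktemp("run2")
    m1 = run_all(cfg, out1)
    m2 = run_all(cfg, out2)
    return m1, m2, Path(out1)


def load_ground_truth(outdir: Path) -> dict:
    return json.loads((outdir / "ground_truth.json").read_text())


def read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
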