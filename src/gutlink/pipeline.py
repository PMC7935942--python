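"""Configuration, orchestration and file formats for the full pipeline.

Stages: simulate -> prep -> da -> de -> rank -> screen -> integrate. Each
stage reads its inputs from and writes its artifacts to the output directory
as TSV/CSV/JSON, and records a manifest entry (parameters, row counts,
sha256 of every artifact) so runs are byte-for-byte reproducible from
(inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .abundance import run_differential_abundance
from .chem import (
    AssayRecord,
    CompoundRecord,
    build_pairs,
    classify_assay,
    degree_histograms,
    fingerprint_from_smiles,
    pleiotropy_filter,
    similarity_search,
)
from .expression import nb_wald_test
from .integrate import DEFAULT_KEYWORDS, link_evidence, summarize_pairs
from .metabolomics import PeakAreaTable, AbundanceMatrix, prepare_metabolomics
from .ranking import (
    MixedEffectsGBM,
    build_features,
    compute_consensus,
    evaluate_model_zoo,
    extract_importances,
    fit_gbm_with_grid,
)
from .synthetic import SyntheticConfig, simulate_all

logger = logging.getLogger("gutlink")

STAGES = ["simulate", "prep", "da", "de", "rank", "screen", "integrate"]
FLOAT_FORMAT = "%.6g"


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


class PrepParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    transform: str = Field("clr", pattern="^(clr|ilr)$")
    min_samples: int = Field(3, gt=0)
    k_sd: float = Field(3.0, gt=0)


class DAParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_boot: int = Field(5000, gt=0)
    fdr: float = Field(0.05, gt=0, le=1)


class RankParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    holdout_fraction: float = Field(0.15, gt=0, lt=1)
    quartile: float = Field(0.75, ge=0, lt=1)
    grid: dict[str, list] | None = None
    run_zoo: bool = True


class ScreenParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t_tanimoto: float = Field(0.85, ge=0, le=1)
    t_tversky: float = Field(0.95, ge=0, le=1)
    tversky_alpha: float = Field(0.05, ge=0, le=1)
    min_pxc50: float = Field(5.5, gt=0, lt=14)
    max_degree: int = Field(20, gt=0)
    fingerprint_family: str = Field("path", pattern="^(path|morgan)$")
    n_bits: int = Field(2048, gt=0)
    functional_only: bool = True


class DEParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fdr: float = Field(0.05, gt=0, le=1)


class IntegrateParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    keywords: list[str] = Field(default_factory=lambda: list(DEFAULT_KEYWORDS))
    consensus_only: bool = False
    from_degs: bool = False
    fdr: float = Field(0.05, gt=0, le=1)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    prep: PrepParams = Field(default_factory=PrepParams)
    da: DAParams = Field(default_factory=DAParams)
    rank: RankParams = Field(default_factory=RankParams)
    screen: ScreenParams = Field(default_factory=ScreenParams)
    de: DEParams = Field(default_factory=DEParams)
    integrate: IntegrateParams = Field(default_factory=IntegrateParams)
    seed: int = 17
    log_level: str = "INFO"


def validate_config(text: str | None) -> PipelineConfig:
    """Parse and range-check a YAML config; empty input gives all defaults."""
    raw = yaml.safe_load(text) if text else None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    try:
        cfg = PipelineConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    logger.info("effective config: %s", cfg.model_dump())
    return cfg


# ---------------------------------------------------------------------------
# artifact I/O


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _read_tsv(path: Path, index_col=None) -> pd.DataFrame:
    if not path.exists():
        raise StageError(f"missing input file: {path}")
    return pd.read_csv(path, sep="\t", index_col=index_col)


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise StageError(f"{name}: missing column(s) {', '.join(missing)}")


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    scfg = cfg.synthetic.model_copy(update={"seed": cfg.seed})
    bundle = simulate_all(scfg)
    for method, table in bundle.peak_tables.items():
        _write_tsv(table.rename_axis("metabolite_id"), outdir / f"peaks_{method}.tsv", index=True)
    _write_tsv(bundle.sample_metadata, outdir / "samples.tsv")
    _write_tsv(bundle.counts.rename_axis("gene_id"), outdir / "counts.tsv", index=True)
    _write_tsv(bundle.biopsy_metadata, outdir / "biopsy_samples.tsv")
    bundle.compounds.to_csv(outdir / "compounds.csv", index=False)
    bundle.assays.to_csv(outdir / "assays.csv", index=False, float_format=FLOAT_FORMAT)
    bundle.evidence.to_csv(outdir / "evidence.csv", index=False)
    bundle.gene_map.to_csv(outdir / "gene_map.csv", index=False)
    _write_tsv(bundle.metabolite_smiles, outdir / "metabolite_smiles.tsv")
    truth = {
        "da_metabolites": bundle.truth.da_metabolites.to_dict(orient="records"),
        "deg_genes": bundle.truth.deg_genes.to_dict(orient="records"),
        "true_pairs": bundle.truth.true_pairs.to_dict(orient="records"),
        "evidence_targets": bundle.truth.evidence_targets,
        "decoy_compounds": bundle.truth.decoy_compounds,
    }
    _write_json(truth, outdir / "ground_truth.json")
    return {
        "n_methods": len(bundle.peak_tables),
        "n_samples": len(bundle.sample_metadata),
        "n_genes": len(bundle.counts),
        "n_compounds": len(bundle.compounds),
    }


def _load_peaks(outdir: Path, n_methods: int) -> list[PeakAreaTable]:
    tables = []
    for path in sorted(outdir.glob("peaks_method*.tsv")):
        df = _read_tsv(path, index_col=0)
        tables.append(PeakAreaTable(path.stem.replace("peaks_", ""), df))
    if not tables:
        raise StageError(f"missing input file: {outdir}/peaks_method*.tsv")
    return tables


def stage_prep(cfg: PipelineConfig, outdir: Path) -> dict:
    tables = _load_peaks(outdir, cfg.synthetic.n_methods)
    metadata = _read_tsv(outdir / "samples.tsv")
    _require_columns(metadata, ["sample_id", "participant_id", "diagnosis", "timepoint"], "samples.tsv")
    matrix, tss_tables, provenance = prepare_metabolomics(
        tables,
        metadata,
        transform=cfg.prep.transform,
        min_samples=cfg.prep.min_samples,
        k_sd=cfg.prep.k_sd,
    )
    _write_tsv(matrix.values.rename_axis("metabolite_id"), outdir / "abundance.tsv", index=True)
    for t in tss_tables:
        _write_tsv(
            t.values.rename_axis("metabolite_id"), outdir / f"relative_{t.method_id}.tsv", index=True
        )
    provenance["pseudocount"] = float(matrix.pseudocount)
    _write_json(provenance, outdir / "prep_provenance.json")
    return {"n_metabolites": len(matrix.values), "n_samples": matrix.values.shape[1]}


def _load_abundance(cfg: PipelineConfig, outdir: Path) -> AbundanceMatrix:
    prov = json.loads((outdir / "prep_provenance.json").read_text())
    values = _read_tsv(outdir / "abundance.tsv", index_col=0)
    return AbundanceMatrix(values, prov["transform"], prov["pseudocount"])


def stage_da(cfg: PipelineConfig, outdir: Path) -> dict:
    matrix = _load_abundance(cfg, outdir)
    metadata = _read_tsv(outdir / "samples.tsv")
    tss_tables = [
        PeakAreaTable(p.stem.replace("relative_", ""), _read_tsv(p, index_col=0), normalized=True)
        for p in sorted(outdir.glob("relative_method*.tsv"))
    ]
    da = run_differential_abundance(
        matrix, tss_tables, metadata, n_boot=cfg.da.n_boot, seed=cfg.seed, fdr=cfg.da.fdr
    )
    _write_tsv(da, outdir / "da_results.tsv")
    return {"n_rows": len(da), "n_significant": int(da["significant"].sum())}


def stage_de(cfg: PipelineConfig, outdir: Path) -> dict:
    counts = _read_tsv(outdir / "counts.tsv", index_col=0)
    metadata = _read_tsv(outdir / "biopsy_samples.tsv")
    _require_columns(metadata, ["sample_id", "diagnosis", "biopsy_location"], "biopsy_samples.tsv")
    res, summary = nb_wald_test(counts, metadata, fdr=cfg.de.fdr)
    _write_tsv(res, outdir / "de_results.tsv")
    _write_json(summary, outdir / "de_summary.json")
    return {"n_rows": len(res), **summary["n_deg"]}


def stage_rank(cfg: PipelineConfig, outdir: Path) -> dict:
    matrix = _load_abundance(cfg, outdir)
    metadata = _read_tsv(outdir / "samples.tsv")
    da = _read_tsv(outdir / "da_results.tsv")
    report: dict = {}
    if cfg.rank.run_zoo:
        scores = evaluate_model_zoo(
            matrix, metadata, seed=cfg.seed, holdout_fraction=cfg.rank.holdout_fraction
        )
        report["zoo_weighted_f1"] = {s.model_name: round(s.weighted_f1, 6) for s in scores}
    tuned, best_params = fit_gbm_with_grid(matrix, metadata, grid=cfg.rank.grid, seed=cfg.seed)
    report["best_grid_point"] = best_params

    x, y, meta = build_features(matrix, metadata)
    me = MixedEffectsGBM(seed=cfg.seed)
    me.fit(x, y, clusters=meta["participant_id"], sites=meta["site"])
    report["sigma_b_participant"] = round(me.sigma_b, 6)
    report["mixed_effects_converged"] = bool(me.converged)

    metabolite_ids = list(matrix.values.index)
    tuned_imps = {d: extract_importances(tuned, x, d, metabolite_ids) for d in ("CD", "UC")}
    me_imps = {d: extract_importances(me, x, d, metabolite_ids) for d in ("CD", "UC")}
    consensus = compute_consensus(da, tuned_imps, me_imps, quartile=cfg.rank.quartile)
    _write_tsv(consensus, outdir / "consensus.tsv")
    _write_json(report, outdir / "model_report.json")
    return {"n_rows": len(consensus), "n_candidates": int(consensus["top_quartile"].sum())}


def stage_screen(cfg: PipelineConfig, outdir: Path) -> dict:
    smiles = _read_tsv(outdir / "metabolite_smiles.tsv")
    _require_columns(smiles, ["metabolite_id", "smiles"], "metabolite_smiles.tsv")
    compounds_df = pd.read_csv(outdir / "compounds.csv")
    _require_columns(compounds_df, ["compound_id", "smiles"], "compounds.csv")
    assays_df = pd.read_csv(outdir / "assays.csv")
    _require_columns(
        assays_df, ["compound_id", "target_id", "readout_type", "pxc50", "action"], "assays.csv"
    )
    fam, nb = cfg.screen.fingerprint_family, cfg.screen.n_bits
    queries = {
        row["metabolite_id"]: fingerprint_from_smiles(row["smiles"], family=fam, n_bits=nb)
        for _, row in smiles.iterrows()
    }
    library = [
        CompoundRecord(
            row["compound_id"],
            row["smiles"],
            fingerprint_from_smiles(row["smiles"], family=fam, n_bits=nb),
        )
        for _, row in compounds_df.iterrows()
    ]
    assays = [
        AssayRecord(
            r["compound_id"],
            r["target_id"],
            r["readout_type"],
            float(r["pxc50"]),
            r["action"],
            assay_class=classify_assay(r["action"]),
        )
        for _, r in assays_df.iterrows()
    ]
    hits = similarity_search(
        queries,
        library,
        t_tanimoto=cfg.screen.t_tanimoto,
        t_tversky=cfg.screen.t_tversky,
        alpha=cfg.screen.tversky_alpha,
    )
    pairs, diagnostics = build_pairs(
        hits, assays, min_pxc50=cfg.screen.min_pxc50, functional_only=cfg.screen.functional_only
    )
    filtered = pleiotropy_filter(pairs, max_degree=cfg.screen.max_degree)
    diagnostics["n_pairs_after_pleiotropy"] = len(filtered)
    diagnostics["fingerprint_family"] = fam
    diagnostics.update(degree_histograms(pairs))
    _write_tsv(filtered, outdir / "pairs.tsv")
    _write_json(diagnostics, outdir / "screen_diagnostics.json")
    return {"n_hits": len(hits), "n_pairs": len(filtered)}


def stage_integrate(cfg: PipelineConfig, outdir: Path) -> dict:
    pairs = _read_tsv(outdir / "pairs.tsv")
    da = _read_tsv(outdir / "da_results.tsv")
    de = _read_tsv(outdir / "de_results.tsv")
    evidence = pd.read_csv(outdir / "evidence.csv")
    gene_map = pd.read_csv(outdir / "gene_map.csv")
    consensus_path = outdir / "consensus.tsv"
    consensus = _read_tsv(consensus_path) if consensus_path.exists() else None
    linked, diagnostics = link_evidence(
        pairs,
        da,
        de,
        evidence,
        gene_map,
        consensus=consensus,
        keywords=cfg.integrate.keywords,
        fdr=cfg.integrate.fdr,
        from_degs=cfg.integrate.from_degs,
    )
    summary, directed = summarize_pairs(linked, consensus_only=cfg.integrate.consensus_only)
    summary.update(diagnostics)
    _write_tsv(linked, outdir / "linked_evidence.tsv")
    _write_tsv(directed, outdir / "directed_pairs.tsv")
    _write_json(summary, outdir / "integration_summary.json")
    return {"n_rows": len(linked), "directed_pairs": summary["directed_pairs"]}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "prep": stage_prep,
    "da": stage_da,
    "de": stage_de,
    "rank": stage_rank,
    "screen": stage_screen,
    "integrate": stage_integrate,
}

_STAGE_ARTIFACTS = {
    "simulate": ["samples.tsv", "counts.tsv", "biopsy_samples.tsv", "compounds.csv",
                 "assays.csv", "evidence.csv", "gene_map.csv", "metabolite_smiles.tsv",
                 "ground_truth.json"],
    "prep": ["abundance.tsv", "prep_provenance.json"],
    "da": ["da_results.tsv"],
    "de": ["de_results.tsv", "de_summary.json"],
    "rank": ["consensus.tsv", "model_report.json"],
    "screen": ["pairs.tsv", "screen_diagnostics.json"],
    "integrate": ["linked_evidence.tsv", "directed_pairs.tsv", "integration_summary.json"],
}


def run_all(cfg: PipelineConfig, outdir: str | Path, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in canonical order; return the manifest.

    With a stage subset, upstream artifacts must already exist in ``outdir``
    (stage caching). The manifest records the package version, the config,
    per-stage row counts and the sha256 of every artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {', '.join(sorted(unknown))}")
    stages = STAGES if stages is None else [s for s in STAGES if s in stages]
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.model_dump(),
        "stages": {},
        "artifacts": {},
    }
    for stage in stages:
        logger.info("running stage %s", stage)
        try:
            counts = _STAGE_FUNCS[stage](cfg, outdir)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage} failed: {exc}") from exc
        manifest["stages"][stage] = counts
        for artifact in _STAGE_ARTIFACTS[stage]:
            path = outdir / artifact
            if path.exists():
                manifest["artifacts"][artifact] = _sha256(path)
        for path in sorted(outdir.glob("peaks_method*.tsv")) + sorted(
            outdir.glob("relative_method*.tsv")
        ):
            manifest["artifacts"][path.name] = _sha256(path)
    _write_json(manifest, outdir / "manifest.json")
    return manifest
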