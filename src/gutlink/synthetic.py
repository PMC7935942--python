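"""Synthetic multi-omics generator with known ground truth.

Emulates the input data of an IBD multi-omics cohort so the whole pipeline is
testable without external downloads: longitudinal stool metabolomics peak
areas over several LC/MS methods with participant- and site-level random
effects and planted differentially abundant metabolites; negative-binomial
biopsy RNA-seq counts under a diagnosis-by-ileum design with planted fold
changes; a ChEMBL-like compound library in which designated analogs of real
metabolite structures exceed the screening similarity thresholds while decoy
scaffolds stay below them; assay records with known modulation directions and
potencies; and a GWAS-catalog-like gene-evidence table with planted
IBD-related traits.

All generators are pure functions of (config, seed): a single master seed is
split into independent child streams (metabolomics, transcriptomics,
chemistry, genetics) so each stage can be regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from rdkit import RDLogger

# candidate analog edits are tried speculatively; failed parses are expected
RDLogger.DisableLog("rdApp.error")

from .chem import (
    SmilesParseError,
    fingerprint_from_smiles,
    tanimoto_similarity,
    tversky_similarity,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticBundle",
    "METABOLITE_TEMPLATES",
    "DECOY_SCAFFOLDS",
    "simulate_metabolomics",
    "simulate_transcriptomics",
    "simulate_compound_library",
    "simulate_genetic_evidence",
    "simulate_all",
]

# Real metabolite structures (short-chain fatty acids, aromatic acids, bile
# acids, purines, amines) so planted-analog fingerprints are chemically
# meaningful.
METABOLITE_TEMPLATES: dict[str, str] = {
    "acetate": "CC(=O)O",
    "propionate": "CCC(=O)O",
    "butyrate": "CCCC(=O)O",
    "valerate": "CCCCC(=O)O",
    "isovalerate": "CC(C)CC(=O)O",
    "hexanoate": "CCCCCC(=O)O",
    "heptanoate": "CCCCCCC(=O)O",
    "octanoate": "CCCCCCCC(=O)O",
    "lactate": "CC(O)C(=O)O",
    "succinate": "OC(=O)CCC(=O)O",
    "tetradecanedioate": "OC(=O)CCCCCCCCCCCCC(=O)O",
    "hydrocinnamate": "OC(=O)CCc1ccccc1",
    "phenylacetate": "OC(=O)Cc1ccccc1",
    "benzoate": "OC(=O)c1ccccc1",
    "nicotinate": "OC(=O)c1cccnc1",
    "nicotinurate": "OC(=O)CNC(=O)c1cccnc1",
    "trigonelline": "C[n+]1cccc(C(=O)[O-])c1",
    "guanine": "Nc1nc2[nH]cnc2c(=O)[nH]1",
    "7-methylguanine": "Cn1cnc2c1c(=O)[nH]c(N)n2",
    "hypoxanthine": "O=c1[nH]cnc2[nH]cnc12",
    "xanthine": "O=c1[nH]cnc2c1[nH]c(=O)[nH]2",
    "adenine": "Nc1ncnc2[nH]cnc12",
    "urate": "O=c1[nH]c(=O)c2[nH]c(=O)[nH]c2[nH]1",
    "serotonin": "NCCc1c[nH]c2ccc(O)cc12",
    "5-hydroxytryptophan": "NC(Cc1c[nH]c2ccc(O)cc12)C(=O)O",
    "tryptophan": "NC(Cc1c[nH]c2ccccc12)C(=O)O",
    "arginine": "NC(CCCNC(=N)N)C(=O)O",
    "taurine": "NCCS(=O)(=O)O",
    "histamine": "NCCc1c[nH]cn1",
    "acetylcarnitine": "CC(=O)OC(CC(=O)[O-])C[N+](C)(C)C",
    "linoleoyl-ethanolamide": "CCCCCC=CCC=CCCCCCCCC(=O)NCCO",
    "lithocholate": "CC(CCC(=O)O)C1CCC2C3CCC4CC(O)CCC4(C)C3CCC12C",
    "deoxycholate": "CC(CCC(=O)O)C1CCC2C3CCC4CC(O)CCC4(C)C3CC(O)C12C",
    "cholate": "CC(CCC(=O)O)C1CCC2C3C(O)CC4CC(O)CCC4(C)C3CC(O)C12C",
    "taurocholate": "CC(CCC(=O)NCCS(=O)(=O)O)C1CCC2C3C(O)CC4CC(O)CCC4(C)C3CC(O)C12C",
    "oleanolate": "CC1(C)CCC2(C(=O)O)CCC3(C)C(=CC4C5(C)CCC(O)C(C)(C)C5CCC34C)C2C1",
}

# Chemically unrelated drug-like scaffolds for decoy library compounds.
DECOY_SCAFFOLDS: list[str] = [
    "c1ccc2c(c1)ccc1ccccc12",
    "CC(C)Cc1ccc(cc1)S(=O)(=O)Nc1ncccn1",
    "ClC1=CC=C(C=C1)C1=CC=CC=C1Cl",
    "O=C(Nc1ccc(F)cc1)N1CCOCC1",
    "c1ccc(-c2ccccc2)cc1",
    "CN1CCN(CC1)c1ccc(cc1)N(=O)=O",
    "FC(F)(F)c1ccc(cc1)S(=O)(=O)N1CCCC1",
    "O=S(=O)(c1ccccc1)c1ccccc1",
    "Clc1ccccc1-c1noc(n1)C1CC1",
    "CCN(CC)c1ccc2nc3ccc(cc3[s+]2c1)N(CC)CC",
    "c1csc(-c2nnc(o2)-c2ccncc2)c1",
    "BrCc1ccc(cc1)-c1ccccn1",
    "O=C1N(Cc2ccccc2)CCN1c1ccccc1",
    "CC1=NN(C(=O)C1)c1ccccc1",
    "FC(F)(F)Oc1ccc(NC2CCNCC2)cc1",
    "ClC(Cl)(Cl)c1nc2ccccc2s1",
    "O=[N+]([O-])c1ccc(o1)C=NN1CCOCC1",
    "c1ccc(COc2ccccc2)cc1",
    "N#Cc1ccc(cc1)N1CCC(CC1)c1ccccn1",
    "Clc1cc2nccnc2cc1Cl",
]

_POSITIVE_ACTIONS = [
    "agonist activity",
    "receptor activator functional assay",
    "channel opener activity",
    "partial agonist activity",
    "potentiator functional assay",
]
_NEGATIVE_ACTIONS = [
    "inhibitor activity",
    "antagonist functional assay",
    "channel blocker activity",
    "inverse agonist activity",
]
_OTHER_ACTIONS = [
    "binding affinity",
    "radioligand displacement Ki",
    "unknown mechanism",
]
_IBD_TRAITS = [
    "Inflammatory bowel disease",
    "Crohn's disease",
    "Ulcerative colitis risk",
    "Monocyte count",
    "Lymphocyte percentage of leukocytes",
]
_UNRELATED_TRAITS = [
    "Standing height",
    "Body mass index",
    "Hair color",
    "Coffee consumption",
    "Type 2 diabetes",
    "Heel bone mineral density",
]

TANIMOTO_THRESHOLD = 0.85
TVERSKY_THRESHOLD = 0.95


class SyntheticConfig(BaseModel):
    """Study conditions for the synthetic cohort."""

    model_config = ConfigDict(extra="forbid")

    n_participants: int = Field(90, gt=0)
    diagnosis_split: tuple[float, float, float] = (0.40, 0.27, 0.33)  # CD, UC, nonIBD
    samples_min: int = Field(3, gt=0)
    samples_max: int = Field(8, gt=0)
    n_metabolites: int = Field(200, gt=0)
    n_methods: int = Field(4, gt=0)
    n_planted_da: int = Field(20, ge=0)
    log10fc_min: float = Field(0.3, gt=0)
    log10fc_max: float = Field(1.0, gt=0)
    participant_sd: float = Field(0.2, ge=0)
    site_sd: float = Field(0.1, ge=0)
    noise_sd: float = Field(0.3, gt=0)
    method_offset_sd: float = Field(0.2, ge=0)
    method_coverage: float = Field(0.8, gt=0, le=1)
    n_sites: int = Field(5, gt=0)
    n_genes: int = Field(2000, gt=0)
    n_planted_deg: int = Field(100, ge=0)
    log2fc_magnitude: float = Field(2.0, gt=0)
    ileum_effect_sd: float = Field(1.0, ge=0)
    ileum_gene_fraction: float = Field(0.1, ge=0, le=1)
    nb_dispersion: float = Field(0.1, gt=0)
    n_library_compounds: int = Field(300, gt=0)
    n_planted_analogs: int = Field(15, ge=0)
    n_targets: int = Field(60, gt=0)
    n_evidence_targets: int = Field(5, ge=0)
    seed: int = 17

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if abs(sum(self.diagnosis_split) - 1.0) > 1e-9:
            raise ValueError("diagnosis_split: proportions must sum to 1")
        if self.samples_max < self.samples_min:
            raise ValueError("samples_max: must be >= samples_min")
        if self.n_planted_da > self.n_metabolites:
            raise ValueError("n_planted_da: must be <= n_metabolites")
        if self.n_planted_deg > self.n_genes:
            raise ValueError("n_planted_deg: must be <= n_genes")
        if self.log10fc_max < self.log10fc_min:
            raise ValueError("log10fc_max: must be >= log10fc_min")
        if self.n_planted_analogs > self.n_library_compounds:
            raise ValueError("n_planted_analogs: must be <= n_library_compounds")
        return self


@dataclass
class GroundTruth:
    """Planted effects and links; every planted id exists in the emitted tables."""

    da_metabolites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["metabolite_id", "disease", "log10fc"])
    )
    deg_genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "disease", "log2fc"])
    )
    true_pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["metabolite_id", "compound_id", "target_id", "direction", "pxc50"]
        )
    )
    participant_effects: dict = field(default_factory=dict)
    site_effects: dict = field(default_factory=dict)
    evidence_targets: list = field(default_factory=list)
    decoy_compounds: list = field(default_factory=list)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        def cat(a, b):
            if a.empty:
                return b.copy()
            if b.empty:
                return a.copy()
            return pd.concat([a, b], ignore_index=True)

        return GroundTruth(
            da_metabolites=cat(self.da_metabolites, other.da_metabolites),
            deg_genes=cat(self.deg_genes, other.deg_genes),
            true_pairs=cat(self.true_pairs, other.true_pairs),
            participant_effects={**self.participant_effects, **other.participant_effects},
            site_effects={**self.site_effects, **other.site_effects},
            evidence_targets=self.evidence_targets + other.evidence_targets,
            decoy_compounds=self.decoy_compounds + other.decoy_compounds,
        )


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ("metabolomics", "transcriptomics", "chemistry", "genetics", "misc")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _metabolite_ids(cfg: SyntheticConfig) -> tuple[list[str], pd.DataFrame]:
    ids = [f"M{i + 1:04d}" for i in range(cfg.n_metabolites)]
    names = list(METABOLITE_TEMPLATES)
    n_named = min(len(names), cfg.n_metabolites)
    smiles = pd.DataFrame(
        {
            "metabolite_id": ids[:n_named],
            "name": names[:n_named],
            "smiles": [METABOLITE_TEMPLATES[n] for n in names[:n_named]],
        }
    )
    return ids, smiles


def _cohort(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Participant table: id, diagnosis, site, age, sex."""
    n = cfg.n_participants
    counts = np.floor(np.asarray(cfg.diagnosis_split) * n).astype(int)
    while counts.sum() < n:
        counts[int(np.argmax(np.asarray(cfg.diagnosis_split) * n - counts))] += 1
    labels = np.repeat(["CD", "UC", "nonIBD"], counts)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:03d}" for i in range(n)],
            "diagnosis": labels,
            "site": rng.choice([f"Site{j + 1}" for j in range(cfg.n_sites)], size=n),
            "age": rng.integers(18, 76, size=n),
            "sex": rng.choice(["F", "M"], size=n),
            "antibiotics": rng.random(n) < 0.2,
        }
    )


def default_planted_da(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Planted metabolite effects: same signed log10 fold change in CD and UC."""
    ids, _ = _metabolite_ids(cfg)
    chosen = rng.choice(ids, size=cfg.n_planted_da, replace=False)
    mags = rng.uniform(cfg.log10fc_min, cfg.log10fc_max, size=cfg.n_planted_da)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_planted_da)
    rows = []
    for met, m, s in zip(chosen, mags, signs):
        for disease in ("CD", "UC"):
            rows.append({"metabolite_id": met, "disease": disease, "log10fc": m * s})
    return pd.DataFrame(rows)


def simulate_metabolomics(
    cfg: SyntheticConfig,
    planted: pd.DataFrame | None = None,
    cohort: pd.DataFrame | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Per-method peak-area tables, sample metadata, and ground truth.

    Peak areas are log-normal: log10(area) = metabolite baseline + disease
    effect + participant intercept + site intercept + method offset +
    N(0, noise_sd). Each LC/MS method measures a random subset
    (``method_coverage``) of the metabolites; every metabolite is guaranteed
    to be measured by at least one method.
    """
    rngs = _child_rngs(cfg.seed)
    rng = rngs["metabolomics"]
    ids, _ = _metabolite_ids(cfg)
    if cohort is None:
        cohort = _cohort(cfg, rngs["misc"])
    if planted is None:
        planted = default_planted_da(cfg, rng)
    missing = set(planted["metabolite_id"]) - set(ids)
    if missing:
        raise ValueError(f"planted metabolites not in table: {sorted(missing)}")

    # sample metadata
    rows = []
    for _, p in cohort.iterrows():
        n_s = int(rng.integers(cfg.samples_min, cfg.samples_max + 1))
        for t in range(1, n_s + 1):
            rows.append(
                {
                    "sample_id": f"S{len(rows) + 1:04d}",
                    "participant_id": p["participant_id"],
                    "diagnosis": p["diagnosis"],
                    "site": p["site"],
                    "age": p["age"],
                    "sex": p["sex"],
                    "antibiotics": p["antibiotics"],
                    "timepoint": t,
                }
            )
    metadata = pd.DataFrame(rows)
    n_samples = len(metadata)

    baseline = rng.normal(6.0, 1.0, size=cfg.n_metabolites)
    part_eff = dict(
        zip(cohort["participant_id"], rng.normal(0, cfg.participant_sd, size=len(cohort)))
    )
    sites = sorted(cohort["site"].unique())
    site_eff = dict(zip(sites, rng.normal(0, cfg.site_sd, size=len(sites))))

    effect = np.zeros((cfg.n_metabolites, n_samples))
    met_index = {m: i for i, m in enumerate(ids)}
    diag = metadata["diagnosis"].to_numpy()
    for _, row in planted.iterrows():
        effect[met_index[row["metabolite_id"]], diag == row["disease"]] = row["log10fc"]

    sample_shift = np.array(
        [part_eff[p] + site_eff[s] for p, s in zip(metadata["participant_id"], metadata["site"])]
    )
    latent = baseline[:, None] + effect + sample_shift[None, :]

    # method coverage with guaranteed union coverage
    coverage = rng.random((cfg.n_methods, cfg.n_metabolites)) < cfg.method_coverage
    uncovered = ~coverage.any(axis=0)
    if uncovered.any():
        coverage[rng.integers(0, cfg.n_methods, size=int(uncovered.sum())), np.where(uncovered)[0]] = True

    tables: dict[str, pd.DataFrame] = {}
    for m in range(cfg.n_methods):
        offsets = rng.normal(0, cfg.method_offset_sd, size=cfg.n_metabolites)
        noise = rng.normal(0, cfg.noise_sd, size=(cfg.n_metabolites, n_samples))
        log_area = latent + offsets[:, None] + noise
        areas = np.power(10.0, log_area)
        sub = pd.DataFrame(areas, index=ids, columns=metadata["sample_id"]).loc[coverage[m]]
        tables[f"method{m + 1}"] = sub

    truth = GroundTruth(
        da_metabolites=planted.copy(), participant_effects=part_eff, site_effects=site_eff
    )
    return tables, metadata, truth


def default_planted_deg(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Planted gene effects: ~40% shared by CD and UC, rest disease-specific."""
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    chosen = rng.choice(genes, size=cfg.n_planted_deg, replace=False)
    rows = []
    for i, g in enumerate(chosen):
        sign = float(rng.choice([-1.0, 1.0]))
        lfc = sign * cfg.log2fc_magnitude
        mode = "both" if i < int(0.4 * len(chosen)) else ("CD" if i % 2 == 0 else "UC")
        for disease in ("CD", "UC"):
            if mode in (disease, "both"):
                rows.append({"gene_id": g, "disease": disease, "log2fc": lfc})
    return pd.DataFrame(rows)


def simulate_transcriptomics(
    cfg: SyntheticConfig,
    planted: pd.DataFrame | None = None,
    cohort: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Negative-binomial biopsy counts under a diagnosis-by-ileum design.

    Gene means are baseline x library size x 2^(planted log2fc in disease)
    x 2^(ileum effect for ileum biopsies). Library sizes span a fixed 4-fold
    log-spaced range.
    """
    rngs = _child_rngs(cfg.seed)
    rng = rngs["transcriptomics"]
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    if cohort is None:
        cohort = _cohort(cfg, rngs["misc"])
    if planted is None:
        planted = default_planted_deg(cfg, rng)
    missing = set(planted["gene_id"]) - set(genes)
    if missing:
        raise ValueError(f"planted genes not in table: {sorted(missing)}")

    rows = []
    for _, p in cohort.iterrows():
        for b in range(int(rng.integers(1, 4))):
            rows.append(
                {
                    "sample_id": f"B{len(rows) + 1:04d}",
                    "participant_id": p["participant_id"],
                    "diagnosis": p["diagnosis"],
                    "biopsy_location": str(rng.choice(["ileum", "rectum", "colon"])),
                }
            )
    metadata = pd.DataFrame(rows)
    n_samples = len(metadata)

    baseline = np.exp(rng.normal(np.log(100.0), 1.0, size=cfg.n_genes))
    lib = np.geomspace(0.5, 2.0, n_samples)
    rng.shuffle(lib)

    lfc = np.zeros((cfg.n_genes, n_samples))
    gene_index = {g: i for i, g in enumerate(genes)}
    diag = metadata["diagnosis"].to_numpy()
    for _, row in planted.iterrows():
        lfc[gene_index[row["gene_id"]], diag == row["disease"]] = row["log2fc"]

    ileum_fc = np.zeros(cfg.n_genes)
    n_ileum_genes = int(cfg.ileum_gene_fraction * cfg.n_genes)
    ileum_idx = rng.choice(cfg.n_genes, size=n_ileum_genes, replace=False)
    ileum_fc[ileum_idx] = rng.normal(0, cfg.ileum_effect_sd, size=n_ileum_genes)
    is_ileum = (metadata["biopsy_location"] == "ileum").to_numpy(dtype=float)

    mu = baseline[:, None] * lib[None, :] * np.power(2.0, lfc + ileum_fc[:, None] * is_ileum[None, :])
    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(counts, index=genes, columns=metadata["sample_id"])
    return counts, metadata, GroundTruth(deg_genes=planted.copy())


def _analog_edits(smiles: str) -> list[str]:
    """Candidate string-level structural edits, largest-first preference."""
    out = []
    if "C(=O)O" in smiles:
        out.append(smiles.replace("C(=O)O", "CC(=O)O", 1))  # chain homologation
        out.append(smiles.replace("C(=O)O", "C(=O)N", 1))  # O->N swap (amide)
    if "[nH]" in smiles:
        out.append(smiles.replace("[nH]", "n(C)", 1))  # ring N-methylation
    if "c1ccccc1" in smiles:
        out.append(smiles.replace("c1ccccc1", "c1ccc(C)cc1", 1))  # ring methyl
    out.append("C" + smiles)  # terminal extension
    if "CC" in smiles:
        out.append(smiles.replace("CC", "C(C)C", 1))  # methyl branch
    out.append(smiles)  # identical library copy as last resort
    return out


def _passes(qfp, cfp) -> bool:
    return (
        tanimoto_similarity(qfp, cfp) >= TANIMOTO_THRESHOLD
        or tversky_similarity(qfp, cfp) >= TVERSKY_THRESHOLD
    )


def viable_analog_parents(metabolite_smiles: pd.DataFrame) -> dict[str, str]:
    """Metabolites for which an analog edit hits them and no other query.

    Returns metabolite_id -> analog SMILES. An edit is viable when the edited
    structure passes the similarity thresholds against its parent and fails
    them against every other query metabolite, so planted hits are exact.
    """
    fps = {}
    bad = []
    for _, row in metabolite_smiles.iterrows():
        try:
            fps[row["metabolite_id"]] = fingerprint_from_smiles(row["smiles"])
        except SmilesParseError:
            bad.append(row["smiles"])
    if bad:
        raise SmilesParseError(bad)
    chosen: dict[str, str] = {}
    smiles_by_id = dict(zip(metabolite_smiles["metabolite_id"], metabolite_smiles["smiles"]))
    for met_id, parent in smiles_by_id.items():
        for edit in _analog_edits(parent):
            try:
                efp = fingerprint_from_smiles(edit)
            except SmilesParseError:
                continue
            if not _passes(fps[met_id], efp):
                continue
            if any(_passes(fps[other], efp) for other in fps if other != met_id):
                continue
            chosen[met_id] = edit
            break
    return chosen


def simulate_compound_library(
    metabolite_smiles: pd.DataFrame,
    cfg: SyntheticConfig,
    planted_assignments: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """ChEMBL-like compound library with planted analogs and decoys.

    Returns (compounds, assays, truth). Each planted analog is a small
    structural edit of a query metabolite that exceeds the screening
    thresholds against its parent only; decoys come from unrelated scaffolds
    and fall below both thresholds for every query. Every compound carries at
    least one assay record; planted analogs get one functional assay with a
    known direction and potency.

    ``planted_assignments`` (optional) fixes metabolite_id/target_id/
    direction/pxc50 per planted analog; otherwise they are drawn here.
    """
    rng = _child_rngs(cfg.seed)["chemistry"]
    targets = [f"T{i + 1:04d}" for i in range(cfg.n_targets)]

    parents = viable_analog_parents(metabolite_smiles)
    if planted_assignments is None:
        if cfg.n_planted_analogs > len(parents):
            raise ValueError(
                f"n_planted_analogs: only {len(parents)} metabolites admit exact-recovery analogs"
            )
        mets = sorted(parents)[: cfg.n_planted_analogs]
        planted_assignments = pd.DataFrame(
            {
                "metabolite_id": mets,
                "target_id": rng.choice(targets, size=len(mets), replace=False),
                "direction": rng.choice(["positive", "negative"], size=len(mets)),
                "pxc50": np.round(rng.uniform(4.8, 9.0, size=len(mets)), 2),
            }
        )
    else:
        unknown = set(planted_assignments["metabolite_id"]) - set(parents)
        if unknown:
            raise ValueError(f"no viable analog edit for metabolites: {sorted(unknown)}")

    compounds = []
    assays = []
    truth_rows = []
    for i, row in planted_assignments.reset_index(drop=True).iterrows():
        cid = f"CHEMBL{900001 + i}"
        compounds.append({"compound_id": cid, "smiles": parents[row["metabolite_id"]]})
        actions = _POSITIVE_ACTIONS if row["direction"] == "positive" else _NEGATIVE_ACTIONS
        assays.append(
            {
                "compound_id": cid,
                "target_id": row["target_id"],
                "readout_type": str(rng.choice(["pIC50", "pEC50"])),
                "pxc50": float(row["pxc50"]),
                "action": str(rng.choice(actions)),
            }
        )
        truth_rows.append(
            {
                "metabolite_id": row["metabolite_id"],
                "compound_id": cid,
                "target_id": row["target_id"],
                "direction": row["direction"],
                "pxc50": float(row["pxc50"]),
            }
        )

    n_decoys = cfg.n_library_compounds - len(planted_assignments)
    decoy_ids = []
    for i in range(n_decoys):
        cid = f"CHEMBL{800001 + i}"
        decoy_ids.append(cid)
        compounds.append({"compound_id": cid, "smiles": DECOY_SCAFFOLDS[i % len(DECOY_SCAFFOLDS)]})
        for _ in range(int(rng.integers(1, 4))):
            pool = [_POSITIVE_ACTIONS, _NEGATIVE_ACTIONS, _OTHER_ACTIONS][int(rng.integers(0, 3))]
            assays.append(
                {
                    "compound_id": cid,
                    "target_id": str(rng.choice(targets)),
                    "readout_type": str(rng.choice(["pIC50", "pEC50"])),
                    "pxc50": float(np.round(rng.uniform(4.5, 9.0), 2)),
                    "action": str(rng.choice(pool)),
                }
            )
    truth = GroundTruth(true_pairs=pd.DataFrame(truth_rows), decoy_compounds=decoy_ids)
    return pd.DataFrame(compounds), pd.DataFrame(assays), truth


def simulate_genetic_evidence(
    targets: list[str],
    cfg: SyntheticConfig,
    gene_map: pd.DataFrame | None = None,
    planted_targets: list[str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """GWAS-catalog-like gene evidence with a planted IBD-trait subset."""
    if not targets:
        raise ValueError("target list is empty")
    rng = _child_rngs(cfg.seed)["genetics"]
    if gene_map is None:
        gene_map = pd.DataFrame({"target_id": targets, "gene_id": targets})
    g = dict(zip(gene_map["target_id"], gene_map["gene_id"]))
    if planted_targets is None:
        n = min(cfg.n_evidence_targets, len(targets))
        planted_targets = list(rng.choice(targets, size=n, replace=False))
    rows = []
    for t in targets:
        trait_pool = _IBD_TRAITS if t in planted_targets else _UNRELATED_TRAITS
        rows.append(
            {
                "gene_id": g.get(t, t),
                "variant_id": f"rs{int(rng.integers(10**6, 10**8))}",
                "trait": str(rng.choice(trait_pool)),
                "source": "gwas_catalog",
            }
        )
    evidence = pd.DataFrame(rows)
    return evidence, GroundTruth(evidence_targets=list(planted_targets))


@dataclass
class SyntheticBundle:
    """All pipeline inputs plus the merged ground truth."""

    peak_tables: dict[str, pd.DataFrame]
    sample_metadata: pd.DataFrame
    counts: pd.DataFrame
    biopsy_metadata: pd.DataFrame
    compounds: pd.DataFrame
    assays: pd.DataFrame
    evidence: pd.DataFrame
    gene_map: pd.DataFrame
    metabolite_smiles: pd.DataFrame
    truth: GroundTruth


def simulate_all(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate a coordinated cohort so fully planted chains are recoverable.

    Coordination rules: planted analog parents are also planted
    differentially abundant; each planted analog's target maps to a planted
    differentially expressed gene whose sign satisfies
    sign(target) = sign(metabolite) x sign(direction), the configuration in
    which metabolite and target changes admit a named co-directionality
    class; a subset of planted targets also carries genetic evidence.
    """
    rngs = _child_rngs(cfg.seed)
    rng = rngs["misc"]
    cohort = _cohort(cfg, rng)
    ids, metabolite_smiles = _metabolite_ids(cfg)

    parents = viable_analog_parents(metabolite_smiles)
    if cfg.n_planted_analogs > len(parents):
        raise ValueError(
            f"n_planted_analogs: only {len(parents)} metabolites admit exact-recovery analogs"
        )
    analog_mets = sorted(parents)[: cfg.n_planted_analogs]

    # planted DA: analog parents first, topped up with random others
    n_extra = max(cfg.n_planted_da - len(analog_mets), 0)
    pool = [m for m in ids if m not in analog_mets]
    extra = list(rng.choice(pool, size=n_extra, replace=False))
    da_mets = (analog_mets + extra)[: cfg.n_planted_da]
    mags = rng.uniform(cfg.log10fc_min, cfg.log10fc_max, size=len(da_mets))
    signs = rng.choice([-1.0, 1.0], size=len(da_mets))
    da_rows = []
    met_sign = {}
    for met, m, s in zip(da_mets, mags, signs):
        met_sign[met] = s
        for disease in ("CD", "UC"):
            da_rows.append({"metabolite_id": met, "disease": disease, "log10fc": m * s})
    planted_da = pd.DataFrame(da_rows)

    # planted analog assignments: one distinct target per analog
    targets = [f"T{i + 1:04d}" for i in range(cfg.n_targets)]
    assigned_targets = list(rng.choice(targets, size=len(analog_mets), replace=False))
    directions = list(rng.choice(["positive", "negative"], size=len(analog_mets)))
    pxc50s = np.round(rng.uniform(4.8, 9.0, size=len(analog_mets)), 2)
    planted_assignments = pd.DataFrame(
        {
            "metabolite_id": analog_mets,
            "target_id": assigned_targets,
            "direction": directions,
            "pxc50": pxc50s,
        }
    )

    # gene map: every target maps to a gene; planted-analog targets map to
    # dedicated genes that will be planted DEGs with the co-directional sign
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    mapped_genes = list(rng.choice(genes, size=cfg.n_targets, replace=False))
    gene_map = pd.DataFrame({"target_id": targets, "gene_id": mapped_genes})
    gene_of = dict(zip(gene_map["target_id"], gene_map["gene_id"]))

    deg_rows = []
    chain_genes = set()
    for met, tgt, direction in zip(analog_mets, assigned_targets, directions):
        gene = gene_of[tgt]
        chain_genes.add(gene)
        dir_sign = 1.0 if direction == "positive" else -1.0
        lfc = met_sign[met] * dir_sign * cfg.log2fc_magnitude
        for disease in ("CD", "UC"):
            deg_rows.append({"gene_id": gene, "disease": disease, "log2fc": lfc})
    n_extra_deg = max(cfg.n_planted_deg - len(chain_genes), 0)
    gene_pool = [g for g in genes if g not in chain_genes]
    extra_genes = list(rng.choice(gene_pool, size=n_extra_deg, replace=False))
    for i, g in enumerate(extra_genes):
        sign = float(rng.choice([-1.0, 1.0]))
        mode = "both" if i < int(0.4 * n_extra_deg) else ("CD" if i % 2 == 0 else "UC")
        for disease in ("CD", "UC"):
            if mode in (disease, "both"):
                deg_rows.append(
                    {"gene_id": g, "disease": disease, "log2fc": sign * cfg.log2fc_magnitude}
                )
    planted_deg = pd.DataFrame(deg_rows)

    peak_tables, sample_metadata, truth_m = simulate_metabolomics(cfg, planted_da, cohort)
    counts, biopsy_metadata, truth_t = simulate_transcriptomics(cfg, planted_deg, cohort)
    compounds, assays, truth_c = simulate_compound_library(metabolite_smiles, cfg, planted_assignments)
    planted_ev = list(
        rng.choice(
            assigned_targets, size=min(cfg.n_evidence_targets, len(assigned_targets)), replace=False
        )
    )
    evidence, truth_g = simulate_genetic_evidence(targets, cfg, gene_map, planted_ev)

    truth = truth_m.merge(truth_t).merge(truth_c).merge(truth_g)
    return SyntheticBundle(
        peak_tables=peak_tables,
        sample_metadata=sample_metadata,
        counts=counts,
        biopsy_metadata=biopsy_metadata,
        compounds=compounds,
        assays=assays,
        evidence=evidence,
        gene_map=gene_map,
        metabolite_smiles=metabolite_smiles,
        truth=truth,
    )
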