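"""Fusion of screened pairs with abundance, expression and genetic evidence.

Each screened metabolite-target pair is annotated, per disease state, with
the metabolite's differential abundance, the target gene's differential
expression (through a target-to-gene mapping), a co-directionality class
joining the two signs with the modulation direction, and a genetic-evidence
flag from keyword-filtered trait associations.

Co-directionality classes for a doubly-significant, directed pair:

  target up,   negative modulator down  -> compensatory_up
  target down, positive modulator down  -> codirectional_down
  target up,   positive modulator up    -> concordant_up
  target down, negative modulator up    -> concordant_down

Anything else (direction "other", missing or non-significant DE/DA) is
``unknown``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_KEYWORDS",
    "filter_traits_by_keywords",
    "annotate_codirectionality",
    "attach_genetic_evidence",
    "link_evidence",
    "summarize_pairs",
]

DEFAULT_KEYWORDS = ["inflammatory", "Crohn", "colitis", "monocyte", "lymphocyte"]
DISEASES = ("CD", "UC")
CONTRAST_OF = {"CD": "CD_vs_nonIBD", "UC": "UC_vs_nonIBD"}


def filter_traits_by_keywords(
    evidence: pd.DataFrame, keywords: list[str] | None = None
) -> pd.DataFrame:
    """Keep evidence rows whose trait contains any keyword (case-insensitive).

    Manually curated rows (source omim or review) pass unconditionally.
    """
    keywords = DEFAULT_KEYWORDS if keywords is None else keywords
    if evidence.empty:
        return evidence.copy()
    curated = evidence["source"].isin(["omim", "review"])
    if not keywords:
        return evidence[curated].reset_index(drop=True)
    low = evidence["trait"].astype(str).str.lower()
    match = np.zeros(len(evidence), dtype=bool)
    for kw in keywords:
        match |= low.str.contains(kw.lower(), regex=False)
    return evidence[match | curated].reset_index(drop=True)


def annotate_codirectionality(
    direction: str,
    metabolite_log10fc: float,
    metabolite_q: float,
    target_log2fc: float | None,
    target_q: float | None,
    fdr: float = 0.05,
) -> str:
    """Joint sign pattern of target expression and metabolite abundance."""
    if direction not in ("positive", "negative"):
        return "unknown"
    if target_log2fc is None or target_q is None or not np.isfinite(target_log2fc):
        return "unknown"
    if not np.isfinite(metabolite_q) or metabolite_q > fdr or (target_q > fdr):
        return "unknown"
    if not np.isfinite(metabolite_log10fc) or metabolite_log10fc == 0 or target_log2fc == 0:
        return "unknown"
    met_up = metabolite_log10fc > 0
    tgt_up = target_log2fc > 0
    if tgt_up and direction == "negative" and not met_up:
        return "compensatory_up"
    if not tgt_up and direction == "positive" and not met_up:
        return "codirectional_down"
    if tgt_up and direction == "positive" and met_up:
        return "concordant_up"
    if not tgt_up and direction == "negative" and met_up:
        return "concordant_down"
    return "unknown"


def attach_genetic_evidence(
    pairs: pd.DataFrame, evidence: pd.DataFrame, gene_map: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Flag pairs whose target maps to a retained evidence gene.

    ``gene_map`` reconciles target ids with gene ids. Targets with no mapping
    are flagged false and counted in the returned diagnostics.
    """
    gmap = dict(zip(gene_map["target_id"], gene_map["gene_id"]))
    by_gene: dict[str, list[str]] = {}
    for _, row in evidence.iterrows():
        by_gene.setdefault(row["gene_id"], []).append(row["source"])
    out = pairs.copy()
    genes = out["target_id"].map(gmap)
    out["genetic_flag"] = [g in by_gene if pd.notna(g) else False for g in genes]
    out["genetic_sources"] = [
        ";".join(sorted(set(by_gene.get(g, [])))) if pd.notna(g) else "" for g in genes
    ]
    unmapped = int(genes.isna().sum())
    return out, {"unmapped_targets": unmapped}


def link_evidence(
    pairs: pd.DataFrame,
    da: pd.DataFrame,
    de: pd.DataFrame,
    evidence: pd.DataFrame,
    gene_map: pd.DataFrame,
    consensus: pd.DataFrame | None = None,
    keywords: list[str] | None = None,
    fdr: float = 0.05,
    from_degs: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Build the LinkedEvidence table: one row per (pair, disease state).

    ``from_degs`` restricts the pair table to targets mapping to a
    differentially expressed gene before annotation (the inverted,
    DEG-first workflow); the per-row annotation is otherwise identical.
    """
    retained = filter_traits_by_keywords(evidence, keywords)
    gmap = dict(zip(gene_map["target_id"], gene_map["gene_id"]))
    de_idx = de.set_index(["gene_id", "contrast"])
    da_idx = da.set_index(["metabolite_id", "contrast"])

    pairs = pairs.copy()
    if from_degs:
        deg_genes = set(de.loc[de["is_deg"], "gene_id"])
        pairs = pairs[pairs["target_id"].map(gmap).isin(deg_genes)].reset_index(drop=True)

    flagged, diagnostics = attach_genetic_evidence(pairs, retained, gene_map)
    top = set()
    if consensus is not None:
        top = set(consensus.loc[consensus["top_quartile"], "metabolite_id"])

    rows = []
    for _, pair in flagged.iterrows():
        gene = gmap.get(pair["target_id"])
        for disease in DISEASES:
            contrast = CONTRAST_OF[disease]
            met_key = (pair["metabolite_id"], contrast)
            met_lfc = met_q = np.nan
            if met_key in da_idx.index:
                met_lfc = float(da_idx.loc[met_key, "log10fc"])
                met_q = float(da_idx.loc[met_key, "q_value"])
            tgt_lfc = tgt_q = None
            if gene is not None and (gene, contrast) in de_idx.index:
                tgt_lfc = float(de_idx.loc[(gene, contrast), "log2fc"])
                tgt_q = float(de_idx.loc[(gene, contrast), "q_value"])
            codir = annotate_codirectionality(
                pair["direction"], met_lfc, met_q, tgt_lfc, tgt_q, fdr=fdr
            )
            row = pair.to_dict()
            row.update(
                {
                    "disease": disease,
                    "gene_id": gene if gene is not None else "",
                    "metabolite_log10fc": met_lfc,
                    "metabolite_q": met_q,
                    "target_log2fc": tgt_lfc if tgt_lfc is not None else np.nan,
                    "target_q": tgt_q if tgt_q is not None else np.nan,
                    "codirectionality": codir,
                    "in_consensus_top_quartile": pair["metabolite_id"] in top,
                }
            )
            rows.append(row)
    linked = pd.DataFrame(rows)
    return linked, diagnostics


def summarize_pairs(linked: pd.DataFrame, consensus_only: bool = False) -> tuple[dict, pd.DataFrame]:
    """Counts of the final integrated table and the directed subset.

    The directed subset keeps pairs with a known modulation direction
    (positive or negative). With ``consensus_only`` the summary is restricted
    to metabolites in the consensus top quartile.
    """
    sub = linked
    if consensus_only and not linked.empty:
        sub = linked[linked["in_consensus_top_quartile"]]
    if sub.empty:
        directed = sub.copy()
        summary = {
            "total_unique_pairs": 0,
            "directed_pairs": 0,
            "pairs_with_genetic_evidence": 0,
            "by_codirectionality": {},
        }
        return summary, directed
    key = ["metabolite_id", "target_id"]
    directed = sub[sub["direction"].isin(["positive", "negative"])].reset_index(drop=True)
    summary = {
        "total_unique_pairs": int(sub[key].drop_duplicates().shape[0]),
        "directed_pairs": int(directed[key].drop_duplicates().shape[0]),
        "pairs_with_genetic_evidence": int(
            sub.loc[sub["genetic_flag"], key].drop_duplicates().shape[0]
        ),
        "by_codirectionality": {
            k: int(v)
            for k, v in sub.groupby("codirectionality")[key[0]].count().to_dict().items()
        },
    }
    return summary, directed
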