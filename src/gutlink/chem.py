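"""Ligand-based virtual screening of metabolites against a compound library.

Metabolite structures (SMILES) are hashed into binary 2D fingerprints and
compared against an assay-annotated compound library with Tanimoto and
asymmetric Tversky similarity. Hits above threshold are joined to assay
records to produce direction- and potency-annotated metabolite-target pairs,
which are then pruned of promiscuous ("pleiotropic") metabolites and targets.

The default fingerprint family is the 2048-bit hashed path (Daylight-style)
fingerprint; a circular radius-2 (Morgan/ECFP4-like) family is available via
``params``. Tversky uses alpha=0.05 on the query side by default, which makes
a metabolite embedded as a substructure of a larger library compound score
close to 1.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "Fingerprint",
    "CompoundRecord",
    "AssayRecord",
    "SimilarityHit",
    "fingerprint_from_smiles",
    "tanimoto_similarity",
    "tversky_similarity",
    "similarity_search",
    "classify_direction",
    "classify_assay",
    "build_pairs",
    "pleiotropy_filter",
]

DEFAULT_N_BITS = 2048
TANIMOTO_THRESHOLD = 0.85
TVERSKY_THRESHOLD = 0.95
TVERSKY_ALPHA = 0.05
MIN_PXC50 = 5.5
MAX_DEGREE = 20


class SmilesParseError(ValueError):
    """Raised when one or more SMILES strings cannot be parsed."""

    def __init__(self, smiles: Sequence[str]):
        self.smiles = list(smiles)
        super().__init__(f"unparsable SMILES: {', '.join(self.smiles)}")


@dataclass(frozen=True)
class Fingerprint:
    """Binary molecular fingerprint as a set of on-bit indices."""

    bits: frozenset[int]
    n_bits: int = DEFAULT_N_BITS
    params: str = "path"

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ValueError("bit index out of range")


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str
    fingerprint: Fingerprint | None = None


@dataclass(frozen=True)
class AssayRecord:
    compound_id: str
    target_id: str
    readout_type: str  # pIC50 | pEC50
    pxc50: float
    action: str
    assay_class: str = "functional"  # functional | binding | other


@dataclass(frozen=True)
class SimilarityHit:
    metabolite_id: str
    compound_id: str
    tanimoto: float
    tversky: float
    arm: str = "tanimoto"  # which threshold arm qualified: tanimoto|tversky|both


def fingerprint_from_smiles(
    smiles: str, family: str = "path", n_bits: int = DEFAULT_N_BITS
) -> Fingerprint:
    """Hash a SMILES string into a binary fingerprint.

    ``family="path"`` gives the default Daylight-style hashed path
    fingerprint; ``family="morgan"`` gives circular radius-2 fingerprints.
    The molecule is canonicalized by the parser so equivalent SMILES
    spellings give identical bits.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError([smiles])
    if family == "path":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    elif family == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    else:
        raise ValueError(f"unknown fingerprint family: {family!r}")
    bv = gen.GetFingerprint(mol)
    return Fingerprint(frozenset(bv.GetOnBits()), n_bits=n_bits, params=family)


def _check_compatible(a: Fingerprint, b: Fingerprint) -> None:
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")


def tanimoto_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """|A∩B| / |A∪B|; 1.0 when both fingerprints are empty."""
    _check_compatible(a, b)
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def tversky_similarity(
    a: Fingerprint, b: Fingerprint, alpha: float = TVERSKY_ALPHA, beta: float | None = None
) -> float:
    """Asymmetric Tversky similarity c / (c + α|A∖B| + β|B∖A|).

    ``a`` is the query (metabolite), ``b`` the library compound. β defaults
    to 1−α. With a small α, a query whose bits are a subset of the library
    compound's scores near 1 (substructure-like matching). α=β=1 recovers
    Tanimoto.
    """
    if alpha < 0 or (beta is not None and beta < 0):
        raise ValueError("alpha and beta must be non-negative")
    if beta is None:
        beta = 1.0 - alpha
    _check_compatible(a, b)
    c = len(a.bits & b.bits)
    denom = c + alpha * len(a.bits - b.bits) + beta * len(b.bits - a.bits)
    if denom == 0:
        return 1.0
    return c / denom


def similarity_search(
    queries: Mapping[str, Fingerprint],
    library: Iterable[CompoundRecord],
    t_tanimoto: float = TANIMOTO_THRESHOLD,
    t_tversky: float = TVERSKY_THRESHOLD,
    alpha: float = TVERSKY_ALPHA,
) -> list[SimilarityHit]:
    """Exhaustive scan of every (query, compound) pair against both arms.

    A pair is a hit when Tanimoto ≥ ``t_tanimoto`` OR Tversky(query,
    compound, α) ≥ ``t_tversky``. Both scores are reported for every hit,
    plus which arm(s) qualified it.
    """
    library = list(library)
    if not library:
        raise ValueError("compound library is empty")
    hits: list[SimilarityHit] = []
    for met_id, qfp in queries.items():
        for comp in library:
            cfp = comp.fingerprint
            if cfp is None:
                cfp = fingerprint_from_smiles(comp.smiles, family=qfp.params, n_bits=qfp.n_bits)
            tan = tanimoto_similarity(qfp, cfp)
            tve = tversky_similarity(qfp, cfp, alpha=alpha)
            pass_tan = tan >= t_tanimoto
            pass_tve = tve >= t_tversky
            if pass_tan or pass_tve:
                arm = "both" if (pass_tan and pass_tve) else ("tanimoto" if pass_tan else "tversky")
                hits.append(SimilarityHit(met_id, comp.compound_id, tan, tve, arm))
    return hits


# Order matters: multi-word modifiers must win over their bare substrings.
_DIRECTION_KEYWORDS: list[tuple[str, str]] = [
    ("inverse agonist", "negative"),
    ("negative allosteric", "negative"),
    ("partial agonist", "positive"),
    ("antagonist", "negative"),
    ("inhibitor", "negative"),
    ("blocker", "negative"),
    ("agonist", "positive"),
    ("activator", "positive"),
    ("opener", "positive"),
    ("cofactor", "positive"),
    ("potentiator", "positive"),
]

_FUNCTIONAL_CUES = ("functional", "agonist", "antagonist", "activity", "ec50")
_BINDING_CUES = ("binding", "ki", "displacement")


def classify_direction(action: str) -> str:
    """Map a free-text assay action string to a modulation direction.

    Returns ``positive`` (agonists, activators, cofactors, ...), ``negative``
    (antagonists, inhibitors, blockers, ...) or ``other`` for uncharacterized
    or unclear interactions. Modified phrases ("inverse agonist") take
    precedence over their bare substrings.
    """
    text = (action or "").lower()
    for keyword, direction in _DIRECTION_KEYWORDS:
        if keyword in text:
            return direction
    return "other"


def classify_assay(action: str) -> str:
    """Heuristic functional/binding/other classification of an assay descriptor."""
    text = (action or "").lower()
    if any(cue in text for cue in _FUNCTIONAL_CUES):
        return "functional"
    if any(cue in text for cue in _BINDING_CUES):
        return "binding"
    return "other"


def _similarity_class(tanimoto: float, tversky: float, arm: str) -> str:
    # Tversky-only hits are classed on the metric that qualified them.
    score = tanimoto if arm in ("tanimoto", "both") else max(tanimoto, tversky)
    if score > 0.9:
        return "strong"
    if score >= 0.8:
        return "medium"
    return "below"


def _affinity_class(pxc50: float) -> str:
    if pxc50 > 7.0:
        return "strong"
    if pxc50 >= 5.5:
        return "medium"
    return "below"


def build_pairs(
    hits: Sequence[SimilarityHit],
    assays: Sequence[AssayRecord],
    min_pxc50: float = MIN_PXC50,
    functional_only: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Join similarity hits to assay records into metabolite-target pairs.

    Keeps functional assays (when ``functional_only``) with potency
    pxC50 ≥ ``min_pxc50``; aggregates multiple assays of one
    (compound, target) into a best potency and a range; annotates modulation
    direction from the action text of the most potent retained assay and
    similarity/affinity strength classes. Hits whose compound has no
    retained assay are dropped and counted in the diagnostics dict.
    """
    assay_by_compound: dict[str, list[AssayRecord]] = {}
    for rec in assays:
        if not 0 < rec.pxc50 < 14:
            raise ValueError(f"pxc50 out of range for {rec.compound_id}: {rec.pxc50}")
        assay_by_compound.setdefault(rec.compound_id, []).append(rec)

    rows = []
    dropped_no_assay = 0
    dropped_filtered = 0
    for hit in hits:
        recs = assay_by_compound.get(hit.compound_id)
        if not recs:
            dropped_no_assay += 1
            continue
        kept = [
            r
            for r in recs
            if r.pxc50 >= min_pxc50 and (not functional_only or r.assay_class == "functional")
        ]
        if not kept:
            dropped_filtered += 1
            continue
        by_target: dict[str, list[AssayRecord]] = {}
        for r in kept:
            by_target.setdefault(r.target_id, []).append(r)
        for target_id, trecs in by_target.items():
            best = max(trecs, key=lambda r: r.pxc50)
            rows.append(
                {
                    "metabolite_id": hit.metabolite_id,
                    "target_id": target_id,
                    "via_compound": hit.compound_id,
                    "tanimoto": hit.tanimoto,
                    "tversky": hit.tversky,
                    "pxc50_best": best.pxc50,
                    "pxc50_low": min(r.pxc50 for r in trecs),
                    "pxc50_high": max(r.pxc50 for r in trecs),
                    "direction": classify_direction(best.action),
                    "similarity_class": _similarity_class(hit.tanimoto, hit.tversky, hit.arm),
                    "affinity_class": _affinity_class(best.pxc50),
                }
            )
    pairs = pd.DataFrame(
        rows,
        columns=[
            "metabolite_id",
            "target_id",
            "via_compound",
            "tanimoto",
            "tversky",
            "pxc50_best",
            "pxc50_low",
            "pxc50_high",
            "direction",
            "similarity_class",
            "affinity_class",
        ],
    )
    diagnostics = {
        "n_hits": len(hits),
        "n_pairs": len(pairs),
        "dropped_no_assay": dropped_no_assay,
        "dropped_by_filters": dropped_filtered,
    }
    return pairs, diagnostics


def pleiotropy_filter(pairs: pd.DataFrame, max_degree: int = MAX_DEGREE) -> pd.DataFrame:
    """Remove pairs of promiscuous metabolites or targets in one pass.

    Degrees (distinct targets per metabolite, distinct metabolites per
    target) are computed once on the input; every pair whose metabolite or
    target reaches ``max_degree`` is dropped simultaneously, so output
    degrees are strictly below the cap and the operation is idempotent.
    """
    if pairs.empty:
        return pairs.copy()
    uniq = pairs[["metabolite_id", "target_id"]].drop_duplicates()
    met_degree = Counter(uniq["metabolite_id"])
    tgt_degree = Counter(uniq["target_id"])
    keep = pairs.apply(
        lambda row: met_degree[row["metabolite_id"]] < max_degree
        and tgt_degree[row["target_id"]] < max_degree,
        axis=1,
    )
    return pairs[keep].reset_index(drop=True)


def degree_histograms(pairs: pd.DataFrame) -> dict:
    """Diagnostics: metabolite- and target-degree distributions."""
    if pairs.empty:
        return {"metabolite_degrees": {}, "target_degrees": {}}
    uniq = pairs[["metabolite_id", "target_id"]].drop_duplicates()
    met = uniq.groupby("metabolite_id")["target_id"].nunique()
    tgt = uniq.groupby("target_id")["metabolite_id"].nunique()
    return {
        "metabolite_degrees": dict(Counter(met.values.tolist())),
        "target_degrees": dict(Counter(tgt.values.tolist())),
    }
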