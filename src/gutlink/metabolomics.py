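"""Preprocessing of per-method LC/MS peak-area tables.

Stool metabolomics peak areas are compositional: the total signal per sample
is an instrument artifact, so each LC/MS method's table is first put on the
simplex by total sum scaling (TSS) and then mapped to unconstrained real
coordinates with a log-ratio transform. Per-method transformed tables are
averaged into a single metabolite-by-sample matrix, and outlying samples are
removed with a PCA score rule.

Pipeline order is fixed: filter_participants -> tss_normalize ->
log_ratio_transform -> average_methods -> pca_outlier_filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from sklearn.decomposition import PCA

__all__ = [
    "PeakAreaTable",
    "AbundanceMatrix",
    "filter_participants",
    "tss_normalize",
    "default_pseudocount",
    "log_ratio_transform",
    "average_methods",
    "pca_outlier_filter",
    "prepare_metabolomics",
]

REQUIRED_METADATA_COLUMNS = ("sample_id", "participant_id", "diagnosis", "site", "timepoint")


@dataclass
class PeakAreaTable:
    """Non-negative metabolite-by-sample peak areas for one LC/MS method."""

    method_id: str
    values: pd.DataFrame  # rows: metabolites, columns: samples
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError(f"negative peak areas in method {self.method_id}")


@dataclass
class AbundanceMatrix:
    """Transformed metabolite-by-sample abundances."""

    values: pd.DataFrame
    transform: str  # clr | ilr
    pseudocount: float
    method_id: str | None = None


def filter_participants(metadata: pd.DataFrame, min_samples: int = 3) -> set[str]:
    """Retain samples of participants with enough longitudinal coverage.

    A participant is kept when they contribute at least ``min_samples``
    samples AND at least two distinct timepoints; the filter is applied per
    datatype by calling it on that datatype's metadata. Returns the retained
    sample-id set.
    """
    if metadata.empty:
        raise ValueError("metadata is empty")
    grouped = metadata.groupby("participant_id").agg(
        n_samples=("sample_id", "nunique"), n_timepoints=("timepoint", "nunique")
    )
    good = grouped.index[(grouped["n_samples"] >= min_samples) & (grouped["n_timepoints"] >= 2)]
    return set(metadata.loc[metadata["participant_id"].isin(good), "sample_id"])


def tss_normalize(table: PeakAreaTable) -> PeakAreaTable:
    """Total sum scaling: divide each sample column by its total."""
    totals = table.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero) > 0:
        raise ValueError(
            f"all-zero sample column(s) in method {table.method_id}: {', '.join(map(str, zero.index))}"
        )
    return PeakAreaTable(table.method_id, table.values / totals, normalized=True)


def default_pseudocount(table: PeakAreaTable) -> float:
    """Half the smallest nonzero relative abundance in the (TSS) table."""
    vals = table.values.values
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise ValueError("table has no nonzero entries")
    return float(nonzero.min() / 2.0)


def _clr(comp: np.ndarray) -> np.ndarray:
    # comp: metabolites x samples, strictly positive
    log = np.log(comp)
    return log - log.mean(axis=0, keepdims=True)


def log_ratio_transform(
    table: PeakAreaTable, transform: str = "clr", pseudocount: float | None = None
) -> AbundanceMatrix:
    """Map a TSS-normalized table to log-ratio coordinates.

    ``clr``: x_i -> ln((x_i+eps)/g(x+eps)) with g the geometric mean; each
    sample's coordinates sum to zero. ``ilr``: Helmert-basis isometric
    coordinates, back-projected through the basis transpose to one score per
    metabolite so downstream analyses stay metabolite-indexed (the
    back-projection of ilr coordinates is exactly the clr image, which is
    what makes cross-method averaging well-defined).
    """
    if not table.normalized:
        raise ValueError("log_ratio_transform expects a TSS-normalized table")
    if transform not in ("clr", "ilr"):
        raise ValueError(f"unknown transform: {transform!r}")
    eps = default_pseudocount(table) if pseudocount is None else pseudocount
    if eps < 0 or (eps == 0 and (table.values.values == 0).any()):
        raise ValueError("pseudocount must be positive when zeros are present")
    comp = table.values.values + eps
    comp = comp / comp.sum(axis=0, keepdims=True)
    if transform == "clr":
        out = _clr(comp)
    else:
        d = comp.shape[0]
        # Orthonormal Helmert-type sequential binary partition basis, V: (D-1) x D
        v = helmert(d, full=False)
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        coords = v @ _clr(comp)  # ilr coordinates, (D-1) x samples
        out = v.T @ coords  # back-projection: per-metabolite scores
    values = pd.DataFrame(out, index=table.values.index, columns=table.values.columns)
    return AbundanceMatrix(values, transform=transform, pseudocount=eps, method_id=table.method_id)


def ilr_coordinates(table: PeakAreaTable, pseudocount: float | None = None) -> np.ndarray:
    """Raw (D-1)-dimensional ilr coordinates (Helmert basis), samples in columns."""
    if not table.normalized:
        raise ValueError("ilr expects a TSS-normalized table")
    eps = default_pseudocount(table) if pseudocount is None else pseudocount
    comp = table.values.values + eps
    comp = comp / comp.sum(axis=0, keepdims=True)
    v = helmert(comp.shape[0], full=False)
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    return v @ _clr(comp)


def average_methods(matrices: list[AbundanceMatrix]) -> AbundanceMatrix:
    """Average transformed values across LC/MS methods.

    Each metabolite's value per sample is the mean over the methods that
    measured it; methods that did not measure a metabolite are ignored
    rather than imputed. Metabolites measured by no method are absent by
    construction.
    """
    if not matrices:
        raise ValueError("no matrices to average")
    shared = set(matrices[0].values.columns)
    for m in matrices[1:]:
        shared &= set(m.values.columns)
    if not shared:
        raise ValueError("methods share no samples")
    cols = [c for c in matrices[0].values.columns if c in shared]
    stacked = pd.concat([m.values[cols] for m in matrices], axis=0)
    averaged = stacked.groupby(level=0, sort=True).mean()
    return AbundanceMatrix(
        averaged, transform=matrices[0].transform, pseudocount=matrices[0].pseudocount
    )


def pca_outlier_filter(matrix: AbundanceMatrix, k_sd: float = 3.0) -> set[str]:
    """Single-pass PCA outlier rule; returns the retained sample-id set.

    Samples whose PC1 or PC2 score lies more than ``k_sd`` standard
    deviations from that component's mean score are removed.
    """
    x = matrix.values.T.values  # samples x metabolites
    if x.shape[0] < 3:
        raise ValueError("PCA outlier filtering needs at least 3 samples")
    n_comp = min(2, x.shape[1])
    scores = PCA(n_components=n_comp).fit_transform(x - x.mean(axis=0))
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = np.abs((scores - scores.mean(axis=0)) / sd)
    keep = (z <= k_sd).all(axis=1)
    return set(np.asarray(matrix.values.columns)[keep])


def prepare_metabolomics(
    tables: list[PeakAreaTable],
    metadata: pd.DataFrame,
    transform: str = "clr",
    min_samples: int = 3,
    k_sd: float = 3.0,
) -> tuple[AbundanceMatrix, list[PeakAreaTable], dict]:
    """Full preprocessing chain; returns (matrix, TSS tables, provenance).

    The returned TSS-normalized per-method tables (restricted to retained
    samples) feed raw-scale fold-change computation downstream.
    """
    retained = filter_participants(metadata, min_samples=min_samples)
    tss_tables: list[PeakAreaTable] = []
    transformed: list[AbundanceMatrix] = []
    for t in tables:
        cols = [c for c in t.values.columns if c in retained]
        sub = PeakAreaTable(t.method_id, t.values[cols])
        tss = tss_normalize(sub)
        tss_tables.append(tss)
        transformed.append(log_ratio_transform(tss, transform=transform))
    matrix = average_methods(transformed)
    kept = pca_outlier_filter(matrix, k_sd=k_sd)
    removed = sorted(set(matrix.values.columns) - kept)
    cols = [c for c in matrix.values.columns if c in kept]
    matrix = AbundanceMatrix(matrix.values[cols], matrix.transform, matrix.pseudocount)
    tss_tables = [
        PeakAreaTable(t.method_id, t.values[[c for c in t.values.columns if c in kept]], True)
        for t in tss_tables
    ]
    provenance = {
        "transform": transform,
        "pseudocounts": {m.method_id: m.pseudocount for m in transformed},
        "n_samples_after_participant_filter": len(retained),
        "pca_removed_samples": removed,
        "k_sd": k_sd,
        "min_samples": min_samples,
    }
    return matrix, tss_tables, provenance
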