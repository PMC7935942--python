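"""Per-metabolite bootstrap effect estimation and nonparametric testing.

Each metabolite is tested independently for CD vs nonIBD and UC vs nonIBD in
a multi-control grouped design (the nonIBD samples serve as the shared
control of both contrasts). The effect estimate is the difference of group
means on the transformed scale with a bias-corrected-and-accelerated (BCa)
bootstrap 95% interval; significance comes from a two-sided Mann-Whitney U
test, FDR-adjusted with Benjamini-Hochberg. Fold changes are reported as
log10 ratios of group-mean relative abundances (pre-log-ratio scale), since
differences of log-ratio coordinates are not log10 ratios.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metabolomics import AbundanceMatrix, PeakAreaTable

__all__ = [
    "bootstrap_mean_difference",
    "mwu_pvalue",
    "bh_adjust",
    "log10_fold_change",
    "run_differential_abundance",
]

CONTRASTS = {"CD_vs_nonIBD": "CD", "UC_vs_nonIBD": "UC"}
CONTROL = "nonIBD"
EXACT_MAX_N = 8


def bootstrap_mean_difference(
    disease: np.ndarray,
    control: np.ndarray,
    n_boot: int = 5000,
    seed: int | np.random.Generator | None = None,
    ci_level: float = 0.95,
) -> tuple[float, float, float]:
    """Mean(disease) − mean(control) with a BCa bootstrap interval.

    Groups are resampled independently within group. Zero-variance data
    (both groups constant) short-circuits to a degenerate interval at the
    observed difference, where the BCa machinery is undefined.
    """
    disease = np.asarray(disease, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(disease) < 2 or len(control) < 2:
        raise ValueError("each group needs at least 2 samples")
    diff = float(disease.mean() - control.mean())
    if np.ptp(disease) == 0 and np.ptp(control) == 0:
        return diff, diff, diff
    rng = np.random.default_rng(seed)
    res = stats.bootstrap(
        (disease, control),
        lambda d, c, axis=-1: np.mean(d, axis=axis) - np.mean(c, axis=axis),
        n_resamples=n_boot,
        method="BCa",
        confidence_level=ci_level,
        vectorized=True,
        rng=rng,
    )
    lo = float(res.confidence_interval.low)
    hi = float(res.confidence_interval.high)
    # BCa can be undefined when the statistic is resampling-degenerate
    if not np.isfinite(lo):
        lo = diff
    if not np.isfinite(hi):
        hi = diff
    return diff, min(lo, diff), max(hi, diff)


def _u_statistic(x: np.ndarray, pooled_ranks: np.ndarray, idx: tuple[int, ...]) -> float:
    return pooled_ranks[list(idx)].sum()


def mwu_pvalue(disease: np.ndarray, control: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value with tie correction.

    When both groups have at most 8 observations the null distribution is
    enumerated exactly over all group assignments of the pooled (possibly
    tied) values; larger groups use the tie-corrected normal approximation.
    """
    disease = np.asarray(disease, dtype=float)
    control = np.asarray(control, dtype=float)
    n1, n2 = len(disease), len(control)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        pooled = np.concatenate([disease, control])
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        n = n1 + n2
        count = 0
        total = 0
        for idx in combinations(range(n), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            if abs(u - mu) >= dev_obs - 1e-9:
                count += 1
            total += 1
        return count / total
    return float(stats.mannwhitneyu(disease, control, alternative="two-sided").pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log10_fold_change(disease_rel: np.ndarray, control_rel: np.ndarray) -> float:
    """log10 of the ratio of group-mean relative abundances."""
    md = float(np.mean(disease_rel))
    mc = float(np.mean(control_rel))
    if md <= 0 or mc <= 0:
        raise ValueError("group mean relative abundances must be positive")
    return float(np.log10(md / mc))


def _relative_abundance_matrix(tss_tables: list[PeakAreaTable]) -> pd.DataFrame:
    """Average TSS relative abundances across methods (ignoring absences)."""
    shared = set(tss_tables[0].values.columns)
    for t in tss_tables[1:]:
        shared &= set(t.values.columns)
    cols = [c for c in tss_tables[0].values.columns if c in shared]
    stacked = pd.concat([t.values[cols] for t in tss_tables], axis=0)
    return stacked.groupby(level=0, sort=True).mean()


def run_differential_abundance(
    matrix: AbundanceMatrix,
    tss_tables: list[PeakAreaTable],
    metadata: pd.DataFrame,
    n_boot: int = 5000,
    seed: int = 0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Bootstrap + Mann-Whitney differential abundance for both contrasts.

    Returns one row per (metabolite, contrast) with columns metabolite_id,
    contrast, mean_diff, ci_low, ci_high, p_mwu, q_value, log10fc,
    significant. q-values are BH-adjusted within contrast.
    """
    meta = metadata.set_index("sample_id")
    cols = [c for c in matrix.values.columns if c in meta.index]
    diag = meta.loc[cols, "diagnosis"]
    rel = _relative_abundance_matrix(tss_tables)
    rel_cols = [c for c in rel.columns if c in meta.index]
    rel_diag = meta.loc[rel_cols, "diagnosis"]
    eps = matrix.pseudocount

    rows = []
    master = np.random.default_rng(seed)
    for contrast, disease_label in CONTRASTS.items():
        d_cols = [c for c in cols if diag[c] == disease_label]
        c_cols = [c for c in cols if diag[c] == CONTROL]
        rd_cols = [c for c in rel_cols if rel_diag[c] == disease_label]
        rc_cols = [c for c in rel_cols if rel_diag[c] == CONTROL]
        sub = matrix.values
        for met in sub.index:
            d = sub.loc[met, d_cols].to_numpy(dtype=float)
            c = sub.loc[met, c_cols].to_numpy(dtype=float)
            diff, lo, hi = bootstrap_mean_difference(d, c, n_boot=n_boot, seed=master.spawn(1)[0])
            p = mwu_pvalue(d, c)
            if met in rel.index:
                fc = log10_fold_change(
                    rel.loc[met, rd_cols].to_numpy(dtype=float) + eps,
                    rel.loc[met, rc_cols].to_numpy(dtype=float) + eps,
                )
            else:
                fc = np.nan
            rows.append(
                {
                    "metabolite_id": met,
                    "contrast": contrast,
                    "mean_diff": diff,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_mwu": p,
                    "log10fc": fc,
                }
            )
    out = pd.DataFrame(rows)
    out["q_value"] = np.nan
    for contrast in CONTRASTS:
        mask = out["contrast"] == contrast
        out.loc[mask, "q_value"] = bh_adjust(out.loc[mask, "p_mwu"].to_numpy())
    out["significant"] = out["q_value"] <= fdr
    return out[
        [
            "metabolite_id",
            "contrast",
            "mean_diff",
            "ci_low",
            "ci_high",
            "p_mwu",
            "q_value",
            "log10fc",
            "significant",
        ]
    ]
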