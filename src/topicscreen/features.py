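"""Dispersion-based gene selection and topic-model input preparation.

Genes are ranked by the absolute difference of their binned dispersion
z-scores between the pooled perturbed (case) and control populations —
"dispersion differentially expressed" (DDE) genes. The selected genes are
then normalized against control means, scaled by 10 and rounded to
nonnegative integers so cells can be treated as documents of gene tokens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("topicscreen")


@dataclass
class DispersionStats:
    """Per-gene dispersion statistics for one population."""

    mean: np.ndarray
    variance: np.ndarray
    dispersion: np.ndarray  # ln(var/mean); NaN where unusable
    zscore: np.ndarray      # binned z-score of dispersion; NaN where unusable
    bin_index: np.ndarray   # -1 where unusable
    usable: np.ndarray


def dispersion(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene dispersion D = ln(variance / mean).

    Genes with zero mean or zero variance are flagged unusable (NaN).
    Returns (D, usable mask).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("dispersion needs at least 2 cells")
    mean = matrix.mean(axis=0)
    var = matrix.var(axis=0, ddof=1)
    usable = (mean > 0) & (var > 0)
    d = np.full(matrix.shape[1], np.nan)
    d[usable] = np.log(var[usable] / mean[usable])
    return d, usable


def binned_dispersion_zscore(d: np.ndarray, mean_expr: np.ndarray,
                             n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each gene's dispersion within equal-frequency mean-expression bins.

    Bins with zero spread of dispersion assign z = 0. If there are fewer
    usable genes than bins, the bin count collapses to floor(usable/2),
    minimum 1. Returns (ZD, bin index), NaN / -1 for unusable genes.
    """
    d = np.asarray(d, dtype=float)
    usable = ~np.isnan(d)
    zd = np.full(d.shape, np.nan)
    bins = np.full(d.shape, -1, dtype=int)
    n_usable = int(usable.sum())
    if n_usable == 0:
        return zd, bins
    k = n_bins if n_usable >= n_bins else max(n_usable // 2, 1)
    idx = np.flatnonzero(usable)
    # stable equal-frequency binning: order by (mean expression, index)
    order = idx[np.lexsort((idx, mean_expr[idx]))]
    for b, chunk in enumerate(np.array_split(order, k)):
        vals = d[chunk]
        mu = vals.mean()
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        zd[chunk] = 0.0 if sd == 0 else (vals - mu) / sd
        bins[chunk] = b
    return zd, bins


def _population_stats(matrix: np.ndarray, n_bins: int) -> DispersionStats:
    mean = matrix.mean(axis=0)
    var = matrix.var(axis=0, ddof=1)
    d, usable = dispersion(matrix)
    zd, bins = binned_dispersion_zscore(d, mean, n_bins)
    return DispersionStats(mean=mean, variance=var, dispersion=d,
                           zscore=zd, bin_index=bins, usable=usable)


def select_dde_genes(case: np.ndarray, control: np.ndarray,
                     gene_ids: np.ndarray, n_top: int = 500, n_bins: int = 20
                     ) -> tuple[list[str], pd.DataFrame]:
    """Rank genes by dispersion difference DD = |ZD_case - ZD_control|.

    Bins are defined independently within case and control. Genes unusable
    in either population are excluded. Returns the top ``n_top`` genes by
    descending DD (ties broken by gene id ascending) and the full DD table.
    """
    case_stats = _population_stats(np.asarray(case, dtype=float), n_bins)
    ctrl_stats = _population_stats(np.asarray(control, dtype=float), n_bins)
    usable = case_stats.usable & ctrl_stats.usable
    dd = np.abs(case_stats.zscore - ctrl_stats.zscore)
    tab = pd.DataFrame({
        "gene": gene_ids,
        "DD": dd,
        "ZD_case": case_stats.zscore,
        "ZD_control": ctrl_stats.zscore,
        "mean_case": case_stats.mean,
        "mean_control": ctrl_stats.mean,
        "usable": usable,
    })
    # round before ranking so ties break by gene id, not float summation order
    ranked = (tab[usable]
              .assign(_dd=lambda t: t.DD.round(10))
              .sort_values(["_dd", "gene"], ascending=[False, True],
                           kind="mergesort")
              .drop(columns="_dd"))
    if n_top > len(ranked):
        logger.warning("requested %d DDE genes but only %d usable; returning all",
                       n_top, len(ranked))
    genes = list(ranked["gene"].head(n_top))
    return genes, tab


def normalize_and_round(matrix: np.ndarray, control_mean: np.ndarray) -> np.ndarray:
    """Map expression to nonnegative integer token counts.

    value = round((X - mu_control) / mu_control * 10), rounding half away
    from zero, with negatives clipped to 0 (word counts must be
    nonnegative; down-regulation is discarded). Genes with zero control
    mean must be excluded upstream.
    """
    matrix = np.asarray(matrix, dtype=float)
    control_mean = np.asarray(control_mean, dtype=float)
    if (control_mean == 0).any():
        raise ValueError("normalize_and_round received genes with zero control mean")
    v = (matrix - control_mean[None, :]) / control_mean[None, :] * 10.0
    rounded = np.sign(v) * np.floor(np.abs(v) + 0.5)
    clipped = rounded < 0
    if clipped.any():
        logger.info("clipped %.1f%% of normalized entries at 0",
                    100.0 * clipped.mean())
    return np.where(clipped, 0.0, rounded).astype(np.int64)
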