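"""Cell quality control and the screen-specific filters.

Beyond routine QC (genes detected, UMI total, mitochondrial fraction),
single-cell CRISPR screens need filters of their own: a perturbation whose
target gene is never expressed carries no usable signal; and because only
70-80% of guide-carrying cells acquire a functional edit, cells whose
differential-expression profile looks like a control ("escapers") must be
removed before effects are quantified. The escaper filter compares, per
perturbed cell, the median cosine similarity of its DE-gene profile to its
perturbation peers against that to the control population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .io import ScreenDataset

logger = logging.getLogger("topicscreen")

MITO_PREFIXES = ("MT-", "mt-")


@dataclass
class QCThresholds:
    """Cell-level quality thresholds.

    min_genes: minimum genes detected per cell (default 500).
    min_umi: minimum total UMI count per cell (default 1000).
    max_mito_fraction: maximum fraction of *detected* genes that are
        mitochondrial (default 0.10); a detected-gene-count fraction, not a
        UMI fraction.
    """

    min_genes: int = 500
    min_umi: int = 1000
    max_mito_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.min_genes < 0 or self.min_umi < 0:
            raise ValueError("thresholds must be nonnegative")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class EfficiencyFilterReport:
    """Audit trail of the sgRNA-efficiency (escaper) filter."""

    cell_table: pd.DataFrame  # cell_id, perturbation, M_P, M_C, removed
    removed_cells: list[str] = field(default_factory=list)
    removed_perturbations: list[str] = field(default_factory=list)
    de_genes: dict[str, list[str]] = field(default_factory=dict)


def qc_filter_cells(dataset: ScreenDataset, thresholds: QCThresholds | None = None,
                    mito_prefix: tuple[str, ...] = MITO_PREFIXES) -> ScreenDataset:
    """Retain cells passing genes-detected, UMI and mitochondrial thresholds."""
    thresholds = thresholds or QCThresholds()
    detected = dataset.counts > 0
    n_detected = detected.sum(axis=1)
    umi = dataset.counts.sum(axis=1)
    is_mito = np.array([str(g).startswith(mito_prefix) for g in dataset.gene_ids])
    n_mito = detected[:, is_mito].sum(axis=1) if is_mito.any() else np.zeros(dataset.n_cells)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(n_detected > 0, n_mito / np.maximum(n_detected, 1), 0.0)
    keep = (
        (n_detected >= thresholds.min_genes)
        & (umi >= thresholds.min_umi)
        & (mito_frac <= thresholds.max_mito_fraction)
    )
    if not keep.any():
        raise ValueError("QC removed every cell; lower min_genes/min_umi or raise "
                         "max_mito_fraction")
    logger.info("QC removed %d of %d cells", int((~keep).sum()), dataset.n_cells)
    return dataset.subset_cells(keep)


def impute(dataset: ScreenDataset, method: str = "none", shrink_lambda: float = 0.1
           ) -> ScreenDataset:
    """Pluggable imputation step.

    ``none`` passes counts through unchanged. ``shrink`` replaces each zero
    entry of a gene by ``shrink_lambda`` times the gene's mean over its
    nonzero cells, a deliberately simple stand-in; an externally imputed
    matrix can equally be supplied as the dataset's counts upstream.
    """
    if method == "none":
        return dataset.subset_cells(np.ones(dataset.n_cells, dtype=bool))
    if method != "shrink":
        raise ValueError(f"unknown imputation method {method!r}")
    counts = dataset.counts.copy()
    nonzero = counts > 0
    n_nonzero = nonzero.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        gene_mean = np.where(n_nonzero > 0, counts.sum(axis=0) / np.maximum(n_nonzero, 1), 0.0)
    fill = shrink_lambda * gene_mean
    counts = np.where(nonzero, counts, fill[None, :])
    out = dataset.subset_cells(np.ones(dataset.n_cells, dtype=bool))
    out.counts = counts
    return out


def filter_zero_perturbations(dataset: ScreenDataset
                              ) -> tuple[ScreenDataset, list[str]]:
    """Drop perturbations whose own target gene is zero in every cell.

    Labels with no matching gene row (e.g. promoter names) skip the check
    with a warning.
    """
    gene_index = {g: i for i, g in enumerate(dataset.gene_ids)}
    dropped: list[str] = []
    for label in dataset.labels():
        gi = gene_index.get(label)
        if gi is None:
            logger.warning("perturbation %r has no matching gene row; "
                           "zero-expression check skipped", label)
            continue
        if not dataset.counts[:, gi].any():
            dropped.append(label)
    if dropped:
        keep = ~np.isin(dataset.perturbation, dropped)
        logger.info("dropped zero-expression perturbations: %s", dropped)
        return dataset.subset_cells(keep), dropped
    return dataset, []


def ks_de_genes(case: np.ndarray, control: np.ndarray, alpha: float = 0.05,
                gene_ids: np.ndarray | None = None) -> list:
    """Genes differentially expressed by a two-sample Kolmogorov-Smirnov test.

    Returns gene indices (or ids if ``gene_ids`` given) with asymptotic
    two-sided p < alpha; no multiplicity correction is applied.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.shape[0] < 2 or control.shape[0] < 2:
        raise ValueError("need at least 2 cells on each side for the KS test")
    hits = []
    for g in range(case.shape[1]):
        x, y = case[:, g], control[:, g]
        if np.array_equal(np.sort(x), np.sort(y)):
            continue  # identical samples: p = 1
        p = ks_2samp(x, y, method="asymp").pvalue
        if p < alpha:
            hits.append(g)
    if gene_ids is not None:
        return [gene_ids[g] for g in hits]
    return hits


def _cosine_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity; zero-norm rows get similarity 0."""
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    an = np.where(na[:, None] > 0, a / np.maximum(na, 1e-300)[:, None], 0.0)
    bn = np.where(nb[:, None] > 0, b / np.maximum(nb, 1e-300)[:, None], 0.0)
    return an @ bn.T


def efficiency_filter(dataset: ScreenDataset, alpha: float = 0.05,
                      drop_fraction: float = 0.90
                      ) -> tuple[ScreenDataset, EfficiencyFilterReport]:
    """Remove perturbed cells that phenotypically resemble controls.

    For each perturbation: find its DE genes versus control (KS test), then
    for each perturbed cell compare M(P_i), the median cosine similarity of
    its DE-gene profile to its same-label peers, with M(C_i), the median
    similarity to control cells. A cell is removed iff M(C_i) > M(P_i); a
    perturbation loses its remaining cells too once the removed share
    reaches ``drop_fraction``. Control cells are never filtered here.
    """
    ctrl_mask = dataset.control_mask
    if not ctrl_mask.any():
        raise ValueError("efficiency filter requires control cells")
    control = dataset.counts[ctrl_mask]
    rows = []
    remove = np.zeros(dataset.n_cells, dtype=bool)
    removed_perts: list[str] = []
    de_map: dict[str, list[str]] = {}
    for label in dataset.labels():
        mask = dataset.perturbation == label
        idx = np.flatnonzero(mask)
        case = dataset.counts[idx]
        if len(idx) < 2:
            logger.warning("perturbation %r has a single cell; peer similarity "
                           "undefined, cell retained", label)
            continue
        de = ks_de_genes(case, control, alpha=alpha)
        de_map[label] = [dataset.gene_ids[g] for g in de]
        if not de:
            logger.warning("perturbation %r has no KS-significant genes; no "
                           "cells filtered", label)
            continue
        pv = case[:, de]
        cv = control[:, de]
        peer_sim = _cosine_matrix(pv, pv)
        ctrl_sim = _cosine_matrix(pv, cv)
        n = len(idx)
        off_diag = peer_sim[~np.eye(n, dtype=bool)].reshape(n, n - 1)
        m_p = np.median(off_diag, axis=1)
        m_c = np.median(ctrl_sim, axis=1)
        cell_removed = m_c > m_p  # ties retain the cell
        for j in range(n):
            rows.append((dataset.cell_ids[idx[j]], label, m_p[j], m_c[j],
                         bool(cell_removed[j])))
        if cell_removed.sum() >= drop_fraction * n:
            removed_perts.append(label)
            remove[idx] = True
        else:
            remove[idx[cell_removed]] = True
    report = EfficiencyFilterReport(
        cell_table=pd.DataFrame(rows, columns=["cell_id", "perturbation",
                                               "M_P", "M_C", "removed"]),
        removed_cells=list(dataset.cell_ids[remove]),
        removed_perturbations=removed_perts,
        de_genes=de_map,
    )
    logger.info("efficiency filter removed %d cells, %d whole perturbations",
                int(remove.sum()), len(removed_perts))
    return dataset.subset_cells(~remove), report


def min_cell_filter(dataset: ScreenDataset, min_cells: int = 30
                    ) -> tuple[ScreenDataset, list[str]]:
    """Drop perturbations with fewer than ``min_cells`` cells remaining."""
    counts = pd.Series(dataset.perturbation).value_counts()
    n_ctrl = counts.get(dataset.control_label, 0)
    if n_ctrl < min_cells:
        raise ValueError(
            f"only {n_ctrl} control cells remain (< {min_cells}); the pipeline "
            "cannot proceed without an adequate control population"
        )
    dropped = [lab for lab in dataset.labels() if counts[lab] < min_cells]
    if dropped:
        keep = ~np.isin(dataset.perturbation, dropped)
        logger.info("dropped %d perturbations below %d cells: %s",
                    len(dropped), min_cells, dropped)
        return dataset.subset_cells(keep), dropped
    return dataset, []


def preprocess(dataset: ScreenDataset, thresholds: QCThresholds | None = None,
               impute_method: str = "none", ks_alpha: float = 0.05,
               drop_fraction: float = 0.90, min_cells: int = 30,
               mito_prefix: tuple[str, ...] = MITO_PREFIXES,
               skip_efficiency_filter: bool = False
               ) -> tuple[ScreenDataset, EfficiencyFilterReport]:
    """Run the full filter chain in its fixed order.

    QC -> imputation -> zero-expression perturbations -> efficiency filter
    -> minimum cells per perturbation. The efficiency filter can be
    skipped for screens where escapers are not expected (e.g. CRISPRi).
    """
    ds = qc_filter_cells(dataset, thresholds, mito_prefix)
    ds = impute(ds, impute_method)
    ds, _ = filter_zero_perturbations(ds)
    if skip_efficiency_filter:
        report = EfficiencyFilterReport(cell_table=pd.DataFrame(
            columns=["cell_id", "perturbation", "M_P", "M_C", "removed"]))
    else:
        ds, report = efficiency_filter(ds, alpha=ks_alpha,
                                       drop_fraction=drop_fraction)
    ds, _ = min_cell_filter(ds, min_cells)
    return ds, report
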