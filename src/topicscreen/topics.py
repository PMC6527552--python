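"""Latent Dirichlet allocation over cells, topic-number selection, annotation.

Each cell is a document whose words are gene tokens (the normalized,
rounded expression values), so a fitted model yields theta — per-cell
topic proportions, the substrate of all downstream effect statistics —
and phi, per-topic gene probabilities used for functional annotation.

Topic-number selection balances two desiderata: topics should spread
unevenly across cells (specificity, the dispersion of each theta column)
and each cell should be dominated by few topics (purity, the variance
within each theta row). Both are combined on a min-max-normalized scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._gibbs import run_gibbs
from .io import GeneSetCollection

logger = logging.getLogger("topicscreen")

_EPS = 1e-12


@dataclass
class TopicModel:
    """A fitted LDA model: theta (cells x topics), phi (topics x genes)."""

    theta: np.ndarray
    phi: np.ndarray
    n_topics: int
    alpha: float
    beta: float
    n_iter: int
    burn_in: int
    seed: int
    cell_ids: np.ndarray | None = None
    gene_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("theta rows must sum to 1")
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("phi rows must sum to 1")
        if (self.theta < 0).any() or (self.phi < 0).any():
            raise ValueError("probabilities must be nonnegative")


@dataclass
class TopicNumberScan:
    candidates: list[int]
    ss: np.ndarray
    ps: np.ndarray
    cs: np.ndarray
    alpha_cs: float
    best: int
    models: dict[int, TopicModel] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_topics": self.candidates, "SS": self.ss,
                             "PS": self.ps, "CS": self.cs})


@dataclass
class TopicAnnotation:
    """Per-topic top genes and gene-set over-representation results."""

    top_genes: dict[int, list[str]]
    enrichment: pd.DataFrame  # topic, term, overlap, set_size, fold, p, q


def _token_stream(counts: np.ndarray, gene_order: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Expand a count matrix into (doc, word) token arrays.

    Tokens are emitted cell-major with genes in ``gene_order``, a canonical
    order independent of column layout, so permuting gene columns (with
    their ids) leaves the chain — and hence theta — unchanged.
    """
    docs, words = [], []
    for d in range(counts.shape[0]):
        row = counts[d]
        for g in gene_order:
            c = int(row[g])
            if c > 0:
                docs.append(np.full(c, d, dtype=np.int64))
                words.append(np.full(c, g, dtype=np.int64))
    if not docs:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(docs), np.concatenate(words)


def fit_lda(counts: np.ndarray, n_topics: int, alpha: float | None = None,
            beta: float = 0.1, n_iter: int = 1000, burn_in: int = 500,
            seed: int = 0, average: bool = False,
            cell_ids: np.ndarray | None = None,
            gene_ids: np.ndarray | None = None) -> TopicModel:
    """Fit LDA by collapsed Gibbs sampling on a nonnegative integer matrix.

    Cells with all-zero rows are dropped from the chain with a warning and
    receive the uniform topic distribution. By default theta and phi are
    the smoothed estimators from the final post-burn-in sweep's assignment
    counts; ``average=True`` averages counts over all post-burn-in sweeps.
    Identical inputs and seed give bit-identical output.
    """
    counts = np.asarray(counts)
    m, v = counts.shape
    if n_topics < 1:
        raise ValueError("n_topics must be >= 1")
    if n_topics > m:
        raise ValueError(f"n_topics={n_topics} exceeds number of cells {m}")
    if alpha is None:
        alpha = 50.0 / n_topics
    zero_rows = ~counts.any(axis=1)
    if zero_rows.any():
        logger.warning("%d all-zero cells excluded from the Gibbs chain",
                       int(zero_rows.sum()))
    if gene_ids is not None:
        gene_order = np.lexsort((np.arange(v), np.asarray(gene_ids, dtype=object)))
    else:
        gene_order = np.arange(v)
    doc_ids, word_ids = _token_stream(counts, gene_order)
    if doc_ids.size == 0:
        raise ValueError("zero total tokens; nothing to model")
    ndk, nkw, ndk_sum, nkw_sum, n_samples = run_gibbs(
        doc_ids, word_ids, m, v, n_topics, float(alpha), float(beta),
        int(n_iter), int(burn_in), int(seed) & 0x7FFFFFFF, bool(average))
    if average and n_samples > 0:
        ndk = ndk_sum / n_samples
        nkw = nkw_sum / n_samples
    theta = (ndk + alpha) / (ndk.sum(axis=1, keepdims=True) + n_topics * alpha)
    phi = (nkw + beta) / (nkw.sum(axis=1, keepdims=True) + v * beta)
    if zero_rows.any():
        theta[zero_rows] = 1.0 / n_topics
    return TopicModel(theta=theta, phi=phi, n_topics=n_topics, alpha=alpha,
                      beta=beta, n_iter=n_iter, burn_in=burn_in, seed=seed,
                      cell_ids=cell_ids, gene_ids=gene_ids)


def _group_means(theta: np.ndarray, cell_groups) -> np.ndarray:
    """Collapse theta rows to per-group (e.g. per-perturbation) means."""
    groups = np.asarray(cell_groups, dtype=object)
    return np.vstack([theta[groups == g].mean(axis=0)
                      for g in sorted(set(groups))])


def specificity_score(theta: np.ndarray, cell_groups=None) -> float:
    """ln of the mean squared coefficient of variation of theta columns.

    SS = ln((1/n) sum_j var_j / mean_j^2) over topic columns; columns with
    zero mean contribute 0, and the log argument is floored at 1e-12.
    ``cell_groups`` (e.g. perturbation labels) computes the score on
    per-group mean theta rows instead of individual cells.
    """
    theta = np.asarray(theta, dtype=float)
    if cell_groups is not None:
        theta = _group_means(theta, cell_groups)
    mean = theta.mean(axis=0)
    var = theta.var(axis=0, ddof=1)
    terms = np.where(mean > 0, var / np.maximum(mean, _EPS) ** 2, 0.0)
    return float(np.log(max(terms.mean(), _EPS)))


def purity_score(theta: np.ndarray, cell_groups=None) -> float:
    """ln of the mean within-cell (row) variance of theta; floored at 1e-12."""
    theta = np.asarray(theta, dtype=float)
    if cell_groups is not None:
        theta = _group_means(theta, cell_groups)
    if theta.shape[1] > 1:
        row_var = theta.var(axis=1, ddof=1)
    else:
        row_var = np.zeros(theta.shape[0])
    return float(np.log(max(row_var.mean(), _EPS)))


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.ones_like(x)
    return (x - lo) / (hi - lo)


def select_topic_number(counts: np.ndarray, candidates: list[int] | None = None,
                        alpha_cs: float = 0.5, seed: int = 0,
                        gene_ids: np.ndarray | None = None,
                        cell_groups=None, **lda_kwargs) -> TopicNumberScan:
    """Fit one model per candidate topic count and score each.

    CS = alpha_cs * minmax(SS) + (1 - alpha_cs) * minmax(PS) across the
    candidates; the best candidate maximizes CS, ties going to the smaller
    topic count. Each candidate's chain is seeded from the master seed plus
    its index so the scan is order-independent.
    """
    candidates = sorted(candidates or [4, 5, 6])
    if len(candidates) == 1:
        logger.warning("single candidate topic count; CS is trivially 1")
    ss, ps, models = [], [], {}
    for i, n in enumerate(candidates):
        model = fit_lda(counts, n, seed=(seed + i) & 0x7FFFFFFF,
                        gene_ids=gene_ids, **lda_kwargs)
        models[n] = model
        ss.append(specificity_score(model.theta, cell_groups))
        ps.append(purity_score(model.theta, cell_groups))
    ss, ps = np.asarray(ss), np.asarray(ps)
    cs = alpha_cs * _minmax(ss) + (1 - alpha_cs) * _minmax(ps)
    best = candidates[int(np.argmax(cs))]  # argmax takes first -> smaller n on ties
    return TopicNumberScan(candidates=candidates, ss=ss, ps=ps, cs=cs,
                           alpha_cs=alpha_cs, best=best, models=models)


def annotate_topics(model: TopicModel, sets: GeneSetCollection,
                    top_fraction: float = 0.10, n_terms: int = 5
                    ) -> TopicAnnotation:
    """Annotate topics by gene-set over-representation of their top genes.

    Per topic, the top ceil(top_fraction * G) genes by phi (ties by gene
    id) are tested against each gene set with the hypergeometric tail over
    the model's gene universe; q-values are Benjamini-Hochberg within the
    topic and the top ``n_terms`` terms by q are reported.
    """
    if model.gene_ids is None:
        raise ValueError("model has no gene_ids; annotation needs a gene universe")
    genes = np.asarray(model.gene_ids, dtype=object)
    universe = set(genes)
    usable_sets = {name: [g for g in gs if g in universe]
                   for name, gs in sets.sets.items()}
    usable_sets = {k: v for k, v in usable_sets.items() if v}
    if not usable_sets:
        logger.warning("no gene set overlaps the model's gene universe")
        return TopicAnnotation(top_genes={}, enrichment=pd.DataFrame(
            columns=["topic", "term", "overlap", "set_size", "fold", "p", "q"]))
    g_total = len(genes)
    k_top = math.ceil(top_fraction * g_total)
    top_genes: dict[int, list[str]] = {}
    rows = []
    for t in range(model.n_topics):
        order = np.lexsort((genes, -model.phi[t]))
        top = list(genes[order[:k_top]])
        top_genes[t] = top
        top_set = set(top)
        pvals, recs = [], []
        for name, members in usable_sets.items():
            overlap = len(top_set & set(members))
            # P(X >= overlap) drawing k_top from g_total with len(members) marked
            p = float(hypergeom.sf(overlap - 1, g_total, len(members), k_top))
            expected = k_top * len(members) / g_total
            fold = overlap / expected if expected > 0 else np.nan
            pvals.append(p)
            recs.append((name, overlap, len(members), fold, p))
        q = multipletests(pvals, method="fdr_bh")[1]
        tab = pd.DataFrame(recs, columns=["term", "overlap", "set_size", "fold", "p"])
        tab["q"] = q
        tab["topic"] = t
        tab = tab.sort_values(["q", "p", "term"], kind="mergesort").head(n_terms)
        rows.append(tab)
    enrichment = pd.concat(rows, ignore_index=True)[
        ["topic", "term", "overlap", "set_size", "fold", "p", "q"]]
    return TopicAnnotation(top_genes=top_genes, enrichment=enrichment)
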