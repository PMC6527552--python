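"""Off-target screening for knockout guides.

Candidate off-target genes are found by a mismatch-tolerant window scan of
the guide against transcript sequences on both strands; a candidate is
then flagged only if the expression correlation between the intended
target and the candidate increases significantly in perturbed cells
relative to controls (Fisher z, one-sided) — sequence similarity alone is
not evidence of an off-target event. CRISPRi screens, whose knockdown is
highly locus-specific, should skip this module entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm as normal

from .io import ScreenDataset

logger = logging.getLogger("topicscreen")

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class OffTargetCandidate:
    sgrna_id: str
    target_gene: str
    candidate_gene: str
    mismatches: int
    offset: int
    strand: str  # '+' window on the given sequence, '-' on its reverse complement


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    if not valid.all():
        bad = chr(arr[~valid][0])
        raise ValueError(f"invalid nucleotide character {bad!r}")
    return arr


def _scan(guide: np.ndarray, seq: np.ndarray, max_mismatch: int,
          require_pam: bool) -> list[tuple[int, int]]:
    """(offset, mismatches) for windows within the mismatch budget."""
    k = len(guide)
    n = len(seq)
    if n < k:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(seq, k)
    mm = (windows != guide).sum(axis=1)
    hits = np.flatnonzero(mm <= max_mismatch)
    out = []
    G = ord("G")
    for off in hits:
        if require_pam:
            # NGG immediately 3' of the protospacer on the matched strand
            if off + k + 3 > n or seq[off + k + 1] != G or seq[off + k + 2] != G:
                continue
        out.append((int(off), int(mm[off])))
    return out


def find_candidates(sgrna: str, transcripts: dict[str, str], target_gene: str,
                    max_mismatch: int = 3, sgrna_id: str = "sgRNA",
                    require_pam: bool = False) -> list[OffTargetCandidate]:
    """Mismatch-tolerant search of a guide against transcript sequences.

    Both strands are scanned with plain Hamming distance over exact-length
    windows; each gene other than the intended target is reported once at
    its minimal distance. Guides must be 18-23 nt over ACGT.
    """
    sgrna = sgrna.upper()
    if not 18 <= len(sgrna) <= 23:
        raise ValueError("sgRNA length must be 18-23 nt")
    guide = _encode(sgrna)
    out = []
    for gene, seq in transcripts.items():
        if gene == target_gene:
            continue
        seq = seq.upper()
        best = None
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            for off, mm in _scan(guide, _encode(s), max_mismatch, require_pam):
                if best is None or mm < best[0]:
                    best = (mm, off, strand)
        if best is not None:
            out.append(OffTargetCandidate(sgrna_id=sgrna_id,
                                          target_gene=target_gene,
                                          candidate_gene=gene,
                                          mismatches=best[0], offset=best[1],
                                          strand=best[2]))
    return sorted(out, key=lambda c: (c.mismatches, c.candidate_gene))


def _fisher_z_increase_p(r_case: float, n_case: int, r_ctrl: float,
                         n_ctrl: int) -> float:
    """One-sided p for r_case > r_ctrl via the Fisher z transform."""
    z1 = np.arctanh(np.clip(r_case, -1 + 1e-15, 1 - 1e-15))
    z2 = np.arctanh(np.clip(r_ctrl, -1 + 1e-15, 1 - 1e-15))
    se = np.sqrt(1.0 / (n_case - 3) + 1.0 / (n_ctrl - 3))
    return float(normal.sf((z1 - z2) / se))


def correlation_increase_test(dataset: ScreenDataset, target_gene: str,
                              candidates: list[OffTargetCandidate],
                              alpha: float = 0.05) -> pd.DataFrame:
    """Test each candidate for a correlation increase in perturbed cells.

    Per candidate gene: Pearson r between target and candidate expression
    within cells perturbed for the target (r_case) and within controls
    (r_control); flagged iff the one-sided Fisher z test finds r_case
    significantly above r_control at ``alpha``. Zero-variance genes on
    either side are skipped with a warning.
    """
    gene_index = {g: i for i, g in enumerate(dataset.gene_ids)}
    if target_gene not in gene_index:
        raise ValueError(f"target gene {target_gene!r} not in dataset")
    case = dataset.counts[dataset.perturbation == target_gene]
    ctrl = dataset.counts[dataset.control_mask]
    if len(case) < 4 or len(ctrl) < 4:
        raise ValueError("need at least 4 cells per side for the Fisher z test")
    ti = gene_index[target_gene]
    rows = []
    for cand in candidates:
        ci = gene_index.get(cand.candidate_gene)
        if ci is None:
            continue
        xs = (case[:, ti], case[:, ci], ctrl[:, ti], ctrl[:, ci])
        if any(v.std() == 0 for v in xs):
            logger.warning("zero-variance expression for %s; candidate skipped",
                           cand.candidate_gene)
            continue
        r_case = float(np.corrcoef(case[:, ti], case[:, ci])[0, 1])
        r_ctrl = float(np.corrcoef(ctrl[:, ti], ctrl[:, ci])[0, 1])
        p = _fisher_z_increase_p(r_case, len(case), r_ctrl, len(ctrl))
        rows.append((cand.sgrna_id, target_gene, cand.candidate_gene,
                     cand.mismatches, r_case, r_ctrl, p, p < alpha))
    return pd.DataFrame(rows, columns=["sgrna_id", "target_gene",
                                       "candidate_gene", "mismatches",
                                       "r_case", "r_control", "p", "flagged"])
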