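"""Perturbation-effect statistics on the topic representation.

All scores derive from TPD, the topic probability difference: a pooled
two-sample t statistic comparing a perturbation's control-normalized topic
probabilities against the control population, bootstrapped at the minimal
perturbation cell count M to neutralize sample-size imbalance (median over
draws). From TPD follow

* TPD_random — the same statistic with the case side drawn from controls,
  a per-topic null baseline;
* TPDA = TPD - TPD_random, the adjusted effect;
* TPDR — each topic's share of a perturbation's total |TPD|;
* CS — the topic-specific score, the average of min-max-normalized |TPD|
  and TPDR within a perturbation, with an empirical significance threshold
  from repeated control-only draws;
* TPDS = sum_j |TPDA_ij| — the overall impact score; and
* PID — the ratio of a perturbation's TPDS share between two conditions.

Randomness is organized as per-(perturbation, topic) substreams keyed by a
label hash, so every statistic is reproducible from the master seed and
invariant to cell or label ordering.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("topicscreen")

_EPS = 1e-12


@dataclass
class EffectProfile:
    """All effect statistics for one screen."""

    perturbations: list[str]
    n_topics: int
    tpd: np.ndarray          # perturbation x topic
    tpd_random: np.ndarray   # per-topic baseline
    tpda: np.ndarray
    tpdr: np.ndarray         # NaN rows where TPD is all-zero
    cs: np.ndarray
    cs_threshold: np.ndarray  # per-topic
    cs_significant: np.ndarray
    tpds: np.ndarray
    tpds_normalized: np.ndarray
    m_cells: int
    n_boot: int
    seed: int

    def ranking(self) -> pd.DataFrame:
        order = np.lexsort((np.asarray(self.perturbations, dtype=object),
                            -self.tpds))
        return pd.DataFrame({
            "rank": np.arange(1, len(order) + 1),
            "perturbation": [self.perturbations[i] for i in order],
            "TPDS": self.tpds[order],
            "TPDS_normalized": self.tpds_normalized[order],
        })


def _substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic substream from the master seed and arbitrary keys."""
    words = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            words.append(zlib.crc32(k.encode()) & 0x7FFFFFFF)
        else:
            words.append(int(k) & 0x7FFFFFFF)
    return np.random.default_rng(words)


def normalize_theta(theta: np.ndarray, control_mask: np.ndarray) -> np.ndarray:
    """Z-normalize every cell's topic probabilities against the controls.

    Per topic, subtract the control mean and divide by the control sample
    SD; a constant control column falls back to SD = 1e-12 with a warning.
    """
    theta = np.asarray(theta, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    if control_mask.sum() < 2:
        raise ValueError("normalization needs at least 2 control cells")
    ctrl = theta[control_mask]
    mu = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    if (sd == 0).any():
        logger.warning("constant control topic column(s); SD floored at 1e-12")
        sd = np.where(sd == 0, _EPS, sd)
    return (theta - mu) / sd


def pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-variance two-sample t statistic.

    t = (mean(x) - mean(y)) / sqrt(pooled_var * (1/nx + 1/ny)) with
    pooled_var = ((nx-1) s_x^2 + (ny-1) s_y^2) / (nx + ny - 2). Zero pooled
    variance gives 0 for equal means, signed infinity otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("pooled_t needs at least 2 values per side")
    diff = x.mean() - y.mean()
    pooled = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    denom = np.sqrt(pooled * (1.0 / nx + 1.0 / ny))
    if denom == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / denom)


def _pooled_t_rows(samples: np.ndarray, y: np.ndarray) -> np.ndarray:
    """pooled_t of each row of ``samples`` against the fixed vector ``y``."""
    nx = samples.shape[1]
    ny = len(y)
    mx = samples.mean(axis=1)
    vx = samples.var(axis=1, ddof=1)
    my = y.mean()
    vy = y.var(ddof=1)
    pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    denom = np.sqrt(pooled * (1.0 / nx + 1.0 / ny))
    diff = mx - my
    out = np.where(denom > 0, diff / np.maximum(denom, _EPS),
                   np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    return out


def _bootstrap_median_t(values: np.ndarray, control: np.ndarray, m: int,
                        n_boot: int, rng: np.random.Generator) -> float:
    """Median over bootstrap draws of pooled_t(M-subsample, control)."""
    n = len(values)
    if n == m:
        return _pooled_t_rows(values[None, :], control)[0]
    # without replacement: first M of a random permutation per draw
    idx = rng.random((n_boot, n)).argsort(axis=1)[:, :m]
    return float(np.median(_pooled_t_rows(values[idx], control)))


def tpd(norm_theta: np.ndarray, labels: np.ndarray, control_label: str = "CTRL",
        m: int | None = None, n_boot: int = 1000, seed: int = 0
        ) -> tuple[np.ndarray, list[str], int]:
    """TPD matrix: bootstrap-median pooled t per (perturbation, topic).

    M defaults to the minimal cell count over non-control perturbations.
    Returns (TPD, perturbation labels sorted, M).
    """
    labels = np.asarray(labels, dtype=object)
    perts = sorted(set(labels) - {control_label})
    if not perts:
        raise ValueError("no perturbations besides the control")
    sizes = {p: int((labels == p).sum()) for p in perts}
    if m is None:
        m = min(sizes.values())
    if m < 2:
        raise ValueError(f"minimal perturbation cell count M={m} < 2")
    ctrl = norm_theta[labels == control_label]
    if len(ctrl) < 2:
        raise ValueError("need at least 2 control cells")
    n_topics = norm_theta.shape[1]
    out = np.zeros((len(perts), n_topics))
    for i, p in enumerate(perts):
        vals = norm_theta[labels == p]
        for j in range(n_topics):
            rng = _substream(seed, p, j)
            out[i, j] = _bootstrap_median_t(vals[:, j], ctrl[:, j], m, n_boot, rng)
    return out, perts, m


def tpd_random(norm_theta: np.ndarray, control_mask: np.ndarray, m: int,
               n_boot: int = 1000, seed: int = 0) -> np.ndarray:
    """Per-topic null baseline: M control cells bootstrapped against all controls."""
    ctrl = norm_theta[np.asarray(control_mask, dtype=bool)]
    n_ctrl = len(ctrl)
    replace = n_ctrl < m
    if replace:
        logger.warning("fewer controls (%d) than M=%d; drawing with replacement",
                       n_ctrl, m)
    n_topics = norm_theta.shape[1]
    out = np.zeros(n_topics)
    for j in range(n_topics):
        rng = _substream(seed, "__random__", j)
        if replace:
            idx = rng.integers(0, n_ctrl, size=(n_boot, m))
        elif n_ctrl == m:
            idx = np.tile(np.arange(n_ctrl), (n_boot, 1))
        else:
            idx = rng.random((n_boot, n_ctrl)).argsort(axis=1)[:, :m]
        out[j] = float(np.median(_pooled_t_rows(ctrl[idx, j], ctrl[:, j])))
    return out


def tpda(tpd_mat: np.ndarray, tpd_rand: np.ndarray) -> np.ndarray:
    """Adjusted TPD: subtract the per-topic control baseline."""
    tpd_mat = np.asarray(tpd_mat, dtype=float)
    tpd_rand = np.asarray(tpd_rand, dtype=float)
    if tpd_mat.shape[1] != tpd_rand.shape[0]:
        raise ValueError("TPD and baseline topic dimensions differ")
    return tpd_mat - tpd_rand[None, :]


def tpdr(tpd_mat: np.ndarray, axis: str = "topics") -> np.ndarray:
    """Share of |TPD| per topic within each perturbation.

    Rows with all-zero TPD are undefined (NaN). ``axis="perturbations"``
    normalizes down columns instead (the literal reading of the printed
    summation index, kept behind this flag).
    """
    a = np.abs(np.asarray(tpd_mat, dtype=float))
    if axis == "topics":
        denom = a.sum(axis=1, keepdims=True)
    elif axis == "perturbations":
        denom = a.sum(axis=0, keepdims=True)
    else:
        raise ValueError("axis must be 'topics' or 'perturbations'")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = a / denom
    return np.where(denom == 0, np.nan, out)


def _cs_row(abs_tpd_row: np.ndarray, tpdr_row: np.ndarray) -> np.ndarray:
    """CS over topics for one perturbation; degenerate extent terms -> 0."""
    def norm(v):
        lo, hi = np.nanmin(v), np.nanmax(v)
        if not np.isfinite(hi - lo) or hi == lo:
            return np.zeros_like(v)
        return (v - lo) / (hi - lo)
    return 0.5 * (norm(abs_tpd_row) + norm(tpdr_row))


def topic_specific_scores(tpd_mat: np.ndarray, tpdr_mat: np.ndarray,
                          norm_theta: np.ndarray | None = None,
                          control_mask: np.ndarray | None = None,
                          m: int | None = None, n_reps: int = 1000,
                          seed: int = 0, extent_axis: str = "topics"
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Topic-specific effect score CS and its empirical threshold.

    CS_ij averages the within-perturbation min-max normalizations of
    |TPD_ij| and TPDR_ij. The per-topic significance threshold is the
    median, over ``n_reps`` repetitions, of the same CS computation applied
    to a control-only TPD row (each repetition draws M control cells per
    topic). Requires at least 2 topics. ``extent_axis="perturbations"``
    instead takes the min-max extents down each topic column.
    """
    tpd_mat = np.asarray(tpd_mat, dtype=float)
    if tpd_mat.shape[1] < 2:
        raise ValueError("topic-specific scores need n_topics >= 2")
    if extent_axis == "topics":
        cs = np.vstack([_cs_row(np.abs(tpd_mat[i]), tpdr_mat[i])
                        for i in range(tpd_mat.shape[0])])
    elif extent_axis == "perturbations":
        cs = np.column_stack([_cs_row(np.abs(tpd_mat[:, j]), tpdr_mat[:, j])
                              for j in range(tpd_mat.shape[1])])
    else:
        raise ValueError("extent_axis must be 'topics' or 'perturbations'")
    if norm_theta is None or control_mask is None or m is None:
        return cs, np.full(tpd_mat.shape[1], np.nan), np.zeros_like(cs, dtype=bool)
    ctrl = norm_theta[np.asarray(control_mask, dtype=bool)]
    n_ctrl = len(ctrl)
    n_topics = tpd_mat.shape[1]
    cs_null = np.empty((n_reps, n_topics))
    for r in range(n_reps):
        row = np.empty(n_topics)
        for j in range(n_topics):
            rng = _substream(seed, "__threshold__", r, j)
            if n_ctrl > m:
                idx = rng.permutation(n_ctrl)[:m]
            else:
                idx = np.arange(n_ctrl)
            row[j] = _pooled_t_rows(ctrl[idx, j][None, :], ctrl[:, j])[0]
        r_tpdr = tpdr(row[None, :])[0]
        cs_null[r] = _cs_row(np.abs(row), r_tpdr)
    threshold = np.median(cs_null, axis=0)
    significant = cs > threshold[None, :]
    return cs, threshold, significant


def overall_ranking(tpda_mat: np.ndarray, perturbations: list[str]
                    ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Overall impact score TPDS_i = sum_j |TPDA_ij| and its ranked table."""
    tpds = np.abs(np.asarray(tpda_mat, dtype=float)).sum(axis=1)
    top = tpds.max()
    tpds_norm = tpds / top if top > 0 else np.zeros_like(tpds)
    order = np.lexsort((np.asarray(perturbations, dtype=object), -tpds))
    table = pd.DataFrame({
        "rank": np.arange(1, len(order) + 1),
        "perturbation": [perturbations[i] for i in order],
        "TPDS": tpds[order],
        "TPDS_normalized": tpds_norm[order],
    })
    return tpds, tpds_norm, table


def perturbation_correlations(tpda_mat: np.ndarray, perturbations: list[str]
                              ) -> pd.DataFrame:
    """Pearson correlation of every pair of TPDA profiles, sorted by |r|."""
    tpda_mat = np.asarray(tpda_mat, dtype=float)
    if len(perturbations) < 2:
        raise ValueError("need at least 2 perturbations for correlations")
    sd = tpda_mat.std(axis=1)
    rows = []
    for i in range(len(perturbations)):
        for j in range(i + 1, len(perturbations)):
            if sd[i] == 0 or sd[j] == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(tpda_mat[i], tpda_mat[j])[0, 1])
            rows.append((perturbations[i], perturbations[j], r))
    tab = pd.DataFrame(rows, columns=["perturbation_a", "perturbation_b", "r"])
    tab["abs_r"] = tab["r"].abs()
    tab = tab.sort_values(["abs_r", "perturbation_a", "perturbation_b"],
                          ascending=[False, True, True], kind="mergesort")
    return tab.drop(columns="abs_r").reset_index(drop=True)


def pid(tpds_cond1: dict[str, float], tpds_cond2: dict[str, float]
        ) -> pd.DataFrame:
    """Perturbation impact difference between two conditions.

    PID_i = (TPDS2_i / sum TPDS2) / (TPDS1_i / sum TPDS1) over the common
    perturbations. A zero condition-1 share yields an infinite PID (flagged).
    """
    common = sorted(set(tpds_cond1) & set(tpds_cond2))
    if not common:
        raise ValueError("no common perturbations between the two conditions")
    t1 = np.array([tpds_cond1[p] for p in common], dtype=float)
    t2 = np.array([tpds_cond2[p] for p in common], dtype=float)
    if t1.sum() <= 0 or t2.sum() <= 0:
        raise ValueError("each condition's TPDS total must be positive")
    share1 = t1 / t1.sum()
    share2 = t2 / t2.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(share1 > 0, share2 / np.maximum(share1, _EPS), np.inf)
    tab = pd.DataFrame({"perturbation": common, "TPDS_cond1": t1,
                        "TPDS_cond2": t2, "PID": ratio})
    with np.errstate(divide="ignore"):
        tab["abs_log_PID"] = np.abs(np.log(tab["PID"]))
    return tab.sort_values(["abs_log_PID", "perturbation"],
                           ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)


def effect_profile(theta: np.ndarray, labels: np.ndarray,
                   control_label: str = "CTRL", n_boot: int = 1000,
                   n_threshold_reps: int = 1000, seed: int = 0
                   ) -> EffectProfile:
    """Compute the complete effect profile from a fitted theta and labels."""
    labels = np.asarray(labels, dtype=object)
    ctrl_mask = labels == control_label
    nt = normalize_theta(theta, ctrl_mask)
    tpd_mat, perts, m = tpd(nt, labels, control_label, n_boot=n_boot, seed=seed)
    tpd_rand = tpd_random(nt, ctrl_mask, m, n_boot=n_boot, seed=seed)
    tpda_mat = tpda(tpd_mat, tpd_rand)
    tpdr_mat = tpdr(tpd_mat)
    cs, thr, sig = topic_specific_scores(tpd_mat, tpdr_mat, nt, ctrl_mask, m,
                                         n_reps=n_threshold_reps, seed=seed)
    tpds, tpds_norm, _ = overall_ranking(tpda_mat, perts)
    return EffectProfile(perturbations=perts, n_topics=theta.shape[1],
                         tpd=tpd_mat, tpd_random=tpd_rand, tpda=tpda_mat,
                         tpdr=tpdr_mat, cs=cs, cs_threshold=thr,
                         cs_significant=sig, tpds=tpds,
                         tpds_normalized=tpds_norm, m_cells=m, n_boot=n_boot,
                         seed=seed)


def robustness_test(theta: np.ndarray, labels: np.ndarray,
                    control_label: str = "CTRL", relabel_fraction: float = 0.2,
                    n_reps: int = 10, n_boot: int = 1000, seed: int = 0
                    ) -> tuple[float, float, pd.DataFrame]:
    """Stability of the ranking under control relabeling.

    Per repetition, a random ``relabel_fraction`` of control cells becomes a
    pseudo-perturbation; the effect stage is rerun and we record (a) the
    fraction of true perturbations ranking below the pseudo-perturbation
    and (b) the Pearson correlation of true perturbations' normalized TPDS
    with the unrelabeled run. The topic representation is label-free, so
    theta is held fixed across repetitions. Returns the two means and a
    per-repetition table.
    """
    labels = np.asarray(labels, dtype=object)
    ctrl_idx = np.flatnonzero(labels == control_label)
    n_take = int(round(relabel_fraction * len(ctrl_idx)))
    if n_take < 2 or len(ctrl_idx) - n_take < 2:
        raise ValueError("too few control cells to split for the robustness test")
    base = effect_profile(theta, labels, control_label, n_boot=n_boot, seed=seed)
    base_norm = dict(zip(base.perturbations, base.tpds_normalized))
    pseudo = "__CTRL_TEST__"
    rows = []
    for rep in range(n_reps):
        rng = _substream(seed, "__robust__", rep)
        take = rng.permutation(len(ctrl_idx))[:n_take]
        new_labels = labels.copy()
        new_labels[ctrl_idx[take]] = pseudo
        prof = effect_profile(theta, new_labels, control_label,
                              n_boot=n_boot, seed=seed)
        scores = dict(zip(prof.perturbations, prof.tpds))
        pseudo_score = scores.pop(pseudo)
        true_perts = sorted(scores)
        below = np.mean([scores[p] < pseudo_score for p in true_perts])
        norm = dict(zip(prof.perturbations, prof.tpds_normalized))
        a = np.array([norm[p] for p in true_perts])
        b = np.array([base_norm[p] for p in true_perts])
        if a.std() == 0 or b.std() == 0:
            corr = np.nan
        else:
            corr = float(np.corrcoef(a, b)[0, 1])
        rows.append((rep, float(below), corr, pseudo_score))
    tab = pd.DataFrame(rows, columns=["rep", "below_rate", "tpds_correlation",
                                      "pseudo_TPDS"])
    return (float(tab["below_rate"].mean()),
            float(tab["tpds_correlation"].mean(skipna=True)), tab)
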