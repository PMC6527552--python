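"""End-to-end orchestration: preprocess -> features -> topics -> effects.

`run_pipeline` is the library entry point used by the CLI's ``all``
subcommand and by the staged subcommands; every intermediate table can be
written to a run directory, each with a header comment carrying the tool
version and a hash of the fully resolved configuration, and a rerun with
the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .effects import EffectProfile, effect_profile, pid, robustness_test
from .features import normalize_and_round, select_dde_genes
from .io import CONTROL_LABEL, ScreenDataset, write_ranking
from .preprocess import EfficiencyFilterReport, QCThresholds, preprocess
from .topics import TopicModel, TopicNumberScan, fit_lda, select_topic_number

logger = logging.getLogger("topicscreen")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, serializable to JSON."""

    # QC / filtering
    min_genes: int = 500
    min_umi: int = 1000
    max_mito_fraction: float = 0.10
    impute_method: str = "none"
    ks_alpha: float = 0.05
    drop_fraction: float = 0.90
    min_cells: int = 30
    skip_efficiency_filter: bool = False  # e.g. CRISPRi screens
    # features
    n_dde_genes: int = 500
    n_bins: int = 20
    # topics
    topic_candidates: list[int] = field(default_factory=lambda: [4, 5, 6])
    n_topics: int | None = None       # fixed topic count; overrides the scan
    lda_alpha: float | None = None    # default 50 / n_topics
    lda_beta: float = 0.1
    n_iter: int = 1000
    burn_in: int = 500
    alpha_cs: float = 0.5
    # effects
    n_boot: int = 1000
    n_threshold_reps: int = 1000
    # global
    control_label: str = CONTROL_LABEL
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        data = {k: v for k, v in json.loads(text).items() if k in known}
        return cls(**data)

    def hash(self) -> str:
        return hashlib.md5(self.to_json().encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    dataset: ScreenDataset            # after all filters
    report: EfficiencyFilterReport
    dde_genes: list[str]
    dde_table: pd.DataFrame
    model: TopicModel
    scan: TopicNumberScan | None
    profile: EffectProfile
    config: RunConfig


def build_features(dataset: ScreenDataset, config: RunConfig
                   ) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """DDE selection + normalization: the topic-model input matrix."""
    ctrl = dataset.control_mask
    if not ctrl.any() or ctrl.all():
        raise ValueError("features stage needs both perturbed and control cells")
    genes, table = select_dde_genes(dataset.counts[~ctrl], dataset.counts[ctrl],
                                    dataset.gene_ids, n_top=config.n_dde_genes,
                                    n_bins=config.n_bins)
    gene_index = {g: i for i, g in enumerate(dataset.gene_ids)}
    idx = np.asarray([gene_index[g] for g in genes], dtype=int)
    mu_ctrl = dataset.counts[ctrl][:, idx].mean(axis=0)
    ok = mu_ctrl > 0
    if not ok.all():
        logger.info("excluding %d DDE genes with zero control mean",
                    int((~ok).sum()))
        idx, mu_ctrl = idx[ok], mu_ctrl[ok]
        genes = [g for g, keep in zip(genes, ok) if keep]
    tokens = normalize_and_round(dataset.counts[:, idx], mu_ctrl)
    return tokens, genes, table


def run_pipeline(dataset: ScreenDataset, config: RunConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full pipeline on an in-memory dataset.

    Stage errors are re-raised with the stage name prefixed so a failure
    is attributable.
    """
    config = config or RunConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    filtered, report = stage(
        "preprocess", preprocess, dataset,
        QCThresholds(config.min_genes, config.min_umi, config.max_mito_fraction),
        config.impute_method, config.ks_alpha, config.drop_fraction,
        config.min_cells, skip_efficiency_filter=config.skip_efficiency_filter)
    tokens, dde_genes, dde_table = stage("features", build_features,
                                         filtered, config)
    gene_ids = np.asarray(dde_genes, dtype=object)
    scan: TopicNumberScan | None = None
    if config.n_topics is not None:
        model = stage("topics", fit_lda, tokens, config.n_topics,
                      alpha=config.lda_alpha, beta=config.lda_beta,
                      n_iter=config.n_iter, burn_in=config.burn_in,
                      seed=config.seed, gene_ids=gene_ids,
                      cell_ids=filtered.cell_ids)
    else:
        scan = stage("topics", select_topic_number, tokens,
                     config.topic_candidates, config.alpha_cs, config.seed,
                     gene_ids=gene_ids, alpha=config.lda_alpha,
                     beta=config.lda_beta, n_iter=config.n_iter,
                     burn_in=config.burn_in)
        model = scan.models[scan.best]
    profile = stage("effects", effect_profile, model.theta,
                    filtered.perturbation, config.control_label,
                    n_boot=config.n_boot,
                    n_threshold_reps=config.n_threshold_reps, seed=config.seed)
    result = PipelineResult(dataset=filtered, report=report,
                            dde_genes=dde_genes, dde_table=dde_table,
                            model=model, scan=scan, profile=profile,
                            config=config)
    if out_dir is not None:
        write_results(result, out_dir)
    return result


def _mat_frame(mat: np.ndarray, rows: list[str], row_name: str,
               col_prefix: str = "topic_") -> pd.DataFrame:
    tab = pd.DataFrame(mat, columns=[f"{col_prefix}{j}" for j in range(mat.shape[1])])
    tab.insert(0, row_name, rows)
    return tab


def write_results(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write every intermediate and final table of a run as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comment = f"topicscreen v{__version__} config={result.config.hash()}"
    (out / "config.json").write_text(result.config.to_json() + "\n")
    prof = result.profile
    perts = prof.perturbations
    write_ranking(result.dde_table, out / "dde_genes.tsv", comment)
    write_ranking(result.report.cell_table, out / "efficiency_report.tsv", comment)
    if result.scan is not None:
        write_ranking(result.scan.as_frame(), out / "topic_scan.tsv", comment)
    write_ranking(_mat_frame(result.model.theta,
                             list(result.dataset.cell_ids), "cell_id"),
                  out / "theta.tsv", comment)
    phi = pd.DataFrame(result.model.phi.T,
                       columns=[f"topic_{j}" for j in range(result.model.n_topics)])
    phi.insert(0, "gene", result.dde_genes)
    write_ranking(phi, out / "phi.tsv", comment)
    for name, mat in (("tpd", prof.tpd), ("tpda", prof.tpda),
                      ("tpdr", prof.tpdr), ("cs", prof.cs)):
        write_ranking(_mat_frame(mat, perts, "perturbation"),
                      out / f"{name}.tsv", comment)
    thr = pd.DataFrame({"topic": range(prof.n_topics),
                        "tpd_random": prof.tpd_random,
                        "cs_threshold": prof.cs_threshold})
    write_ranking(thr, out / "topic_thresholds.tsv", comment)
    write_ranking(prof.ranking(), out / "overall_ranking.tsv", comment)
    from .effects import perturbation_correlations
    if len(perts) >= 2:
        write_ranking(perturbation_correlations(prof.tpda, perts),
                      out / "correlations.tsv", comment)
    return out


def compare_conditions(dataset_a: ScreenDataset, dataset_b: ScreenDataset,
                       config: RunConfig | None = None,
                       out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run both conditions and rank perturbations by impact difference.

    Returns the PID table sorted by |ln PID| descending over the common
    perturbations.
    """
    config = config or RunConfig()
    res_a = run_pipeline(dataset_a, config)
    res_b = run_pipeline(dataset_b, config)
    tab = pid(dict(zip(res_a.profile.perturbations, res_a.profile.tpds)),
              dict(zip(res_b.profile.perturbations, res_b.profile.tpds)))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        comment = f"topicscreen v{__version__} config={config.hash()}"
        write_ranking(tab, out / "pid.tsv", comment)
        write_results(res_a, out / "condition_1")
        write_results(res_b, out / "condition_2")
    return tab


def run_robustness(dataset: ScreenDataset, config: RunConfig | None = None,
                   n_reps: int = 10, relabel_fraction: float = 0.2
                   ) -> tuple[float, float, pd.DataFrame]:
    """Pipeline + ranking-stability test under control relabeling."""
    config = config or RunConfig()
    result = run_pipeline(dataset, config)
    return robustness_test(result.model.theta, result.dataset.perturbation,
                           config.control_label,
                           relabel_fraction=relabel_fraction, n_reps=n_reps,
                           n_boot=config.n_boot, seed=config.seed)
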