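"""Synthetic single-cell CRISPR screens with planted ground truth.

The generator mirrors the topic-model view of a screen: each topic is a
distribution over genes (Dirichlet-distributed loadings), each cell draws
topic proportions from a Dirichlet prior, and its transcript tokens are
multinomial in the mixed gene distribution. A perturbation shifts the
Dirichlet prior toward its assigned topic by its effect size; a planted
fraction of "escaper" cells keeps the perturbed label but draws from the
control law, emulating guides that fail to edit (20-30% in practice, so
the default escaper fraction is 0.25). Knockdown of the target gene itself
is emulated by scaling its counts in edited cells. Dropout is independent
Bernoulli zeroing — the simplest mechanism producing the sparsity regime
of real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CONTROL_LABEL, ScreenDataset


@dataclass
class SimConfig:
    """Generative settings for one synthetic screen.

    effect_sizes maps perturbation index -> Dirichlet shift magnitude on
    its assigned topic (perturbations cycle through topics). Gene ids are
    G0001..; the first ``n_perturbations`` genes double as the knockout
    targets so the own-gene knockdown (factor 0.1) is observable.
    """

    n_perturbations: int = 5
    n_cells_per_perturbation: int = 60
    n_control_cells: int = 150
    n_genes: int = 300
    n_topics_true: int = 3
    dirichlet_base: np.ndarray | None = None      # default: 0.8 per topic
    topic_concentration: float = 0.05             # Dirichlet beta for gene loadings
    effect_sizes: np.ndarray | None = None        # default: 4.0 per perturbation
    escaper_fraction: float = 0.25
    library_size: float = 1000.0
    dropout_rate: float = 0.1
    knockdown_factor: float = 0.1
    seed: int = 0

    @classmethod
    def strong_separation(cls, **overrides) -> "SimConfig":
        """The strong-separation regime used to probe the escaper filter.

        A concentrated control prior (Dirichlet 5 per topic) makes the
        wild-type phenotype coherent — the premise under which escapers
        are identifiable at all — and a large topic shift (25) gives the
        edited cells an unambiguous phenotype.
        """
        n_topics = overrides.pop("n_topics_true", 3)
        n_perts = overrides.pop("n_perturbations", 5)
        cfg = dict(n_perturbations=n_perts, n_topics_true=n_topics,
                   dirichlet_base=np.full(n_topics, 5.0),
                   effect_sizes=np.full(n_perts, 25.0))
        cfg.update(overrides)
        return cls(**cfg)

    def __post_init__(self) -> None:
        if self.dirichlet_base is None:
            self.dirichlet_base = np.full(self.n_topics_true, 0.8)
        self.dirichlet_base = np.asarray(self.dirichlet_base, dtype=float)
        if len(self.dirichlet_base) != self.n_topics_true:
            raise ValueError("dirichlet_base length must equal n_topics_true")
        if (self.dirichlet_base <= 0).any():
            raise ValueError("Dirichlet concentrations must be positive")
        if self.effect_sizes is None:
            self.effect_sizes = np.full(self.n_perturbations, 4.0)
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        if len(self.effect_sizes) != self.n_perturbations:
            raise ValueError("effect_sizes length must equal n_perturbations")
        if (self.effect_sizes < 0).any():
            raise ValueError("effect sizes must be nonnegative")
        if not 0 <= self.escaper_fraction < 1:
            raise ValueError("escaper_fraction must be in [0, 1)")


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated screen."""

    theta_true: np.ndarray          # cells x topics
    escaper: np.ndarray             # per-cell bool
    perturbation_topic: dict[str, int]
    perturbation_effect: dict[str, float]
    phi_true: np.ndarray            # topics x genes
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))


def _gene_ids(n: int) -> np.ndarray:
    return np.asarray([f"G{i + 1:04d}" for i in range(n)], dtype=object)


def _draw_phi(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Topic gene loadings; targets get a baseline loading.

    Screens target expressed genes, so each target gene is floored at
    4/n_genes before renormalization — its knockdown (not its absence) is
    what the filters should see.
    """
    phi = rng.dirichlet(np.full(cfg.n_genes, cfg.topic_concentration),
                        size=cfg.n_topics_true)
    floor = 4.0 / cfg.n_genes
    phi[:, : cfg.n_perturbations] = np.maximum(phi[:, : cfg.n_perturbations],
                                               floor)
    return phi / phi.sum(axis=1, keepdims=True)


def simulate_screen(config: SimConfig,
                    phi_true: np.ndarray | None = None
                    ) -> tuple[ScreenDataset, SimTruth]:
    """Generate one synthetic screen and its ground truth.

    ``phi_true`` may be supplied to share gene loadings across conditions.
    Fixed seed reproduces counts bitwise.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    if phi_true is None:
        phi_true = _draw_phi(cfg, rng)
    else:
        phi_true = np.asarray(phi_true, dtype=float)
        if phi_true.shape != (cfg.n_topics_true, cfg.n_genes):
            raise ValueError("phi_true shape mismatch")
    target_genes = genes[: cfg.n_perturbations]
    pert_topic = {g: i % cfg.n_topics_true for i, g in enumerate(target_genes)}
    pert_effect = {g: float(cfg.effect_sizes[i]) for i, g in enumerate(target_genes)}

    labels, thetas, escapers = [], [], []
    for g in target_genes:
        alpha_pert = cfg.dirichlet_base.copy()
        alpha_pert[pert_topic[g]] += pert_effect[g]
        for _ in range(cfg.n_cells_per_perturbation):
            is_escaper = rng.random() < cfg.escaper_fraction
            alpha = cfg.dirichlet_base if is_escaper else alpha_pert
            thetas.append(rng.dirichlet(alpha))
            labels.append(g)
            escapers.append(is_escaper)
    for _ in range(cfg.n_control_cells):
        thetas.append(rng.dirichlet(cfg.dirichlet_base))
        labels.append(CONTROL_LABEL)
        escapers.append(False)
    theta_true = np.vstack(thetas)
    labels = np.asarray(labels, dtype=object)
    escapers = np.asarray(escapers, dtype=bool)

    n_cells = len(labels)
    counts = np.zeros((n_cells, cfg.n_genes))
    gene_index = {g: i for i, g in enumerate(genes)}
    for c in range(n_cells):
        lib = rng.poisson(cfg.library_size)
        p = theta_true[c] @ phi_true
        counts[c] = rng.multinomial(lib, p / p.sum()) if lib > 0 else 0.0
        lab = labels[c]
        if lab != CONTROL_LABEL and not escapers[c]:
            gi = gene_index[lab]
            counts[c, gi] = np.floor(counts[c, gi] * cfg.knockdown_factor)
    if cfg.dropout_rate > 0:
        keep = rng.random(counts.shape) >= cfg.dropout_rate
        counts = counts * keep

    cells = np.asarray([f"cell{c + 1:05d}" for c in range(n_cells)], dtype=object)
    dataset = ScreenDataset(counts=counts, cell_ids=cells, gene_ids=genes,
                            perturbation=labels)
    truth = SimTruth(theta_true=theta_true, escaper=escapers,
                     perturbation_topic=pert_topic,
                     perturbation_effect=pert_effect, phi_true=phi_true,
                     labels=labels)
    return dataset, truth


def simulate_two_conditions(config: SimConfig, modulation: np.ndarray
                            ) -> tuple[tuple[ScreenDataset, SimTruth],
                                       tuple[ScreenDataset, SimTruth]]:
    """Two screens sharing gene loadings, with condition-2 effects scaled.

    ``modulation`` multiplies each perturbation's planted effect size in
    condition 2; factors must be nonnegative.
    """
    modulation = np.asarray(modulation, dtype=float)
    if len(modulation) != config.n_perturbations:
        raise ValueError("modulation length must equal n_perturbations")
    if (modulation < 0).any():
        raise ValueError("modulation factors must be nonnegative")
    rng = np.random.default_rng(config.seed)
    phi_true = _draw_phi(config, rng)
    cond1 = simulate_screen(replace(config, seed=(config.seed * 2 + 1) & 0x7FFFFFFF),
                            phi_true=phi_true)
    cfg2 = replace(config, effect_sizes=config.effect_sizes * modulation,
                   seed=(config.seed * 2 + 2) & 0x7FFFFFFF)
    cond2 = simulate_screen(cfg2, phi_true=phi_true)
    return cond1, cond2


def truth_table(dataset: ScreenDataset, truth: SimTruth) -> pd.DataFrame:
    """Ground truth as a flat per-cell table (for writing alongside MTX)."""
    tab = pd.DataFrame({"cell_id": dataset.cell_ids,
                        "perturbation": dataset.perturbation,
                        "escaper": truth.escaper})
    for t in range(truth.theta_true.shape[1]):
        tab[f"theta_true_{t}"] = truth.theta_true[:, t]
    return tab
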