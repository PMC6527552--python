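import logging

import numpy as np
import pytest

import topicscreen as ts

logging.getLogger("topicscreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_screen():
    """A small strong-effect screen shared by read-only tests."""
    cfg = ts.SimConfig(seed=42, n_perturbations=3, n_cells_per_perturbation=40,
                       n_control_cells=80, n_genes=150, library_size=500.0)
    return ts.simulate_screen(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_dataset(counts, labels, gene_ids=None, control_label="CTRL"):
    counts = np.asarray(counts, dtype=float)
    n, g = counts.shape
    return ts.ScreenDataset(
        counts=counts,
        cell_ids=np.asarray([f"c{i}" for i in range(n)], dtype=object),
        gene_ids=np.asarray(gene_ids if gene_ids is not None
                            else [f"g{j}" for j in range(g)], dtype=object),
        perturbation=np.asarray(labels, dtype=object),
        control_label=control_label,
    )
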