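"""QC thresholds and the screen-specific filter chain."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

import topicscreen as ts
from topicscreen.preprocess import QCThresholds, _cosine_matrix

from conftest import make_dataset


# -- QC ---------------------------------------------------------------------

def test_qc_thresholds_applied_per_cell():
    # cell 0: 630 detected genes (30 mito = 4.8%), 1260 UMI -> retained
    # cell 1: 499 detected genes -> removed
    # cell 2: 600 detected, 120 mito = 20% -> removed
    n_genes = 1000
    gene_ids = [f"MT-{j}" if j < 120 else f"g{j}" for j in range(n_genes)]
    counts = np.zeros((3, n_genes))
    counts[0, 90:720] = 2        # 630 detected, of which 30 are MT- (90..119)
    counts[1, 120:619] = 10      # 499 detected, no mito
    counts[2, :600] = 2          # 600 detected, 120 mito
    ds = make_dataset(counts, ["gX", "gX", "gX"], gene_ids=gene_ids)
    out = ts.qc_filter_cells(ds, QCThresholds(500, 1000, 0.10))
    assert list(out.cell_ids) == ["c0"]


def test_qc_identity_when_thresholds_trivial(small_screen):
    ds, _ = small_screen
    out = ts.qc_filter_cells(ds, QCThresholds(0, 0, 1.0))
    assert out.n_cells == ds.n_cells


def test_qc_all_removed_is_an_error(small_screen):
    ds, _ = small_screen
    with pytest.raises(ValueError, match="every cell"):
        ts.qc_filter_cells(ds, QCThresholds(10**6, 0, 1.0))


# -- imputation -------------------------------------------------------------

def test_impute_none_is_identity(small_screen):
    ds, _ = small_screen
    out = ts.impute(ds, "none")
    np.testing.assert_array_equal(out.counts, ds.counts)


def test_impute_shrink_fills_zeros_only():
    counts = np.array([[10.0, 0.0], [0.0, 0.0], [10.0, 0.0]])
    ds = make_dataset(counts, ["CTRL"] * 3)
    out = ts.impute(ds, "shrink", shrink_lambda=0.1)
    # gene 0: nonzero mean 10 -> zeros become 1.0; nonzero entries unchanged
    np.testing.assert_allclose(out.counts[:, 0], [10.0, 1.0, 10.0])
    # all-zero gene stays zero
    np.testing.assert_array_equal(out.counts[:, 1], 0.0)
    with pytest.raises(ValueError, match="unknown"):
        ts.impute(ds, "magic")


# -- zero-expression perturbations ------------------------------------------

def test_filter_zero_perturbations():
    counts = np.array([
        [0.0, 5.0, 1.0],   # G1 cell; gene G1 all-zero overall
        [0.0, 3.0, 1.0],   # G2 cell; gene G2 expressed
        [0.0, 2.0, 1.0],   # CTRL
        [0.0, 1.0, 1.0],   # NTC-like: no matching gene row
    ])
    ds = make_dataset(counts, ["G1", "G2", "CTRL", "NTClike"],
                      gene_ids=["G1", "G2", "other"])
    out, dropped = ts.filter_zero_perturbations(ds)
    assert dropped == ["G1"]
    assert set(out.perturbation) == {"G2", "CTRL", "NTClike"}


# -- KS DE genes ------------------------------------------------------------

def test_ks_de_genes_matches_scipy_oracle(rng):
    case = rng.poisson(5, size=(30, 5)).astype(float)
    control = rng.poisson(5, size=(40, 5)).astype(float)
    case[:, 2] += 100  # one clearly shifted gene
    hits = ts.ks_de_genes(case, control, alpha=0.05)
    expected = [g for g in range(5)
                if ks_2samp(case[:, g], control[:, g], method="asymp").pvalue
                < 0.05]
    assert hits == expected
    assert 2 in hits


def test_ks_de_genes_identical_sides_empty():
    x = np.tile(np.arange(10.0)[:, None], (1, 4))
    assert ts.ks_de_genes(x, x.copy()) == []
    with pytest.raises(ValueError, match="2 cells"):
        ts.ks_de_genes(x[:1], x)


# -- efficiency filter ------------------------------------------------------

def test_efficiency_filter_cosine_extremes():
    """A cell matching controls and orthogonal to peers is removed."""
    # genes: [a, b] DE between case and control by construction
    control = np.tile([10.0, 0.0, 1.0], (20, 1))
    peers = np.tile([0.0, 10.0, 1.0], (10, 1))
    escaper = np.array([[10.0, 0.0, 1.0]])
    counts = np.vstack([control, peers, escaper])
    labels = ["CTRL"] * 20 + ["P"] * 11
    ds = make_dataset(counts, labels)
    out, report = ts.efficiency_filter(ds)
    tab = report.cell_table.set_index("cell_id")
    assert bool(tab.loc["c30", "removed"])          # the control-like cell
    assert tab.loc["c30", "M_C"] > tab.loc["c30", "M_P"]
    assert not tab.loc["c20":"c29", "removed"].any()  # true-effect peers kept


def test_efficiency_filter_homogeneous_perturbation_untouched(rng):
    control = rng.poisson(5, size=(20, 6)).astype(float)
    case = np.tile([20.0, 0.0, 5.0, 5.0, 5.0, 0.0], (10, 1))
    ds = make_dataset(np.vstack([control, case]), ["CTRL"] * 20 + ["P"] * 10)
    out, report = ts.efficiency_filter(ds)
    assert not report.cell_table["removed"].any()
    assert (out.perturbation == "P").sum() == 10


def test_efficiency_filter_drop_fraction_rule():
    """A perturbation whose cells all mimic controls is dropped wholesale."""
    rng = np.random.default_rng(1)
    # each perturbed cell spikes its own private gene (silencing the rest),
    # making it closer to the control centroid than to any of its peers
    n_ctrl, n_pert = 30, 10
    n_genes = n_pert + 2
    control = np.zeros((n_ctrl, n_genes))
    control[:, -2] = 50.0                       # shared control direction
    control[:, :n_pert] = rng.poisson(5.0, (n_ctrl, n_pert))
    pert = np.zeros((n_pert, n_genes))
    for i in range(n_pert):
        pert[i, i] = 50.0                       # private spike
        pert[i, -2] = 30.0                      # still control-aligned
    ds = make_dataset(np.vstack([control, pert]),
                      ["CTRL"] * n_ctrl + ["P"] * n_pert)
    out, report = ts.efficiency_filter(ds, drop_fraction=0.90)
    assert report.removed_perturbations == ["P"]
    assert "P" not in set(out.perturbation)


def test_efficiency_filter_invariant_to_cell_and_gene_order(small_screen):
    ds, _ = small_screen
    sub = ds.subset_cells(np.isin(ds.perturbation, ["CTRL", "G0001"]))
    _, rep1 = ts.efficiency_filter(sub)
    rng = np.random.default_rng(7)
    cell_perm = rng.permutation(sub.n_cells)
    gene_perm = rng.permutation(sub.n_genes)
    shuffled = ts.ScreenDataset(
        counts=sub.counts[cell_perm][:, gene_perm],
        cell_ids=sub.cell_ids[cell_perm],
        gene_ids=sub.gene_ids[gene_perm],
        perturbation=sub.perturbation[cell_perm])
    _, rep2 = ts.efficiency_filter(shuffled)
    r1 = rep1.cell_table.set_index("cell_id")["removed"]
    r2 = rep2.cell_table.set_index("cell_id")["removed"]
    assert r1.sort_index().equals(r2.sort_index())


def test_cosine_zero_norm_rows_are_zero_similarity():
    a = np.array([[0.0, 0.0], [1.0, 0.0]])
    sim = _cosine_matrix(a, a)
    assert sim[0, 0] == 0.0 and sim[0, 1] == 0.0 and sim[1, 1] == 1.0


# -- minimum cells ----------------------------------------------------------

@pytest.mark.parametrize("n_cells,kept", [(29, False), (30, True)])
def test_min_cell_boundary(n_cells, kept):
    counts = np.ones((n_cells + 30, 2))
    labels = ["P"] * n_cells + ["CTRL"] * 30
    ds = make_dataset(counts, labels)
    out, dropped = ts.min_cell_filter(ds, min_cells=30)
    assert ("P" in set(out.perturbation)) is kept
    assert (dropped == ["P"]) is not kept


def test_min_cell_zero_is_identity_and_control_guard():
    ds = make_dataset(np.ones((5, 2)), ["P"] * 3 + ["CTRL"] * 2)
    out, dropped = ts.min_cell_filter(ds, min_cells=0)
    assert out.n_cells == 5 and dropped == []
    with pytest.raises(ValueError, match="control"):
        ts.min_cell_filter(ds, min_cells=3)


# -- purity of the chain ----------------------------------------------------

def test_filters_do_not_mutate_input(small_screen):
    ds, _ = small_screen
    before = ds.counts.copy()
    ts.qc_filter_cells(ds, QCThresholds(0, 0, 1.0))
    ts.impute(ds, "shrink")
    ts.filter_zero_perturbations(ds)
    ts.min_cell_filter(ds, min_cells=10)
    np.testing.assert_array_equal(ds.counts, before)
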