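"""Readers and writers for the formats the pipeline touches.

A screen is represented in memory as a :class:`ScreenDataset`: a dense
cells x genes count matrix plus per-cell perturbation labels. Counts come
in either as a Matrix Market triple (matrix + barcodes + genes, the usual
10x-style layout) or as a dense TSV/CSV table. Gene sets for topic
annotation use the standard GMT format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("topicscreen")

#: Reserved perturbation label for negative-control cells.
CONTROL_LABEL = "CTRL"


@dataclass
class ScreenDataset:
    """A single-cell CRISPR screen: counts, identifiers, perturbation labels.

    Parameters
    ----------
    counts
        Dense nonnegative matrix, cells x genes. Raw data are integers;
        imputation may introduce fractional values.
    cell_ids, gene_ids
        Unique identifier arrays matching the matrix dimensions.
    perturbation
        Per-cell label: a gene symbol, or :data:`CONTROL_LABEL` for
        negative-control cells.
    condition
        Optional per-cell experimental-condition tag.
    """

    counts: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    perturbation: np.ndarray
    condition: np.ndarray | None = None
    control_label: str = CONTROL_LABEL

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.perturbation = np.asarray(self.perturbation, dtype=object)
        if self.condition is not None:
            self.condition = np.asarray(self.condition, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(self.perturbation) != n_cells:
            raise ValueError("perturbation labels do not match cell count")
        if self.condition is not None and len(self.condition) != n_cells:
            raise ValueError("condition tags do not match cell count")
        if (self.counts < 0).any():
            raise ValueError("counts contain negative entries")
        for name, ids in (("cell_ids", self.cell_ids), ("gene_ids", self.gene_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"{name} contain duplicates")

    # -- convenience -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def control_mask(self) -> np.ndarray:
        return self.perturbation == self.control_label

    def labels(self, include_control: bool = False) -> list[str]:
        """Distinct perturbation labels, sorted; control excluded by default."""
        out = sorted(set(self.perturbation))
        if not include_control and self.control_label in out:
            out.remove(self.control_label)
        return out

    def subset_cells(self, mask: np.ndarray) -> "ScreenDataset":
        """New dataset restricted to cells where ``mask`` is True."""
        mask = np.asarray(mask)
        return ScreenDataset(
            counts=self.counts[mask].copy(),
            cell_ids=self.cell_ids[mask].copy(),
            gene_ids=self.gene_ids.copy(),
            perturbation=self.perturbation[mask].copy(),
            condition=None if self.condition is None else self.condition[mask].copy(),
            control_label=self.control_label,
        )

    def subset_genes(self, genes: list[str]) -> "ScreenDataset":
        idx = [list(self.gene_ids).index(g) for g in genes]
        return ScreenDataset(
            counts=self.counts[:, idx].copy(),
            cell_ids=self.cell_ids.copy(),
            gene_ids=np.asarray(genes, dtype=object),
            perturbation=self.perturbation.copy(),
            condition=None if self.condition is None else self.condition.copy(),
            control_label=self.control_label,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. from a GMT file) used to annotate topics."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")


def _read_lines(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def _read_perturbation_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in tab.columns]
    tab.columns = cols
    if "cell_id" not in cols or "perturbation" not in cols:
        raise ValueError(
            "perturbation file must have header columns cell_id, perturbation[, condition]"
        )
    return tab


def _assemble(counts: np.ndarray, barcodes: list[str], genes: list[str],
              pert_tab: pd.DataFrame, control_label: str) -> ScreenDataset:
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate cell barcodes")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids")
    known = set(barcodes)
    extra = set(pert_tab["cell_id"]) - known
    if extra:
        raise ValueError(
            f"perturbation file lists barcodes absent from the matrix: {sorted(extra)[:5]}"
        )
    # realign to barcode order; cells without an assignment are dropped
    lab = dict(zip(pert_tab["cell_id"], pert_tab["perturbation"]))
    cond_col = pert_tab["condition"] if "condition" in pert_tab.columns else None
    cond = dict(zip(pert_tab["cell_id"], cond_col)) if cond_col is not None else None
    keep, labels, conds = [], [], []
    for i, bc in enumerate(barcodes):
        label = lab.get(bc)
        if label is None or (isinstance(label, float) and np.isnan(label)) or label == "":
            continue
        keep.append(i)
        labels.append(label)
        if cond is not None:
            conds.append(cond[bc])
    dropped = len(barcodes) - len(keep)
    if dropped:
        logger.info("dropped %d cells without a perturbation assignment", dropped)
    return ScreenDataset(
        counts=counts[keep],
        cell_ids=np.asarray(barcodes, dtype=object)[keep],
        gene_ids=np.asarray(genes, dtype=object),
        perturbation=np.asarray(labels, dtype=object),
        condition=np.asarray(conds, dtype=object) if cond is not None else None,
        control_label=control_label,
    )


def read_mtx(matrix_path, barcodes_path, genes_path, perturbation_path,
             control_label: str = CONTROL_LABEL) -> ScreenDataset:
    """Read a Matrix Market screen (matrix + barcodes + genes + assignments).

    The on-disk orientation is resolved by matching the matrix dimensions
    against the barcode and gene file lengths; a square matrix whose two
    dimensions both match is ambiguous and rejected.
    """
    mat = scipy.io.mmread(matrix_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    barcodes = _read_lines(barcodes_path)
    genes = _read_lines(genes_path)
    nb, ng = len(barcodes), len(genes)
    r, c = mat.shape
    cells_first = (r, c) == (nb, ng)
    genes_first = (r, c) == (ng, nb)
    if cells_first and genes_first:
        raise ValueError(
            "ambiguous orientation: matrix is square and barcode/gene counts are equal"
        )
    if cells_first:
        counts = mat
    elif genes_first:
        counts = mat.T
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither {nb} barcodes x {ng} genes "
            "nor its transpose"
        )
    return _assemble(counts, barcodes, genes, _read_perturbation_table(perturbation_path),
                     control_label)


def read_counts_table(path, perturbation_path,
                      control_label: str = CONTROL_LABEL) -> ScreenDataset:
    """Read a dense gene x cell (or cell x gene) TSV/CSV count table.

    The first column holds gene ids and the header row cell ids, or the
    transpose; orientation is resolved against the perturbation file's
    barcodes.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    tab = pd.read_csv(path, sep=sep, index_col=0)
    if tab.empty:
        raise ValueError(f"empty count table: {path}")
    if not all(np.issubdtype(dt, np.number) for dt in tab.dtypes):
        raise ValueError("count table contains non-numeric cells")
    pert_tab = _read_perturbation_table(perturbation_path)
    cells = set(pert_tab["cell_id"])
    rows_are_cells = len(cells & set(map(str, tab.index))) >= len(
        cells & set(map(str, tab.columns))
    )
    if rows_are_cells:
        barcodes, genes = list(map(str, tab.index)), list(map(str, tab.columns))
        counts = tab.to_numpy(dtype=float)
    else:
        barcodes, genes = list(map(str, tab.columns)), list(map(str, tab.index))
        counts = tab.to_numpy(dtype=float).T
    return _assemble(counts, barcodes, genes, pert_tab, control_label)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, tab-separated genes)."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    for lineno, line in enumerate(_read_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
        name, d = fields[0], fields[1]
        if name in sets:
            raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
        genes = list(dict.fromkeys(g for g in fields[2:] if g))
        if not genes:
            raise ValueError(f"GMT line {lineno}: set {name!r} has no genes")
        sets[name] = genes
        desc[name] = d
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_ranking(table: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a pipeline table as TSV with fixed float precision.

    Rows are sorted by a ``rank`` column if present (ties by the first
    label-like column); floats are printed at 6 significant digits.
    """
    table = table.copy()
    sort_cols = [c for c in ("rank",) if c in table.columns]
    label_cols = [c for c in table.columns if table[c].dtype == object]
    if label_cols:
        sort_cols.append(label_cols[0])
    if sort_cols:
        table = table.sort_values(sort_cols, kind="mergesort")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_mtx(dataset: ScreenDataset, out_dir, perturbation_name="perturbations.tsv") -> None:
    """Write a dataset as MTX + barcodes + genes + perturbation TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sp = scipy.sparse.coo_matrix(dataset.counts.T)  # genes x cells, 10x convention
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp)
    (out / "barcodes.tsv").write_text("\n".join(dataset.cell_ids) + "\n")
    (out / "genes.tsv").write_text("\n".join(dataset.gene_ids) + "\n")
    tab = pd.DataFrame({"cell_id": dataset.cell_ids,
                        "perturbation": dataset.perturbation})
    if dataset.condition is not None:
        tab["condition"] = dataset.condition
    tab.to_csv(out / perturbation_name, sep="\t", index=False)
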