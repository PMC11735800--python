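"""scRNA-seq quality-control filters and the two-gene co-expression rule.

Cells with fewer than 300 detected genes, fewer than 3000 total transcripts,
or a mitochondrial-read percentage of at least 20% are removed; genes
detected in fewer than 10 cells are removed afterwards (cells first, one
pass).  A cell co-expresses two genes iff at least one transcript of each is
detected.  No normalization or clustering happens here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "CountMatrix",
    "QCReport",
    "filter_cells",
    "filter_genes",
    "qc_pipeline",
    "classify_coexpression",
    "COEXPRESS",
    "A_ONLY",
    "B_ONLY",
    "NEITHER",
]

LOW_GENES = "LOW_GENES"
LOW_COUNTS = "LOW_COUNTS"
HIGH_MITO = "HIGH_MITO"

COEXPRESS = "COEXPRESS"
A_ONLY = "A_ONLY"
B_ONLY = "B_ONLY"
NEITHER = "NEITHER"


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts, genes x cells, with mito flags."""

    counts: sparse.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    mito: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sparse.csc_matrix(self.counts)
        self.mito = np.asarray(self.mito, dtype=bool)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("counts shape does not match id lists")
        if len(self.mito) != len(self.gene_ids):
            raise ValueError("mito flags must match gene count")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def detected_genes_per_cell(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def total_counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def mito_pct_per_cell(self) -> np.ndarray:
        """100 * mito counts / total counts; NaN for empty cells."""
        total = self.total_counts_per_cell().astype(float)
        mito_counts = np.asarray(self.counts[self.mito].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, 100.0 * mito_counts / total, np.nan)

    def cells_per_gene(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()


@dataclass
class QCReport:
    cells_removed: dict[str, list[str]] = field(default_factory=dict)
    genes_removed: list[str] = field(default_factory=list)
    n_retained_cells: int = 0
    n_retained_genes: int = 0


def filter_cells(
    m: CountMatrix,
    min_genes: int = 300,
    min_counts: int = 3000,
    max_mito_pct: float = 20.0,
) -> tuple[CountMatrix, QCReport]:
    """Remove poor-quality cells.

    A cell is removed iff detected genes < ``min_genes`` OR total counts <
    ``min_counts`` OR mito percentage >= ``max_mito_pct`` (inclusive bound;
    exactly 20% is removed).  Empty cells count as 0% mito but fail the
    other bounds anyway.
    """
    detected = m.detected_genes_per_cell()
    totals = m.total_counts_per_cell()
    mito_pct = np.nan_to_num(m.mito_pct_per_cell(), nan=0.0)

    low_genes = detected < min_genes
    low_counts = totals < min_counts
    high_mito = mito_pct >= max_mito_pct
    keep = ~(low_genes | low_counts | high_mito)

    report = QCReport(
        cells_removed={
            LOW_GENES: [c for c, f in zip(m.cell_ids, low_genes) if f],
            LOW_COUNTS: [c for c, f in zip(m.cell_ids, low_counts) if f],
            HIGH_MITO: [c for c, f in zip(m.cell_ids, high_mito) if f],
        },
        n_retained_cells=int(keep.sum()),
        n_retained_genes=m.n_genes,
    )
    if not keep.any():
        warnings.warn("all cells removed by QC filters")
    filtered = CountMatrix(
        counts=m.counts[:, keep],
        gene_ids=list(m.gene_ids),
        cell_ids=[c for c, f in zip(m.cell_ids, keep) if f],
        mito=m.mito,
    )
    return filtered, report


def filter_genes(m: CountMatrix, min_cells: int = 10) -> tuple[CountMatrix, QCReport]:
    """Remove genes detected (count >= 1) in fewer than ``min_cells`` cells."""
    per_gene = m.cells_per_gene()
    keep = per_gene >= min_cells
    report = QCReport(
        genes_removed=[g for g, f in zip(m.gene_ids, keep) if not f],
        n_retained_cells=m.n_cells,
        n_retained_genes=int(keep.sum()),
    )
    filtered = CountMatrix(
        counts=m.counts[keep],
        gene_ids=[g for g, f in zip(m.gene_ids, keep) if f],
        cell_ids=list(m.cell_ids),
        mito=m.mito[keep],
    )
    return filtered, report


def qc_pipeline(
    m: CountMatrix,
    min_genes: int = 300,
    min_counts: int = 3000,
    max_mito_pct: float = 20.0,
    min_cells: int = 10,
    fixed_point: bool = False,
) -> tuple[CountMatrix, QCReport]:
    """Cells first, then genes, in one pass by default.

    With ``fixed_point=True`` the two filters are iterated until neither
    removes anything (gene removal can drop a cell's detected-gene count
    back below the threshold).
    """
    out = m
    all_cells_removed: dict[str, list[str]] = {}
    all_genes_removed: list[str] = []
    while True:
        cells_filtered, cell_report = filter_cells(
            out, min_genes, min_counts, max_mito_pct
        )
        out, gene_report = filter_genes(cells_filtered, min_cells)
        for reason, ids in cell_report.cells_removed.items():
            all_cells_removed.setdefault(reason, []).extend(ids)
        all_genes_removed.extend(gene_report.genes_removed)
        removed_any = (
            any(cell_report.cells_removed.values()) or gene_report.genes_removed
        )
        if not fixed_point or not removed_any:
            break
    report = QCReport(
        cells_removed=all_cells_removed,
        genes_removed=all_genes_removed,
        n_retained_cells=out.n_cells,
        n_retained_genes=out.n_genes,
    )
    return out, report


def classify_coexpression(
    m: CountMatrix, gene_a: str, gene_b: str
) -> dict[str, str]:
    """Per-cell co-expression label for two genes.

    COEXPRESS iff at least one transcript of *both* genes is detected;
    A_ONLY / B_ONLY / NEITHER otherwise.
    """
    try:
        ia = m.gene_ids.index(gene_a)
        ib = m.gene_ids.index(gene_b)
    except ValueError as exc:
        raise KeyError(f"gene not in matrix: {exc}") from None
    a = np.asarray(m.counts[ia].todense()).ravel() >= 1
    b = np.asarray(m.counts[ib].todense()).ravel() >= 1
    labels = np.where(
        a & b, COEXPRESS, np.where(a, A_ONLY, np.where(b, B_ONLY, NEITHER))
    )
    return dict(zip(m.cell_ids, (str(s) for s in labels)))
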