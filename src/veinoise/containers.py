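"""Core in-memory containers for genes-by-cells expression data.

Matrices are gene-major: rows are genes, columns are cells. Counts are stored
as scipy CSC sparse matrices of integers; normalized values as CSC floats.
Internal indexing is 0-based (Matrix Market files on disk are 1-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse


def dedupe_symbols(symbols: list[str]) -> list[str]:
    """Make symbols unique by appending ``.1``, ``.2``, ... in file order.

    The first occurrence keeps its bare name, matching the common convention
    for duplicate feature symbols in 10x feature tables.
    """
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


def _as_csc(m) -> sparse.csc_matrix:
    if sparse.issparse(m):
        return m.tocsc()
    return sparse.csc_matrix(np.asarray(m))


@dataclass
class CountMatrix:
    """Sparse UMI count matrix with gene and cell-barcode identifiers.

    Parameters
    ----------
    genes
        Ordered gene symbols (rows). Must be unique; use
        :func:`dedupe_symbols` first if they are not.
    barcodes
        Ordered cell identifiers (columns). Must be unique.
    counts
        Non-negative integer matrix, genes x cells. Any dense or sparse
        input is coerced to CSC int64.
    """

    genes: list[str]
    barcodes: list[str]
    counts: sparse.csc_matrix

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.barcodes = list(self.barcodes)
        m = _as_csc(self.counts)
        m.sum_duplicates()
        if m.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"counts shape {m.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if m.nnz:
            data = m.data
            if data.min() < 0:
                raise ValueError("counts must be non-negative")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integral")
        self.counts = m.astype(np.int64)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique (see dedupe_symbols)")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def toarray(self) -> np.ndarray:
        return self.counts.toarray()

    def subset_cells(self, idx) -> "CountMatrix":
        """New matrix restricted to cell columns ``idx`` (indices or bool mask)."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.genes, [self.barcodes[i] for i in idx], self.counts[:, idx]
        )

    def subset_genes(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            [self.genes[i] for i in idx], self.barcodes, self.counts[idx, :]
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression matrix (genes x cells, CSC float).

    Values are ln(1 + count * scale_factor / cell_total); a value is 0
    exactly where the underlying count is 0.
    """

    genes: list[str]
    barcodes: list[str]
    values: sparse.csc_matrix
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.barcodes = list(self.barcodes)
        m = _as_csc(self.values).astype(np.float64)
        if m.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("values shape does not match gene/barcode lists")
        if m.nnz and not np.all(np.isfinite(m.data)):
            raise ValueError("normalized values must be finite")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        self.values = m

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    def subset_cells(self, idx) -> "NormalizedMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(
            self.genes,
            [self.barcodes[i] for i in idx],
            self.values[:, idx],
            self.scale_factor,
        )
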