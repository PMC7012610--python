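"""Core in-memory containers shared across the pipeline.

The single-cell side of the package works on a genes × cells sparse UMI
matrix (the orientation the upstream droplet pipeline emits); the imaging
side works on per-cell coverage tables.  Both are thin, explicit wrappers
around scipy.sparse / pandas so that every downstream operation has an
unambiguous contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """Sparse genes × cells UMI count matrix with identifiers and metadata.

    Parameters
    ----------
    X
        Non-negative integer counts, shape ``(n_genes, n_cells)``; stored CSR.
    genes
        Gene symbols, length ``n_genes``.
    barcodes
        Cell barcodes, length ``n_cells``.
    obs
        Optional per-cell metadata (animal, hemisphere, ...), indexed by
        barcode.
    """

    X: sp.spmatrix
    genes: np.ndarray
    barcodes: np.ndarray
    obs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.genes = np.asarray(self.genes, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.X.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} cells"
            )
        if len(self.obs) == 0:
            self.obs = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        elif len(self.obs) != len(self.barcodes):
            raise ValueError("obs length does not match number of cells")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def subset(self, gene_idx=None, cell_idx=None) -> "CountMatrix":
        """Return a new CountMatrix restricted to the given indices."""
        gi = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        ci = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        return CountMatrix(
            X=self.X[gi][:, ci],
            genes=self.genes[gi],
            barcodes=self.barcodes[ci],
            obs=self.obs.iloc[ci].copy(),
        )

    def to_anndata(self):
        """Convert to an AnnData (cells × genes) for interop with scanpy."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.X.T.tocsr().astype(np.float32),
            obs=self.obs.copy(),
            var=pd.DataFrame(index=pd.Index(self.genes, name="gene")),
        )
        adata.obs_names = [str(b) for b in self.barcodes]
        return adata


@dataclass
class NormalizedMatrix:
    """Genes × cells log-normalized expression: ``log(1 + sf * c / total)``."""

    X: sp.spmatrix
    genes: np.ndarray
    barcodes: np.ndarray
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.genes = np.asarray(self.genes, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def gene_index(self, names) -> np.ndarray:
        """Indices of the given gene symbols; raises on unknown symbols."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)


@dataclass
class ScaledMatrix:
    """Genes × cells covariate-regressed, z-scored residuals (dense)."""

    X: np.ndarray
    genes: np.ndarray
    barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.genes = np.asarray(self.genes, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)


@dataclass
class EmbeddingSet:
    """PCA result: cell scores, gene loadings, explained variance per PC."""

    scores: np.ndarray  # cells x n_pcs
    loadings: np.ndarray  # genes x n_pcs
    explained_variance: np.ndarray
    genes: np.ndarray | None = None
    barcodes: np.ndarray | None = None

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]
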