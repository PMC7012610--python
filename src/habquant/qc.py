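"""Quality control, filtering, normalization, and covariate regression.

The preprocessing contract for droplet scRNA-seq of habenula tissue:
per-cell QC metrics (total UMIs, detected genes, mitochondrial fraction),
inclusive-bound cell filters, total-count and detection-fraction gene
filters, log-normalization to a fixed transcript total per cell, and
per-gene ordinary-least-squares regression of technical covariates
(nUMI, percent.mito) followed by z-scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, NormalizedMatrix, ScaledMatrix


@dataclass
class QCThresholds:
    """Inclusive per-cell QC bounds. Defaults are the full filter set
    (500 <= nUMI <= 18000, 200 <= nGene <= 6000, percent.mito <= 0.1;
    percent.mito is a fraction, so the "10%" bound is 0.1)."""

    numi_min: float = 500
    numi_max: float = 18000
    ngene_min: float = 200
    ngene_max: float = 6000
    mito_max: float = 0.1

    def __post_init__(self) -> None:
        if self.numi_min > self.numi_max or self.ngene_min > self.ngene_max:
            raise ValueError("QC threshold min exceeds max")


def qc_metrics(counts: CountMatrix, mito_prefix: str = "mt-") -> pd.DataFrame:
    """Per-cell nUMI, nGene, and mitochondrial UMI fraction.

    Mitochondrial genes are identified by a case-insensitive symbol prefix
    (mouse nomenclature ``mt-``). Cells with zero UMIs get percent.mito 0.
    """
    X = counts.X.tocsc()
    numi = np.asarray(X.sum(axis=0)).ravel()
    ngene = np.asarray((X > 0).sum(axis=0)).ravel()
    is_mito = np.array(
        [str(g).lower().startswith(mito_prefix.lower()) for g in counts.genes]
    )
    mito_umi = (
        np.asarray(X[is_mito].sum(axis=0)).ravel()
        if is_mito.any()
        else np.zeros_like(numi, dtype=float)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pmito = np.where(numi > 0, mito_umi / np.maximum(numi, 1), 0.0)
    return pd.DataFrame(
        {"nUMI": numi, "nGene": ngene, "percent.mito": pmito},
        index=pd.Index(counts.barcodes, name="barcode"),
    )


def qc_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Median / min / max / IQR for nUMI and nGene across cells.

    IQR uses linear-interpolation quantiles (Q3 - Q1).
    """
    if len(metrics) == 0:
        raise ValueError("qc_summary requires at least one cell")
    rows = {}
    for col in ("nUMI", "nGene"):
        v = metrics[col].to_numpy(dtype=float)
        q1, q3 = np.percentile(v, [25, 75])
        rows[col] = {
            "median": float(np.median(v)),
            "min": float(v.min()),
            "max": float(v.max()),
            "IQR": float(q3 - q1),
        }
    return pd.DataFrame(rows).T


def filter_cells(metrics: pd.DataFrame, thresholds: QCThresholds) -> np.ndarray:
    """Indices of cells passing all QC bounds (inclusive)."""
    keep = (
        (metrics["nUMI"] >= thresholds.numi_min)
        & (metrics["nUMI"] <= thresholds.numi_max)
        & (metrics["nGene"] >= thresholds.ngene_min)
        & (metrics["nGene"] <= thresholds.ngene_max)
        & (metrics["percent.mito"] <= thresholds.mito_max)
    )
    return np.flatnonzero(keep.to_numpy())


def filter_genes(
    counts: CountMatrix,
    min_total_umi: float | None = 5,
    min_cell_frac: float | None = None,
) -> np.ndarray:
    """Indices of genes kept: total UMIs strictly > ``min_total_umi`` and
    detected in at least ``min_cell_frac`` of cells.

    Either criterion may be disabled with None. The default total-count
    bound is strict (a gene with exactly 5 UMIs is removed); the subset
    detection bound used after splitting neurons is 0.5% of cells.
    """
    X = counts.X.tocsr()
    keep = np.ones(counts.n_genes, dtype=bool)
    if min_total_umi is not None:
        keep &= np.asarray(X.sum(axis=1)).ravel() > min_total_umi
    if min_cell_frac is not None and counts.n_cells > 0:
        det_frac = np.asarray((X > 0).sum(axis=1)).ravel() / counts.n_cells
        keep &= det_frac >= min_cell_frac
    return np.flatnonzero(keep)


def lognormalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Log-normalize: ``value = ln(1 + scale_factor * c / cell_total)``.

    Sparsity is preserved (zeros map to zero). Cells with zero total UMIs
    are an error; their barcodes are listed.
    """
    X = counts.X.tocsc().astype(float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = list(counts.barcodes[totals == 0])
        raise ValueError(f"cells with zero counts cannot be normalized: {bad}")
    Xn = X.multiply(scale_factor / totals)  # broadcasts over columns
    Xn = sp.csc_matrix(Xn)
    Xn.data = np.log1p(Xn.data)
    return NormalizedMatrix(
        X=Xn.tocsr(),
        genes=counts.genes,
        barcodes=counts.barcodes,
        scale_factor=scale_factor,
    )


def scale_regress(
    norm: NormalizedMatrix,
    covariates: pd.DataFrame | np.ndarray | None = None,
    clip: float | None = None,
) -> ScaledMatrix:
    """Regress covariates out of each gene and z-score the residuals.

    Per gene, ordinary least squares on ``[intercept | covariates]``
    (the identity-link Gaussian GLM); residuals are centered and scaled to
    unit variance. Constant genes come back as all-zero rows; collinear
    covariate columns are dropped with a warning. ``clip`` truncates
    |z| > clip.
    """
    n_cells = norm.n_cells
    if n_cells < 2:
        raise ValueError("scale_regress requires at least 2 cells")
    if covariates is None:
        C = np.empty((n_cells, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if not np.isfinite(C).all():
            raise ValueError("covariates must be finite")
    design = np.column_stack([np.ones(n_cells), C])
    # drop columns that add no rank (collinear covariates)
    keep_cols = [0]
    for j in range(1, design.shape[1]):
        cand = design[:, keep_cols + [j]]
        if np.linalg.matrix_rank(cand) > len(keep_cols):
            keep_cols.append(j)
        else:
            warnings.warn(f"dropping collinear covariate column {j - 1}")
    design = design[:, keep_cols]

    Y = np.asarray(norm.X.todense(), dtype=float)  # genes x cells
    beta, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
    resid = Y - (design @ beta).T
    mean = resid.mean(axis=1, keepdims=True)
    sd = resid.std(axis=1, ddof=0, keepdims=True)
    nonconst = sd.ravel() > 1e-12
    Z = np.zeros_like(resid)
    Z[nonconst] = (resid[nonconst] - mean[nonconst]) / sd[nonconst]
    if clip is not None:
        Z = np.clip(Z, -clip, clip)
    return ScaledMatrix(X=Z, genes=norm.genes, barcodes=norm.barcodes)


def preprocess(
    counts: CountMatrix,
    thresholds: QCThresholds | None = None,
    min_total_umi: float | None = 5,
    min_cell_frac: float | None = None,
    mito_prefix: str = "mt-",
    blacklist: set | None = None,
) -> tuple[CountMatrix, pd.DataFrame, NormalizedMatrix, ScaledMatrix]:
    """Full preprocessing chain: QC -> cell filter -> gene filter ->
    log-normalize -> covariate regression.

    Gene filtering runs after cell filtering so detection fractions refer
    to the kept cells. ``blacklist`` removes named barcodes (the external
    stand-in for manual low-quality-library curation).
    """
    thresholds = thresholds or QCThresholds()
    metrics = qc_metrics(counts, mito_prefix=mito_prefix)
    keep_cells = filter_cells(metrics, thresholds)
    if blacklist:
        keep_cells = np.array(
            [i for i in keep_cells if counts.barcodes[i] not in blacklist], dtype=int
        )
    filtered = counts.subset(cell_idx=keep_cells)
    keep_genes = filter_genes(filtered, min_total_umi, min_cell_frac)
    filtered = filtered.subset(gene_idx=keep_genes)
    norm = lognormalize(filtered)
    kept_metrics = metrics.iloc[keep_cells]
    cov = kept_metrics[["nUMI", "percent.mito"]]
    scaled = scale_regress(norm, cov)
    return filtered, kept_metrics, norm, scaled
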