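"""Hurdle-model differential expression between cell groups.

A two-part (MAST-style) test per gene: a logistic model for whether the
gene is detected in a cell, and a Gaussian model for the log-normalized
expression among the detected cells. The per-cell detection rate (CDR,
the fraction of all genes a cell expresses) enters both parts as a
nuisance covariate by default. The combined likelihood-ratio statistic is
the sum of the two component deviance differences, compared against a
chi-square with one degree of freedom per estimable component. Genes are
prefiltered on detection fraction and natural-log fold change, and
p-values are Bonferroni-corrected over the tested genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import NormalizedMatrix

try:  # statsmodels moved/renamed this across versions
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    class PerfectSeparationError(Exception):
        pass


@dataclass
class DEConfig:
    logfc_threshold: float = 0.25
    min_pct: float = 0.1
    alpha: float = 0.05
    include_cdr: bool = True

    def __post_init__(self) -> None:
        if self.logfc_threshold < 0 or self.min_pct < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _group_indices(labels, contrast):
    labels = np.asarray(labels)
    set_a, set_b = contrast
    a = np.flatnonzero(np.isin(labels, list(np.atleast_1d(list(set_a)))))
    b = np.flatnonzero(np.isin(labels, list(np.atleast_1d(list(set_b)))))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both contrast groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("contrast groups overlap")
    return a, b


def _log_fold_change(Xa, Xb) -> np.ndarray:
    """ln(mean(expm1(x)) + 1) in group A minus the same in group B."""
    ma = np.asarray(Xa.expm1().mean(axis=1)).ravel()
    mb = np.asarray(Xb.expm1().mean(axis=1)).ravel()
    return np.log(ma + 1.0) - np.log(mb + 1.0)


def gene_prefilter(
    norm: NormalizedMatrix, labels, contrast, config: DEConfig | None = None
) -> pd.DataFrame:
    """Per-gene detection fractions and logFC, with a ``tested`` flag.

    A gene is tested iff max(pct.1, pct.2) >= min_pct and
    |avg_logFC| >= logfc_threshold.
    """
    config = config or DEConfig()
    a, b = _group_indices(labels, contrast)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each contrast group needs at least 3 cells")
    Xa, Xb = norm.X[:, a], norm.X[:, b]
    pct1 = np.asarray((Xa > 0).mean(axis=1)).ravel()
    pct2 = np.asarray((Xb > 0).mean(axis=1)).ravel()
    lfc = _log_fold_change(Xa, Xb)
    tested = (np.maximum(pct1, pct2) >= config.min_pct) & (
        np.abs(lfc) >= config.logfc_threshold
    )
    return pd.DataFrame(
        {
            "gene": norm.genes,
            "avg_logFC": lfc,
            "pct.1": pct1,
            "pct.2": pct2,
            "tested": tested,
        }
    )


def _gaussian_lrt(y, design_full, design_null) -> float:
    """2 * (llf_full - llf_null) for Gaussian ML fits."""
    with np.errstate(divide="ignore"):
        full = sm.OLS(y, design_full).fit()
        null = sm.OLS(y, design_null).fit()
        dev = 2.0 * (full.llf - null.llf)
    if not np.isfinite(dev):  # zero-residual degenerate fit
        dev = 1400.0
    return max(0.0, dev)


def _logistic_deviance_diff(y, design_full, design_null) -> float:
    full = sm.GLM(y, design_full, family=sm.families.Binomial()).fit(maxiter=100)
    null = sm.GLM(y, design_null, family=sm.families.Binomial()).fit(maxiter=100)
    return max(0.0, null.deviance - full.deviance)


def hurdle_test(
    expr: np.ndarray,
    group: np.ndarray,
    cdr: np.ndarray | None = None,
    config: DEConfig | None = None,
) -> dict:
    """Two-part hurdle LRT for one gene.

    Parameters
    ----------
    expr
        Log-normalized expression per cell.
    group
        Binary group indicator per cell.
    cdr
        Optional per-cell detection rate covariate (used when
        ``config.include_cdr``).

    Returns a dict with ``p_val``, the summed LRT ``stat``, its ``df``,
    per-component deviances, and a ``separation`` flag set when the
    logistic part hit perfect separation and fell back to a Fisher exact
    test on the 2×2 detection table.
    """
    config = config or DEConfig()
    expr = np.asarray(expr, dtype=float)
    group = np.asarray(group, dtype=float)
    n = len(expr)
    detect = (expr > 0).astype(float)
    covs = [np.ones(n), group]
    if config.include_cdr and cdr is not None:
        c = np.asarray(cdr, dtype=float)
        covs.append(c - c.mean())
    design_full = np.column_stack(covs)
    design_null = np.delete(design_full, 1, axis=1)

    dev_disc, df_disc, separation = 0.0, 0, False
    if 0 < detect.sum() < n:
        # detection perfectly aligned with group -> logistic MLE diverges
        g1 = group == 1
        perfectly_separated = (
            detect[g1].min() > detect[~g1].max()
            or detect[~g1].min() > detect[g1].max()
        )
        try:
            if perfectly_separated:
                raise PerfectSeparationError
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dev_disc = _logistic_deviance_diff(detect, design_full, design_null)
            if not np.isfinite(dev_disc):
                raise PerfectSeparationError
            df_disc = 1
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            table = [
                [np.sum(detect[group == g] == d) for d in (1, 0)] for g in (1, 0)
            ]
            p_fisher = stats.fisher_exact(table)[1]
            dev_disc = float(stats.chi2.isf(min(max(p_fisher, 1e-300), 1.0), 1))
            df_disc, separation = 1, True

    dev_cont, df_cont = 0.0, 0
    det_idx = np.flatnonzero(detect)
    if det_idx.size >= 2:
        g_det = group[det_idx]
        if 0 < g_det.sum() < det_idx.size:  # group coefficient estimable
            dev_cont = _gaussian_lrt(
                expr[det_idx], design_full[det_idx], design_null[det_idx]
            )
            df_cont = 1

    stat = dev_disc + dev_cont
    df = df_disc + df_cont
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return {
        "p_val": p,
        "stat": stat,
        "df": df,
        "dev_discrete": dev_disc,
        "dev_continuous": dev_cont,
        "separation": separation,
    }


def find_markers(
    norm: NormalizedMatrix,
    labels,
    contrast,
    config: DEConfig | None = None,
) -> pd.DataFrame:
    """Marker table for one contrast: prefilter, hurdle test per gene,
    Bonferroni over the tested genes, sorted by p-value.

    ``contrast`` is a pair of label sets (group 1, group 2); ``avg_logFC``
    is positive for genes higher in group 1.
    """
    config = config or DEConfig()
    pre = gene_prefilter(norm, labels, contrast, config)
    tested = np.flatnonzero(pre["tested"].to_numpy())
    if tested.size == 0:
        warnings.warn("no genes pass the DE prefilter")
        return pd.DataFrame(
            columns=["gene", "p_val", "avg_logFC", "pct.1", "pct.2", "p_val_adj"]
        )
    a, b = _group_indices(labels, contrast)
    cells = np.concatenate([a, b])
    group = np.concatenate([np.ones(len(a)), np.zeros(len(b))])
    X = norm.X[:, cells].tocsr()
    cdr = np.asarray((X > 0).mean(axis=0)).ravel() if config.include_cdr else None
    rows = []
    for gi in tested:
        expr = np.asarray(X[gi].todense()).ravel()
        res = hurdle_test(expr, group, cdr, config)
        rows.append(
            {
                "gene": pre["gene"].iloc[gi],
                "p_val": res["p_val"],
                "avg_logFC": pre["avg_logFC"].iloc[gi],
                "pct.1": pre["pct.1"].iloc[gi],
                "pct.2": pre["pct.2"].iloc[gi],
                "separation": res["separation"],
            }
        )
    table = pd.DataFrame(rows)
    table["p_val_adj"] = np.minimum(1.0, table["p_val"] * len(tested))
    return table.sort_values("p_val", kind="stable").reset_index(drop=True)
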