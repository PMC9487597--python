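"""Normalization, per-gene scaling and highly-variable-gene selection.

The preprocessing contract for every dataset is: log-normalize counts to a
common library size, standardize each gene to mean 0 / sample variance 1
(ddof=1 everywhere), and embed on highly variable genes shared between the
datasets being integrated.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import CountMatrix, NormalizedMatrix, ScaledMatrix


def lognormalize(cm: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Log-normalize counts: entry = ln(1 + X_ij / librarysize_j * scale_factor).

    Raises if any cell has zero total count (its library size is undefined).
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    sparse = sp.issparse(cm.values)
    colsums = np.asarray(cm.values.sum(axis=0)).ravel()
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        names = ", ".join(str(cm.cell_ids[i]) for i in zero[:10])
        raise ValueError(f"cells with zero total count: {names}")
    if sparse:
        mat = cm.values.tocsc().astype(float)
        # scale columns, then log1p on the nonzero data only: zeros stay zero
        inv = sp.diags(scale_factor / colsums)
        mat = mat @ inv
        mat.data = np.log1p(mat.data)
        values: "np.ndarray | sp.spmatrix" = mat
    else:
        values = np.log1p(np.asarray(cm.values, dtype=float)
                          / colsums * scale_factor)
    return NormalizedMatrix(
        values=values,
        gene_ids=cm.gene_ids,
        cell_ids=cm.cell_ids,
        platform=cm.platform,
        scale_factor=float(scale_factor),
        counts=cm.values,
    )


def scale_genes(nm: NormalizedMatrix) -> ScaledMatrix:
    """Scale each gene to unit sample variance (ddof=1), without centering.

    Scaling must stay purely multiplicative: the downstream re-scaling step
    divides these values by subset standard deviations, which can cancel a
    composition-induced variance distortion but not an additive offset that
    per-dataset centering would introduce.  (PCA centers features on the
    combined data, so embeddings are unaffected.)  Genes with zero variance
    become all-zero rows.
    """
    dense = nm.dense()
    sds = dense.std(axis=1, ddof=1, keepdims=True)
    nonconst = sds.ravel() > 0
    out = dense.copy()
    out[nonconst] /= sds[nonconst]
    out[~nonconst] = 0.0
    return ScaledMatrix(
        values=out,
        gene_ids=nm.gene_ids,
        cell_ids=nm.cell_ids,
        platform=nm.platform,
    )


def _vst_statistic(counts: "np.ndarray | sp.spmatrix", span: float = 0.3) -> np.ndarray:
    """Variance-stabilized dispersion: variance of clipped standardized counts.

    A lowess fit of log10(variance) against log10(mean) across genes gives each
    gene an expected standard deviation; counts are standardized with it,
    clipped at sqrt(n_cells), and the statistic is the variance of the result.
    """
    if sp.issparse(counts):
        x = np.asarray(counts.todense(), dtype=float)
    else:
        x = np.asarray(counts, dtype=float)
    n_genes, n_cells = x.shape
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1) if n_cells > 1 else np.zeros(n_genes)
    stat = np.zeros(n_genes)
    fit_mask = (mean > 0) & (var > 0)
    if fit_mask.sum() < 2:
        return var
    lx = np.log10(mean[fit_mask])
    ly = np.log10(var[fit_mask])
    fitted = lowess(ly, lx, frac=span, return_sorted=False)
    exp_sd = np.sqrt(10.0 ** fitted)
    clip = np.sqrt(n_cells)
    z = (x[fit_mask] - mean[fit_mask, None]) / exp_sd[:, None]
    np.clip(z, -clip, clip, out=z)
    stat[fit_mask] = z.var(axis=1, ddof=1)
    return stat


def _dispersion_statistic(values: "np.ndarray | sp.spmatrix") -> np.ndarray:
    """Simple dispersion of log-normalized values: variance / mean."""
    if sp.issparse(values):
        x = np.asarray(values.todense(), dtype=float)
    else:
        x = np.asarray(values, dtype=float)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1) if x.shape[1] > 1 else np.zeros(x.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    return disp


def hvg_statistic(nm: NormalizedMatrix, method: str = "vst") -> np.ndarray:
    """Per-gene variability statistic (higher = more variable)."""
    if method == "vst":
        if nm.counts is None:
            warnings.warn("no counts stored; falling back to dispersion statistic")
            return _dispersion_statistic(nm.values)
        return _vst_statistic(nm.counts)
    if method == "dispersion":
        return _dispersion_statistic(nm.values)
    raise ValueError(f"unknown hvg method {method!r}; expected vst or dispersion")


def select_hvg(nm: NormalizedMatrix, n: int = 4000, method: str = "vst") -> list:
    """Top-``n`` highly variable genes, ties broken by lexicographic gene id.

    If ``n`` is at least the gene count, all genes are returned (with a
    warning when it exceeds it).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    gene_ids = nm.gene_ids.astype(str)
    if n > len(gene_ids):
        warnings.warn(
            f"requested {n} variable genes but only {len(gene_ids)} genes exist; "
            "returning all genes"
        )
        n = len(gene_ids)
    stat = hvg_statistic(nm, method=method)
    order = sorted(range(len(gene_ids)), key=lambda i: (-stat[i], gene_ids[i]))
    return [gene_ids[i] for i in order[:n]]


def shared_hvg(list_a: Sequence[str], list_b: Sequence[str]) -> list:
    """Genes highly variable in both datasets, sorted lexicographically."""
    common = sorted(set(map(str, list_a)) & set(map(str, list_b)))
    if not common:
        raise ValueError(
            "no shared highly variable genes between the datasets; "
            "increase the number of variable genes selected per dataset"
        )
    return common
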