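"""Normalization, cv-mean variable-gene selection, PCA, and neighbor graph.

Every downstream stage works on the ``normalized`` layer produced here:
counts scaled per cell to the median library size, then ``log(1 + x)``.
Highly variable genes are ranked by excess coefficient of variation over a
binned-median CV-vs-mean trend ("cv-mean enriched" genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp


def _dense_layer(adata: ad.AnnData, layer: str) -> np.ndarray:
    if layer == "X":
        mat = adata.X
    else:
        if layer not in adata.layers:
            raise ValueError(f"layer {layer!r} missing; run normalize_log first"
                             if layer == "normalized" else f"layer {layer!r} missing")
        mat = adata.layers[layer]
    return np.asarray(mat.todense(), dtype=float) if sp.issparse(mat) else np.asarray(mat, dtype=float)


def normalize_log(adata: ad.AnnData) -> ad.AnnData:
    """Add a ``normalized`` layer: median-library scaling then log1p.

    Zeros stay zero, and within-cell rank order of genes is preserved.
    Cells with zero total counts are an error (QC should remove them).
    """
    X = sp.csr_matrix(adata.X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = int((totals == 0).sum())
        raise ValueError(f"{bad} cell(s) with zero total counts; run qc_filter first")
    target = float(np.median(totals))
    scaled = sp.diags(target / totals) @ X
    scaled.data = np.log1p(scaled.data)
    adata.layers["normalized"] = scaled.tocsr()
    return adata


@dataclass
class HVGSelection:
    """Result of cv-mean variable-gene selection."""

    selected_genes: list[str]
    stats: pd.DataFrame  # per gene: mean, cv, trend_cv, residual_cv, selected


def select_hvg_cv_mean(adata: ad.AnnData, n: int = 2000, n_bins: int = 20) -> HVGSelection:
    """Top ``n`` genes by CV in excess of the CV-vs-mean trend.

    The trend is the per-bin median CV over ``n_bins`` equal-count mean
    bins, linearly interpolated between bin centers; the excess is
    studentized by the interpolated within-bin MAD so that the noisy
    low-expression bins (where CV scales steeply with mean) do not dominate
    the ranking. Ties in the residual are broken lexicographically by
    symbol so the selection is order-invariant.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if adata.n_vars < 10:
        raise ValueError("need at least 10 genes to fit a CV-mean trend")
    Y = _dense_layer(adata, "normalized")
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1) if Y.shape[0] > 1 else np.zeros(Y.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)

    expressed = mean > 0
    order = np.argsort(mean[expressed], kind="stable")
    idx = np.flatnonzero(expressed)[order]
    n_expressed = idx.size
    bins = np.array_split(np.arange(n_expressed), min(n_bins, max(1, n_expressed)))
    centers = np.array([mean[idx[b]].mean() for b in bins if b.size])
    med_cv = np.array([np.median(cv[idx[b]]) for b in bins if b.size])
    mad_cv = np.array(
        [np.median(np.abs(cv[idx[b]] - np.median(cv[idx[b]]))) for b in bins if b.size]
    )
    mad_floor = max(1e-8, 0.1 * np.median(mad_cv[mad_cv > 0])) if (mad_cv > 0).any() else 1e-8
    trend = np.interp(mean, centers, med_cv)  # clamped at the end bins
    spread = np.maximum(np.interp(mean, centers, mad_cv), mad_floor)
    residual = np.where(expressed, (cv - trend) / spread, -np.inf)

    symbols = np.asarray(adata.var_names)
    rank_order = np.lexsort((symbols, -residual))
    n_take = min(n, int(np.isfinite(residual).sum()))
    chosen = rank_order[:n_take]
    selected = np.zeros(adata.n_vars, dtype=bool)
    selected[chosen] = True
    stats = pd.DataFrame(
        {"mean": mean, "cv": cv, "trend_cv": trend,
         "residual_cv": np.where(np.isfinite(residual), residual, np.nan),
         "selected": selected},
        index=adata.var_names,
    )
    return HVGSelection(selected_genes=[symbols[i] for i in chosen], stats=stats)


@dataclass
class Embedding:
    """Low-dimensional cell coordinates from a linear decomposition."""

    coordinates: np.ndarray  # cells x d
    method: str
    genes: list[str]
    explained_variance: np.ndarray = field(default_factory=lambda: np.array([]))
    explained_variance_ratio: np.ndarray = field(default_factory=lambda: np.array([]))
    loadings: np.ndarray | None = None  # genes x d


def _standardize(Y: np.ndarray, clip: float = 10.0) -> np.ndarray:
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (Y - mean) / sd
    return np.clip(Z, -clip, clip)


def pca(adata: ad.AnnData, genes=None, d: int = 50) -> Embedding:
    """PCA on centered, unit-scaled genes of the normalized layer.

    Gene z-scores are clipped at +/-10 SD before decomposition. Component
    signs are fixed by making each component's largest-magnitude gene
    loading positive.
    """
    if genes is not None:
        view = adata[:, list(genes)]
    else:
        view = adata
    Y = _dense_layer(view, "normalized")
    n, p = Y.shape
    if d > min(n, p):
        raise ValueError(f"d={d} exceeds min(cells, genes)={min(n, p)}")
    Z = _standardize(Y)
    Z = Z - Z.mean(axis=0)  # re-center after clipping
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    evar = S**2 / max(n - 1, 1)
    total = (Z**2).sum() / max(n - 1, 1)
    # sign convention: largest-|loading| positive per component
    for k in range(d):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    coords = U[:, :d] * S[:d]
    return Embedding(
        coordinates=coords,
        method="pca",
        genes=list(view.var_names),
        explained_variance=evar[:d],
        explained_variance_ratio=evar[:d] / total if total > 0 else evar[:d],
        loadings=Vt[:d].T,
    )


def neighbor_graph(embedding, k: int) -> sp.csr_matrix:
    """Symmetric (union) k-nearest-neighbor adjacency in embedding space.

    Accepts an :class:`Embedding` or a raw coordinate array. Entries are 1
    for an edge; self-loops are excluded. Ties at equal distance resolve to
    the lower cell index (stable neighbor ordering).
    """
    coords = embedding.coordinates if isinstance(embedding, Embedding) else np.asarray(embedding)
    n = coords.shape[0]
    if k <= 0:
        raise ValueError("k must be > 0")
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    # brute-force distances with a stable sort so equal distances resolve
    # to the lower cell index
    d2 = (
        (coords**2).sum(axis=1)[:, None]
        + (coords**2).sum(axis=1)[None, :]
        - 2 * coords @ coords.T
    )
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    cols = order.ravel()
    A = sp.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    A = ((A + A.T) > 0).astype(float)
    return A.tocsr()
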