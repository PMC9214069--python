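"""Pseudotime, pseudotemporal profiles, and steady-state RNA velocity.

Pseudotime is the diffusion distance from a root cell on the k-nearest
neighbor graph, min-max scaled to [0, 1]. The velocity fit follows the
steady-state model: for each gene the unspliced/spliced ratio at
equilibrium gives a slope ``gamma_hat`` (an origin-constrained least
squares fit on cells in the extreme quantiles of spliced expression);
cells above the steady-state line are upregulating the gene, cells below
are downregulating it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh

from .preprocess import Embedding, _dense_layer
from .signatures import GeneSignature, score_signature


@dataclass
class PseudotimeResult:
    """Cells ordered along a maturation continuum."""

    pseudotime: np.ndarray  # in [0, 1], root at 0
    root: int
    root_strategy: str


def _diffusion_coords(coords: np.ndarray, graph: sp.spmatrix, n_comps: int = 10):
    """Diffusion-map coordinates from a Gaussian-weighted neighbor graph."""
    graph = sp.csr_matrix(graph)
    A = graph.maximum(graph.T)
    rows, cols = A.nonzero()
    d2 = ((coords[rows] - coords[cols]) ** 2).sum(axis=1)
    pos = d2[d2 > 0]
    sigma2 = np.median(pos) if pos.size else 1.0
    w = np.exp(-d2 / sigma2)
    W = sp.csr_matrix((w, (rows, cols)), shape=A.shape)
    deg = np.asarray(W.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    Dinv = sp.diags(1.0 / np.sqrt(deg))
    M = Dinv @ W @ Dinv  # symmetric, eigenvalues in [-1, 1]
    k = min(n_comps + 1, M.shape[0] - 1)
    vals, vecs = eigsh(M, k=k, which="LA", v0=np.ones(M.shape[0]) / np.sqrt(M.shape[0]))
    order = np.argsort(-vals)
    vals, vecs = vals[order], vecs[:, order]
    # drop the trivial stationary component; weight by lambda / (1 - lambda)
    vals, vecs = vals[1:], vecs[:, 1:]
    psi = Dinv @ vecs  # right eigenvectors of the Markov matrix
    scale = np.where(vals < 1 - 1e-10, vals / np.maximum(1 - vals, 1e-10), 0.0)
    return psi * scale


def pseudotime(
    adata: ad.AnnData,
    embedding,
    graph: sp.spmatrix,
    root,
    n_comps: int = 10,
) -> PseudotimeResult:
    """Diffusion distance from a root cell, scaled to [0, 1].

    ``root`` is a cell barcode, an integer index, or a
    :class:`~retinodiff.signatures.GeneSignature` whose maximal scorer
    becomes the root (e.g. a progenitor signature to orient a
    progenitor-to-RPE axis). The neighbor graph must be connected.
    """
    coords = embedding.coordinates if isinstance(embedding, Embedding) else np.asarray(embedding)
    n_comp_graph, labels = connected_components(sp.csr_matrix(graph), directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"neighbor graph has {n_comp_graph} connected components "
            f"(sizes {sizes.tolist()}); pseudotime needs a connected graph"
        )
    if isinstance(root, GeneSignature):
        scores = score_signature(adata, root)
        best = scores.max()
        ties = np.flatnonzero(scores == best)
        if len(ties) > 1:
            warnings.warn(f"{len(ties)} cells tie for the root; using the lowest index")
        root_idx = int(ties[0])
        strategy = f"max_signature:{root.name}"
    elif isinstance(root, (int, np.integer)):
        root_idx = int(root)
        strategy = "cell_index"
    else:
        matches = np.flatnonzero(adata.obs_names == str(root))
        if len(matches) == 0:
            raise ValueError(f"root cell {root!r} not found")
        root_idx = int(matches[0])
        strategy = "cell_id"
    dc = _diffusion_coords(coords, graph, n_comps=n_comps)
    dist = np.linalg.norm(dc - dc[root_idx], axis=1)
    if dist.max() > 0:
        dist = dist / dist.max()
    return PseudotimeResult(pseudotime=dist, root=root_idx, root_strategy=strategy)


def pseudotemporal_profiles(
    adata: ad.AnnData,
    pt: np.ndarray,
    genes,
    n_bins: int = 20,
    smooth_window: int = 3,
) -> pd.DataFrame:
    """Binned, smoothed, max-scaled expression profiles along pseudotime.

    Cells are binned into ``n_bins`` equal-width pseudotime intervals
    (empty bins are merged into their nearest populated neighbor with a
    warning); binned means are moving-average smoothed and scaled to each
    gene's profile maximum, so rows are comparable and orderable by argmax
    (wave ordering). ``smooth_window=1`` returns the raw binned means.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise ValueError(f"genes not in dataset: {missing}")
    pt = np.asarray(pt, dtype=float)
    Y = _dense_layer(adata[:, genes], "normalized")
    bins = np.minimum((pt * n_bins).astype(int), n_bins - 1)
    prof = np.full((len(genes), n_bins), np.nan)
    for b in range(n_bins):
        mask = bins == b
        if mask.any():
            prof[:, b] = Y[mask].mean(axis=0)
    empty = np.isnan(prof[0])
    if empty.any():
        warnings.warn(f"{int(empty.sum())} empty pseudotime bin(s) merged with neighbors")
        filled = np.flatnonzero(~empty)
        for b in np.flatnonzero(empty):
            src = filled[np.argmin(np.abs(filled - b))]
            prof[:, b] = prof[:, src]
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(prof, ((0, 0), (pad, pad)), mode="edge")
        prof = np.apply_along_axis(
            lambda r: np.convolve(r, kernel, mode="valid"), 1, padded
        )[:, :n_bins]
    peak = prof.max(axis=1)
    scaled = np.where(peak[:, None] > 0, prof / np.maximum(peak[:, None], 1e-300), 0.0)
    return pd.DataFrame(
        scaled, index=genes, columns=[f"bin{b}" for b in range(n_bins)]
    )


@dataclass
class KineticFit:
    """Steady-state velocity fit for each gene."""

    genes: pd.DataFrame  # gamma_hat, n_cells_used, tol, fitted
    residuals: np.ndarray  # cells x genes, u - gamma_hat * s
    calls: np.ndarray  # cells x genes in {+1 up, -1 down, 0 steady}


def _window_neighborhoods(coord: np.ndarray, k: int) -> np.ndarray:
    """Index matrix of the k+1 cells nearest in a scalar coordinate.

    Neighborhoods are contiguous windows in the coordinate's rank order
    (clipped at the ends), with ties resolved by cell index.
    """
    n = coord.shape[0]
    k = min(k, n - 1)
    order = np.argsort(coord, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    start = np.clip(rank - k // 2, 0, n - (k + 1))
    return order[start[:, None] + np.arange(k + 1)[None, :]]


def fit_steady_state(
    adata: ad.AnnData,
    quantile: float = 0.05,
    tol: float | None = None,
    min_cells: int = 30,
    smooth_k: int | None = None,
) -> KineticFit:
    """Fit the per-gene steady-state slope and classify cells up/down.

    Both layers are first scaled per cell to the median library size so
    depth variation does not masquerade as kinetic state. ``gamma_hat`` is
    the origin-constrained least-squares slope of unspliced vs spliced on
    cells in the bottom and top ``quantile`` of spliced expression (the
    classic steady-state velocity estimator), computed on counts pooled
    over ``smooth_k`` cells of similar state (0 disables pooling). The
    pooling coordinate for a gene is the library size of all *other*
    genes, and each neighborhood is split into a selection half and a fit
    half (averaging the two role assignments), so neither the pooling nor
    the extreme-quantile selection shares counting noise with the fitted
    values -- the slope is therefore not attenuated by noise. The residual
    ``u - gamma_hat * s`` is thresholded at ``tol`` (default 5% of the
    gene's maximum pooled unspliced signal): above is "up(regulated)",
    below ``-tol`` is "down", between is "steady". Genes detected in fewer
    than ``min_cells`` cells are flagged unfitted.
    """
    for layer in ("spliced", "unspliced"):
        if layer not in adata.layers:
            raise ValueError(f"layer {layer!r} missing")
    if not 0 < quantile < 0.5:
        raise ValueError("quantile must lie in (0, 0.5)")
    S_raw = _dense_layer(adata, "spliced")
    U_raw = _dense_layer(adata, "unspliced")

    def _sizenorm(M):
        tot = M.sum(axis=1)
        tot[tot == 0] = 1.0
        return M * (np.median(tot) / tot)[:, None]

    S_n = _sizenorm(S_raw)
    U_n = _sizenorm(U_raw)
    totals = S_raw.sum(axis=1)
    n, p = S_n.shape
    if smooth_k is None:
        # velocity-style pooling at ~1/15 of the dataset (>= 30 cells)
        smooth_k = max(30, n // 15)
    pool = smooth_k > 0 and n > smooth_k
    gammas = np.full(p, np.nan)
    tols = np.full(p, np.nan)
    n_used = np.zeros(p, dtype=int)
    fitted = np.zeros(p, dtype=bool)
    residuals = np.full((n, p), np.nan)
    calls = np.zeros((n, p), dtype=np.int8)
    for g in range(p):
        detected = (S_raw[:, g] > 0) | (U_raw[:, g] > 0)
        if detected.sum() < min_cells:
            continue
        if pool:
            coord = np.log1p(totals - S_raw[:, g])
            hood = _window_neighborhoods(coord, smooth_k)
            s = S_n[hood, g].mean(axis=1)
            u = U_n[hood, g].mean(axis=1)
            half_a, half_b = hood[:, 0::2], hood[:, 1::2]
            s_a, s_b = S_n[half_a, g].mean(axis=1), S_n[half_b, g].mean(axis=1)
            u_a, u_b = U_n[half_a, g].mean(axis=1), U_n[half_b, g].mean(axis=1)
            splits = [(s_a, s_b, u_b), (s_b, s_a, u_a)]
        else:
            s, u = S_n[:, g], U_n[:, g]
            splits = [(s, s, u)]
        nums, dens, n_ext = [], [], 0
        for s_sel, s_fit, u_fit in splits:
            lo, hi = np.quantile(s_sel, [quantile, 1 - quantile])
            extreme = (s_sel <= lo) | (s_sel >= hi)
            w = s_sel[extreme]
            nums.append((w * u_fit[extreme]).sum())
            dens.append((w * s_fit[extreme]).sum())
            n_ext = max(n_ext, int(extreme.sum()))
        if not any(d > 0 for d in dens):
            continue
        gamma = max(
            float(np.mean([nu / de for nu, de in zip(nums, dens) if de > 0])), 0.0
        )
        r = u - gamma * s
        t = tol if tol is not None else 0.05 * np.abs(u).max()
        gammas[g] = gamma
        tols[g] = t
        n_used[g] = n_ext
        fitted[g] = True
        residuals[:, g] = r
        calls[:, g] = np.where(r > t, 1, np.where(r < -t, -1, 0))
    genes = pd.DataFrame(
        {"gamma_hat": gammas, "n_cells_used": n_used, "tol": tols, "fitted": fitted},
        index=adata.var_names,
    )
    return KineticFit(genes=genes, residuals=residuals, calls=calls)


def velocity_summary(fit: KineticFit, genes=None) -> pd.DataFrame:
    """Fraction of cells called up / down / steady per fitted gene."""
    index = fit.genes.index
    if genes is not None:
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValueError(f"genes not in fit: {missing}")
        sel = index.get_indexer(list(genes))
    else:
        sel = np.flatnonzero(fit.genes["fitted"].values)
    rows = []
    for g in sel:
        if not fit.genes["fitted"].iloc[g]:
            raise ValueError(f"gene {index[g]!r} was not fitted")
        c = fit.calls[:, g]
        n = len(c)
        rows.append((index[g], (c == 1).sum() / n, (c == -1).sum() / n, (c == 0).sum() / n))
    return pd.DataFrame(
        rows, columns=["gene", "frac_up", "frac_down", "frac_steady"]
    ).set_index("gene")
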