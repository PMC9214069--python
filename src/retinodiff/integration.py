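"""Dataset alignment, pseudospace ordering, and correlation-distance projection.

CCA here follows the single-cell convention of treating shared genes as the
observations and cells as the variables of each block: canonical vectors are
per-cell weightings whose gene-space projections are maximally correlated
between the two datasets. A small ridge term keeps the problem well posed
when cells are not outnumbered by genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .preprocess import _dense_layer


@dataclass
class CCAAlignment:
    """Shared low-dimensional space for two datasets."""

    canonical_correlations: np.ndarray  # non-increasing, in [0, 1]
    coords_x: np.ndarray  # cells_x x n_cc
    coords_y: np.ndarray  # cells_y x n_cc
    genes: list[str]


def _standardize_genes(Y: np.ndarray) -> np.ndarray:
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (Y - mean) / sd


def _inv_sqrt(C: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    w = np.maximum(w, 1e-12)
    return (V / np.sqrt(w)) @ V.T


def cca_align(
    ds_x: ad.AnnData,
    ds_y: ad.AnnData,
    shared_genes,
    n_cc: int = 10,
    ridge: float = 0.05,
) -> CCAAlignment:
    """Ridge-regularized canonical correlation over shared genes.

    A penalty of ``ridge * trace(C)`` is added to each block's cell-cell
    covariance before whitening; at this strength the solution approaches
    the diagonal-covariance CCA used for single-cell integration, which is
    robust when cells outnumber the gene observations. The reported
    canonical correlations are the empirical Pearson correlations of the
    paired canonical variates across the shared genes, sorted
    non-increasing. Component signs are fixed so the largest-magnitude
    entry of each X-block vector is positive.
    """
    genes = list(shared_genes)
    if len(genes) < n_cc:
        raise ValueError(f"need >= n_cc={n_cc} shared genes, got {len(genes)}")
    X = _standardize_genes(_dense_layer(ds_x[:, genes], "normalized"))
    Y = _standardize_genes(_dense_layer(ds_y[:, genes], "normalized"))
    g = len(genes)
    if n_cc > min(X.shape[0], Y.shape[0], g):
        raise ValueError(f"n_cc={n_cc} exceeds feasible rank")
    Cxx = X @ X.T / g
    Cyy = Y @ Y.T / g
    Cxy = X @ Y.T / g
    Cxx += ridge * np.trace(Cxx) * np.eye(Cxx.shape[0])
    Cyy += ridge * np.trace(Cyy) * np.eye(Cyy.shape[0])
    Wx = _inv_sqrt(Cxx)
    Wy = _inv_sqrt(Cyy)
    U, S, Vt = np.linalg.svd(Wx @ Cxy @ Wy)
    coords_x = Wx @ U[:, :n_cc]
    coords_y = Wy @ Vt[:n_cc].T
    # empirical correlation of the paired gene-space variates
    zx = X.T @ coords_x  # genes x n_cc
    zy = Y.T @ coords_y
    corrs = np.zeros(n_cc)
    for k in range(n_cc):
        sx, sy = zx[:, k].std(), zy[:, k].std()
        if sx > 0 and sy > 0:
            corrs[k] = np.corrcoef(zx[:, k], zy[:, k])[0, 1]
    corrs = np.clip(corrs, 0.0, 1.0)
    order = np.argsort(-corrs, kind="stable")
    corrs = corrs[order]
    coords_x = coords_x[:, order]
    coords_y = coords_y[:, order]
    for k in range(n_cc):
        j = np.argmax(np.abs(coords_x[:, k]))
        if coords_x[j, k] < 0:
            coords_x[:, k] = -coords_x[:, k]
            coords_y[:, k] = -coords_y[:, k]
    return CCAAlignment(
        canonical_correlations=corrs, coords_x=coords_x, coords_y=coords_y,
        genes=genes,
    )


@dataclass
class PseudospaceOrdering:
    """Cells positioned along a unit patterning axis, anchored at one end."""

    positions: np.ndarray  # in [0, 1]
    anchor_gene: str
    bins: np.ndarray  # bin index per cell
    flipped: bool


def pseudospace(
    adata: ad.AnnData,
    axis,
    anchor_gene: str,
    n_bins: int = 10,
) -> tuple[PseudospaceOrdering, pd.DataFrame]:
    """Min-max scale an axis into [0, 1] and profile genes along it.

    The orientation contract: the anchor gene's mean expression must be
    higher in the first decile than in the last, flipping the axis if
    needed. Profiles are per-bin mean normalized expression scaled to each
    gene's maximum (relative expression in [0, 1]; constant genes come out
    flat at 1 and are flagged).
    """
    axis = np.asarray(axis, dtype=float)
    if not np.all(np.isfinite(axis)):
        raise ValueError("axis contains non-finite values")
    if axis.max() == axis.min():
        raise ValueError("axis is constant")
    if anchor_gene not in adata.var_names:
        raise ValueError(f"anchor gene {anchor_gene!r} not in dataset")
    pos = (axis - axis.min()) / (axis.max() - axis.min())
    Y = _dense_layer(adata, "normalized")
    anchor = Y[:, list(adata.var_names).index(anchor_gene)]
    first, last = pos <= 0.1, pos >= 0.9
    flipped = False
    if anchor[first].mean() < anchor[last].mean():
        pos = 1.0 - pos
        flipped = True
        first, last = last, first
    bins = np.minimum((pos * n_bins).astype(int), n_bins - 1)
    prof = np.full((adata.n_vars, n_bins), np.nan)
    for b in range(n_bins):
        mask = bins == b
        if mask.any():
            prof[:, b] = Y[mask].mean(axis=0)
    # forward/backward fill empty bins from the nearest populated neighbor
    for b in range(n_bins):
        if np.isnan(prof[0, b]):
            left = b - 1
            while left >= 0 and np.isnan(prof[0, left]):
                left -= 1
            right = b + 1
            while right < n_bins and np.isnan(prof[0, right]):
                right += 1
            src = left if left >= 0 else right
            prof[:, b] = prof[:, src]
    peak = prof.max(axis=1)
    flat = peak == prof.min(axis=1)
    scaled = np.where(peak[:, None] > 0, prof / np.maximum(peak[:, None], 1e-300), 1.0)
    scaled[flat] = 1.0
    profiles = pd.DataFrame(
        scaled, index=adata.var_names,
        columns=[f"bin{b}" for b in range(n_bins)],
    )
    profiles["flat"] = flat
    ordering = PseudospaceOrdering(
        positions=pos, anchor_gene=anchor_gene, bins=bins, flipped=flipped
    )
    return ordering, profiles


@dataclass
class ProjectionResult:
    """Query cells mapped onto a labelled reference."""

    table: pd.DataFrame  # per query cell: label, mean_distance, low_confidence
    neighbor_ids: np.ndarray  # query x k reference indices
    projected_coordinates: np.ndarray | None = None


def project_labels(
    query: ad.AnnData,
    reference: ad.AnnData,
    shared_genes,
    label_key: str = "cluster",
    k: int = 10,
    reference_embedding: np.ndarray | None = None,
    distance_flag: float = 0.9,
) -> ProjectionResult:
    """Transfer labels by k-nearest-neighbor vote under correlation distance.

    Distance is ``1 - Pearson(query, reference)`` over the shared genes'
    normalized expression (range [0, 2]). The label is the majority among
    the ``k`` nearest reference cells; ties break by smaller mean distance,
    then lexicographically. Projected coordinates, when a reference
    embedding is given, are the inverse-distance-weighted mean of neighbor
    coordinates (an identical cell lands exactly on its reference twin).
    Queries whose mean neighbor distance exceeds ``distance_flag`` are
    marked low-confidence.
    """
    genes = list(shared_genes)
    if not genes:
        raise ValueError("shared gene set is empty")
    if k > reference.n_obs:
        raise ValueError(f"k={k} exceeds reference size {reference.n_obs}")
    if label_key not in reference.obs:
        raise ValueError(f"reference metadata column {label_key!r} missing")
    Q = _dense_layer(query[:, genes], "normalized")
    R = _dense_layer(reference[:, genes], "normalized")

    def _rowstd(M):
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (M - mu) / sd

    corr = _rowstd(Q) @ _rowstd(R).T / len(genes)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    labels = np.asarray(reference.obs[label_key].astype(str))
    ref_coords = None
    if reference_embedding is not None:
        ref_coords = np.asarray(reference_embedding)
        if ref_coords.shape[0] != reference.n_obs:
            raise ValueError("reference embedding size mismatch")

    assigned, mean_dists = [], []
    proj = np.zeros((query.n_obs, ref_coords.shape[1])) if ref_coords is not None else None
    for i in range(query.n_obs):
        neigh = order[i]
        d = dist[i, neigh]
        votes: dict[str, list] = {}
        for j, dj in zip(neigh, d):
            votes.setdefault(labels[j], []).append(dj)
        best = sorted(
            votes.items(), key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])), kv[0])
        )[0][0]
        assigned.append(best)
        mean_dists.append(float(d.mean()))
        if proj is not None:
            w = 1.0 / (d + 1e-12)
            proj[i] = (w[:, None] * ref_coords[neigh]).sum(axis=0) / w.sum()
    table = pd.DataFrame(
        {
            "label": assigned,
            "mean_distance": mean_dists,
            "low_confidence": np.asarray(mean_dists) > distance_flag,
        },
        index=query.obs_names,
    )
    return ProjectionResult(
        table=table, neighbor_ids=order, projected_coordinates=proj
    )
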