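"""Cluster marker detection and the anticorrelation surface-marker screen.

Enriched genes per cluster come from a one-vs-rest Wilcoxon rank-sum test
on the normalized layer with Benjamini-Hochberg correction within each
cluster. The anticorrelation screen ranks genes whose expression is
negatively correlated with both an RPE and a neural-tube signature score --
candidate progenitor markers -- after excluding lowly expressed genes
(mean normalized expression < 0.5 by default); intersecting with a
surfaceome list yields sortable surface candidates (the route by which
NCAM1-class markers are nominated).
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import _dense_layer
from .signatures import GeneSignature, score_signature


def log2fc(
    adata: ad.AnnData, group_mask_a, group_mask_b, pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene log2 fold change of mean normalized expression, A over B."""
    mask_a = np.asarray(group_mask_a, dtype=bool)
    mask_b = np.asarray(group_mask_b, dtype=bool)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both groups must be non-empty")
    Y = _dense_layer(adata, "normalized")
    mean_a = Y[mask_a].mean(axis=0)
    mean_b = Y[mask_b].mean(axis=0)
    vals = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return pd.Series(vals, index=adata.var_names, name="log2_fold_change")


def enriched_genes(
    adata: ad.AnnData,
    cluster_key: str = "cluster",
    min_cells: int = 3,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One-vs-rest rank-sum enrichment per cluster.

    Returns a table with one row per (cluster, gene): log2_fold_change,
    the standardized rank-sum statistic, p_value, BH-adjusted p within the
    cluster, and rank (1 = best). Ranking is by statistic descending among
    genes with positive log2FC, then the remaining genes.
    """
    if cluster_key not in adata.obs:
        raise ValueError(f"cell metadata column {cluster_key!r} missing")
    labels = adata.obs[cluster_key].astype(str).values
    sizes = pd.Series(labels).value_counts()
    usable = [c for c in sizes.index if sizes[c] >= min_cells]
    for c in sizes.index:
        if sizes[c] < min_cells:
            warnings.warn(f"cluster {c!r} has {sizes[c]} < {min_cells} cells; skipped")
    if len(usable) < 2:
        raise ValueError("need at least 2 clusters with enough cells")
    Y = _dense_layer(adata, "normalized")
    frames = []
    for c in sorted(usable):
        mask = labels == c
        res = stats.mannwhitneyu(
            Y[mask], Y[~mask], alternative="two-sided", axis=0, method="asymptotic"
        )
        n1, n2 = int(mask.sum()), int((~mask).sum())
        mu = n1 * n2 / 2.0
        # standardized statistic (tie-uncorrected scale factor is fine for ranking)
        sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        z = (res.statistic - mu) / sigma
        lfc = np.log2(
            (Y[mask].mean(axis=0) + pseudocount) / (Y[~mask].mean(axis=0) + pseudocount)
        )
        adj = multipletests(res.pvalue, method="fdr_bh")[1]
        df = pd.DataFrame({
            "cluster": c,
            "gene": adata.var_names,
            "log2_fold_change": lfc,
            "statistic": z,
            "p_value": res.pvalue,
            "adjusted_p": adj,
        })
        positive = df["log2_fold_change"] > 0
        order = np.lexsort((df["gene"], -df["statistic"], ~positive))
        rank = np.empty(len(df), dtype=int)
        rank[order] = np.arange(1, len(df) + 1)
        df["rank"] = rank
        frames.append(df.sort_values("rank"))
    return pd.concat(frames, ignore_index=True)


def top_enriched(table: pd.DataFrame, n: int = 30) -> dict[str, list[str]]:
    """Per-cluster ranked top-``n`` enriched genes (positive log2FC only)."""
    out = {}
    for c, grp in table.groupby("cluster", sort=False):
        pos = grp[grp["log2_fold_change"] > 0].sort_values("rank")
        out[c] = list(pos["gene"].head(n))
    return out


def anticorrelation_screen(
    adata: ad.AnnData,
    rpe_sig: GeneSignature,
    neural_tube_sig: GeneSignature,
    min_mean: float = 0.5,
    combine: str = "mean",
    seed: int = 0,
) -> pd.DataFrame:
    """Rank genes anticorrelated with both lineage signatures.

    Genes with mean normalized expression below ``min_mean`` are excluded
    outright. For each retained gene the Pearson correlation between its
    normalized expression and each per-cell signature score is computed;
    the combined score (``mean`` of the two correlations, or ``max`` via
    ``combine="max"``) sorts ascending so the strongest double
    anticorrelation -- candidate progenitor markers -- comes first.
    """
    if combine not in ("mean", "max"):
        raise ValueError("combine must be 'mean' or 'max'")
    rpe_score = score_signature(adata, rpe_sig, seed=seed)
    nt_score = score_signature(adata, neural_tube_sig, seed=seed + 1)
    Y = _dense_layer(adata, "normalized")
    gene_mean = Y.mean(axis=0)
    keep = gene_mean >= min_mean
    if not keep.any():
        raise ValueError(f"no gene has mean normalized expression >= {min_mean}")
    Yk = Y[:, keep]
    sd = Yk.std(axis=0)
    ok = sd > 0
    def _corr(score):
        zs = (score - score.mean())
        zs_sd = zs.std()
        c = np.full(Yk.shape[1], np.nan)
        if zs_sd > 0:
            num = (Yk - Yk.mean(axis=0)).T @ zs / len(zs)
            c[ok] = num[ok] / (sd[ok] * zs_sd)
        return np.clip(c, -1.0, 1.0)
    corr_rpe = _corr(rpe_score)
    corr_nt = _corr(nt_score)
    combined = (
        (corr_rpe + corr_nt) / 2 if combine == "mean" else np.maximum(corr_rpe, corr_nt)
    )
    out = pd.DataFrame({
        "gene": np.asarray(adata.var_names)[keep],
        "mean_normalized_expression": gene_mean[keep],
        "correlation_to_rpe": corr_rpe,
        "correlation_to_neural_tube": corr_nt,
        "combined_score": combined,
        "surface_flag": False,
    })
    out = out.sort_values(
        ["combined_score", "gene"], na_position="last"
    ).reset_index(drop=True)
    return out


def surface_filter(screen: pd.DataFrame, surfaceome) -> pd.DataFrame:
    """Restrict a screen to surfaceome genes, preserving rank order."""
    symbols = list(dict.fromkeys(surfaceome))
    if not symbols:
        raise ValueError("surfaceome list is empty")
    out = screen[screen["gene"].isin(symbols)].copy()
    if out.empty:
        warnings.warn("no screened gene is in the surfaceome list")
    out["surface_flag"] = True
    return out.reset_index(drop=True)
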