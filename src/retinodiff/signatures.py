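"""Gene-set signature scoring and derived per-cell statistics.

A signature score is the mean normalized expression of the signature genes
minus the mean of a control gene pool sampled from matching mean-expression
bins (25 bins, 50 controls per signature gene by default). Bin-matching
removes library-depth and expression-level confounding, so a random gene set
scores ~0 on average.

Also here: cell-cycle phase assignment from S/G2M signature scores, marker
positivity fractions with Wilson 95% confidence intervals, cross-reference
signature mapping (top-N enriched genes of each reference population scored
on query clusters), and group-level Pearson correlation matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import anndata as ad
import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .preprocess import _dense_layer


@dataclass(frozen=True)
class GeneSignature:
    """Named, ordered gene list; all signatures are up-sets."""

    name: str
    genes: tuple

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate symbols")


def read_signatures(path) -> dict[str, GeneSignature]:
    """Read a two-column (signature_name, gene_symbol) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["signature", "gene"])
    return {
        name: GeneSignature(name, tuple(grp["gene"]))
        for name, grp in df.groupby("signature", sort=False)
    }


def builtin_signatures() -> dict[str, GeneSignature]:
    """Editable default sets: pluripotency / retinal progenitor / RPE marker
    waves and S / G2M cell-cycle programs."""
    sigs = {}
    for fname in ("signatures.tsv", "cell_cycle.tsv"):
        ref = resources.files("retinodiff").joinpath("data", fname)
        with resources.as_file(ref) as p:
            sigs.update(read_signatures(p))
    return sigs


def score_signature(
    adata: ad.AnnData,
    sig: GeneSignature,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell signature score with bin-matched control genes.

    Deterministic under a fixed seed. Signature genes absent from the
    dataset are dropped with a warning; if none remain this is an error.
    """
    Y = _dense_layer(adata, "normalized")
    var_index = pd.Index(adata.var_names)
    present = [g for g in sig.genes if g in var_index]
    missing = set(sig.genes) - set(present)
    if missing:
        warnings.warn(
            f"signature {sig.name!r}: {len(missing)} gene(s) absent, dropped"
        )
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in dataset")
    sig_idx = var_index.get_indexer(present)

    gene_mean = Y.mean(axis=0)
    order = np.argsort(gene_mean, kind="stable")
    bin_of = np.empty(len(var_index), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b

    rng = np.random.default_rng(seed)
    ctrl: set[int] = set()
    for gi in sig_idx:
        pool = np.flatnonzero(bin_of == bin_of[gi])
        pool = pool[~np.isin(pool, sig_idx)]
        if pool.size == 0:
            continue
        take = min(n_ctrl, pool.size)
        ctrl.update(rng.choice(pool, size=take, replace=False))
    if not ctrl:
        # degenerate dataset in which every gene is in the signature
        return Y[:, sig_idx].mean(axis=1)
    ctrl_idx = np.fromiter(sorted(ctrl), dtype=int)
    return Y[:, sig_idx].mean(axis=1) - Y[:, ctrl_idx].mean(axis=1)


@dataclass
class CyclePhaseAssignment:
    """Per-cell cycle phase: cycling cells are those in S or G2/M."""

    phase: np.ndarray  # {"G1_G0", "S", "G2M"} per cell
    s_score: np.ndarray
    g2m_score: np.ndarray

    @property
    def cycling(self) -> np.ndarray:
        return self.phase != "G1_G0"

    def to_frame(self, index) -> pd.DataFrame:
        return pd.DataFrame(
            {"phase": self.phase, "s_score": self.s_score,
             "g2m_score": self.g2m_score, "cycling": self.cycling},
            index=index,
        )


def assign_cell_cycle(
    adata: ad.AnnData,
    sig_s: GeneSignature,
    sig_g2m: GeneSignature,
    threshold: float = 0.0,
    seed: int = 0,
) -> CyclePhaseAssignment:
    """G1/G0 if both scores are at or below threshold, else the larger wins."""
    s_score = score_signature(adata, sig_s, seed=seed)
    g2m_score = score_signature(adata, sig_g2m, seed=seed + 1)
    phase = np.where(
        (s_score <= threshold) & (g2m_score <= threshold),
        "G1_G0",
        np.where(s_score >= g2m_score, "S", "G2M"),
    )
    return CyclePhaseAssignment(phase=phase, s_score=s_score, g2m_score=g2m_score)


def positive_fraction(
    adata: ad.AnnData,
    gene: str,
    group_by: str = "time_point",
    min_count: int = 1,
) -> pd.DataFrame:
    """Fraction of cells with raw count >= ``min_count`` per group.

    95% confidence intervals use the Wilson score interval, which stays
    valid at fractions near 0 and 1. Returns a table indexed by group with
    columns (n, n_positive, fraction, ci_low, ci_high).
    """
    if gene not in adata.var_names:
        raise ValueError(f"gene {gene!r} not in dataset")
    if group_by not in adata.obs:
        raise ValueError(f"cell metadata column {group_by!r} missing")
    counts = np.asarray(
        adata[:, [gene]].X.todense()
    ).ravel() if hasattr(adata.X, "todense") else np.asarray(adata[:, [gene]].X).ravel()
    pos = counts >= min_count
    rows = []
    for group, idx in adata.obs.groupby(group_by, observed=True, sort=False).groups.items():
        mask = adata.obs.index.isin(idx)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"group {group!r} is empty")
        k = int(pos[mask].sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append((group, n, k, k / n, float(lo), float(hi)))
    return pd.DataFrame(
        rows, columns=["group", "n", "n_positive", "fraction", "ci_low", "ci_high"]
    ).set_index("group")


def reference_signature_scores(
    query: ad.AnnData,
    reference_rankings: dict[str, list],
    cluster_key: str = "cluster",
    top_n: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Score each reference population's top-N enriched genes on query clusters.

    ``reference_rankings`` maps reference type -> enriched genes ranked best
    first (e.g. from :func:`retinodiff.markers.enriched_genes`). Returns a
    clusters x reference-types matrix of mean per-cell scores.
    """
    if cluster_key not in query.obs:
        raise ValueError(f"cell metadata column {cluster_key!r} missing")
    clusters = query.obs[cluster_key].astype(str)
    out = {}
    for i, (ref_type, ranking) in enumerate(reference_rankings.items()):
        if len(ranking) == 0:
            raise ValueError(f"reference type {ref_type!r} has no enriched genes")
        if len(ranking) < top_n:
            warnings.warn(
                f"reference type {ref_type!r}: only {len(ranking)} enriched "
                f"genes available (requested {top_n})"
            )
        sig = GeneSignature(str(ref_type), tuple(ranking[:top_n]))
        scores = score_signature(query, sig, seed=seed + i)
        out[ref_type] = pd.Series(scores, index=query.obs_names).groupby(
            clusters.values
        ).mean()
    return pd.DataFrame(out)


def group_correlation_matrix(
    adata: ad.AnnData, group_by: str, genes=None
) -> pd.DataFrame:
    """Pearson correlation between group mean normalized-expression profiles.

    Constant profiles have undefined correlation; those entries are NaN.
    """
    if group_by not in adata.obs:
        raise ValueError(f"cell metadata column {group_by!r} missing")
    view = adata[:, list(genes)] if genes is not None else adata
    Y = _dense_layer(view, "normalized")
    groups = adata.obs[group_by].astype(str).values
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    profiles = np.vstack([Y[groups == g].mean(axis=0) for g in labels])
    sd = profiles.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(profiles)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=labels, columns=labels)
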