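"""Ordinal developmental-stage classifier.

Places transcriptomes along an ordered set of developmental classes
(default: embryonic weeks W5, W6-8, W9-13, W17-24, then adult RPE). The
model is a ridge-penalized proportional-odds (cumulative-logit) regression
on the leading principal components of the reference: a single latent
maturation score per cell plus ordered thresholds between classes, so
misclassifications naturally concentrate on adjacent stages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .preprocess import _dense_layer

CLIP_SD = 10.0


def _theta_from_params(t0: float, deltas: np.ndarray) -> np.ndarray:
    return t0 + np.concatenate([[0.0], np.cumsum(np.exp(deltas))])


def _nll_grad(params, X, y, n_classes, lam):
    p = X.shape[1]
    beta = params[:p]
    t0 = params[p]
    deltas = params[p + 1:]
    theta = _theta_from_params(t0, deltas)
    eta = X @ beta
    # a = theta_y - eta (inf for top class), b = theta_{y-1} - eta (-inf for bottom)
    a = np.where(y < n_classes - 1, theta[np.minimum(y, n_classes - 2)] - eta, np.inf)
    b = np.where(y > 0, theta[np.maximum(y - 1, 0)] - eta, -np.inf)
    Fa = np.where(np.isinf(a), 1.0, expit(a))
    Fb = np.where(np.isinf(b), 0.0, expit(b))
    D = np.maximum(Fa - Fb, 1e-12)
    nll = -np.log(D).sum() + lam * beta @ beta

    fa = np.where(np.isinf(a), 0.0, Fa * (1 - Fa))
    fb = np.where(np.isinf(b), 0.0, Fb * (1 - Fb))
    ga = fa / D
    gb = fb / D
    grad_eta = ga - gb
    grad_beta = X.T @ grad_eta + 2 * lam * beta
    grad_theta = np.zeros(n_classes - 1)
    for j in range(n_classes - 1):
        grad_theta[j] = -ga[y == j].sum() + gb[y == j + 1].sum()
    grad_t0 = grad_theta.sum()
    grad_deltas = np.array([
        grad_theta[m:].sum() * np.exp(deltas[m - 1]) for m in range(1, n_classes - 1)
    ])
    return nll, np.concatenate([grad_beta, [grad_t0], grad_deltas])


@dataclass
class OrdinalStageModel:
    """Fitted proportional-odds stage classifier."""

    classes: list[str]  # declared total order, first = least mature
    genes: list[str]
    gene_mean: np.ndarray
    gene_sd: np.ndarray
    loadings: np.ndarray  # genes x n_features
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    beta: np.ndarray
    thresholds: np.ndarray  # strictly increasing, len = n_classes - 1
    centroids: pd.DataFrame | None = None  # per-class mean feature profile
    n_per_class: dict = field(default_factory=dict)
    non_separable: bool = False
    ridge: float = 1.0

    def features(self, adata: ad.AnnData) -> np.ndarray:
        """Project a dataset onto the model's feature space.

        Basis genes missing from the query are imputed as zero normalized
        expression (warning above 20% missing; error above 50%).
        """
        var_index = pd.Index(adata.var_names)
        present = var_index.get_indexer(self.genes)
        missing = (present < 0).sum()
        frac = missing / len(self.genes)
        if frac > 0.5:
            raise ValueError(
                f"only {len(self.genes) - missing}/{len(self.genes)} basis genes "
                "present in query (need >= 50%)"
            )
        if frac > 0.2:
            warnings.warn(f"{frac:.0%} of basis genes missing; imputed as zero")
        Y = _dense_layer(adata, "normalized")
        M = np.zeros((adata.n_obs, len(self.genes)))
        has = present >= 0
        M[:, has] = Y[:, present[has]]
        Z = np.clip((M - self.gene_mean) / self.gene_sd, -CLIP_SD, CLIP_SD)
        F = Z @ self.loadings
        return (F - self.feat_mean) / self.feat_sd

    def save(self, path) -> None:
        obj = {
            "classes": self.classes,
            "genes": self.genes,
            "gene_mean": self.gene_mean.tolist(),
            "gene_sd": self.gene_sd.tolist(),
            "loadings": self.loadings.tolist(),
            "feat_mean": self.feat_mean.tolist(),
            "feat_sd": self.feat_sd.tolist(),
            "beta": self.beta.tolist(),
            "thresholds": self.thresholds.tolist(),
            "n_per_class": self.n_per_class,
            "non_separable": self.non_separable,
            "ridge": self.ridge,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def load(cls, path) -> "OrdinalStageModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            classes=obj["classes"],
            genes=obj["genes"],
            gene_mean=np.array(obj["gene_mean"]),
            gene_sd=np.array(obj["gene_sd"]),
            loadings=np.array(obj["loadings"]),
            feat_mean=np.array(obj["feat_mean"]),
            feat_sd=np.array(obj["feat_sd"]),
            beta=np.array(obj["beta"]),
            thresholds=np.array(obj["thresholds"]),
            n_per_class={k: int(v) for k, v in obj["n_per_class"].items()},
            non_separable=obj["non_separable"],
            ridge=obj["ridge"],
        )


def fit_stage_classifier(
    reference: ad.AnnData,
    stage_key: str = "stage",
    class_order: list | None = None,
    n_features: int = 50,
    ridge: float = 1.0,
) -> OrdinalStageModel:
    """Fit the proportional-odds model on reference PCs.

    ``class_order`` declares the total order (least to most mature); by
    default classes are taken in order of first appearance. Every class
    needs at least 5 cells.
    """
    if stage_key not in reference.obs:
        raise ValueError(f"cell metadata column {stage_key!r} missing")
    labels = reference.obs[stage_key].astype(str).values
    if class_order is None:
        class_order = list(dict.fromkeys(labels))
    class_order = [str(c) for c in class_order]
    if len(class_order) < 2:
        raise ValueError("need at least 2 stage classes")
    counts = pd.Series(labels).value_counts()
    for c in class_order:
        if counts.get(c, 0) < 5:
            raise ValueError(f"class {c!r} has {counts.get(c, 0)} < 5 cells")
    y = np.array([class_order.index(l) for l in labels])
    n_classes = len(class_order)

    Y = _dense_layer(reference, "normalized")
    gene_mean = Y.mean(axis=0)
    gene_sd = Y.std(axis=0, ddof=1)
    gene_sd[gene_sd == 0] = 1.0
    Z = np.clip((Y - gene_mean) / gene_sd, -CLIP_SD, CLIP_SD)
    Zc = Z - Z.mean(axis=0)
    d = min(n_features, min(Zc.shape) - 1)
    U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    loadings = Vt[:d].T
    F = Zc @ loadings
    feat_mean = F.mean(axis=0)
    feat_sd = F.std(axis=0, ddof=1)
    feat_sd[feat_sd == 0] = 1.0
    X = (F - feat_mean) / feat_sd

    x0 = np.concatenate([
        np.zeros(d),
        [-1.0],
        np.zeros(max(n_classes - 2, 0)),
    ])
    res = minimize(
        _nll_grad, x0, args=(X, y, n_classes, ridge), jac=True,
        method="L-BFGS-B", options={"maxiter": 500},
    )
    beta = res.x[:d]
    thresholds = _theta_from_params(res.x[d], res.x[d + 1:])
    # non-separability: overfitting-adjusted McFadden pseudo-R^2 against the
    # intercept-only (class-frequency) model
    freqs = np.bincount(y, minlength=n_classes) / len(y)
    nll0 = -np.sum(np.bincount(y, minlength=n_classes) * np.log(np.maximum(freqs, 1e-12)))
    nll = res.fun - ridge * beta @ beta
    n_params = d + (n_classes - 1)
    pseudo_r2 = (nll0 - nll - n_params) / nll0

    model = OrdinalStageModel(
        classes=class_order,
        genes=list(reference.var_names),
        gene_mean=gene_mean,
        gene_sd=gene_sd,
        loadings=loadings,
        feat_mean=feat_mean,
        feat_sd=feat_sd,
        beta=beta,
        thresholds=thresholds,
        n_per_class={c: int(counts.get(c, 0)) for c in class_order},
        ridge=ridge,
    )
    centroids = pd.DataFrame(
        [X[y == j].mean(axis=0) for j in range(n_classes)], index=class_order
    )
    model.centroids = centroids
    model.non_separable = bool(pseudo_r2 < 0.05)
    return model


@dataclass
class StagePrediction:
    """Per-cell stage probabilities plus modal class and expected position."""

    probabilities: pd.DataFrame  # cells x classes, rows sum to 1
    table: pd.DataFrame  # modal_class, expected_position

    def summary_matrix(self, groups) -> pd.DataFrame:
        """Percentage of cells per class per sample group (rows sum to 100)."""
        df = self.table.copy()
        df["group"] = np.asarray(groups)
        counts = (
            df.groupby("group", sort=False)["modal_class"]
            .value_counts()
            .unstack(fill_value=0)
        )
        counts = counts.reindex(columns=self.probabilities.columns, fill_value=0)
        return counts.div(counts.sum(axis=1), axis=0) * 100


def predict_stages(model: OrdinalStageModel, query: ad.AnnData) -> StagePrediction:
    """Class probability simplex, modal class, and expected ordinal position."""
    X = model.features(query)
    eta = X @ model.beta
    n_classes = len(model.classes)
    cum = expit(model.thresholds[None, :] - eta[:, None])  # cells x (J-1)
    cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
    probs = np.maximum(np.diff(cum, axis=1), 0.0)
    probs /= probs.sum(axis=1, keepdims=True)
    prob_df = pd.DataFrame(probs, index=query.obs_names, columns=model.classes)
    modal = prob_df.idxmax(axis=1)
    expected = probs @ np.arange(n_classes)
    table = pd.DataFrame(
        {"modal_class": modal, "expected_position": expected}, index=query.obs_names
    )
    return StagePrediction(probabilities=prob_df, table=table)
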