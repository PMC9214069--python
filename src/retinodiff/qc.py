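"""Quality-control filtering of cells and genes.

Filtering order is cells first, then genes: cell filters see the full gene
panel, and gene detection counts are recomputed on the retained cells. The
order is part of the contract because it changes results on edge cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import validate_dataset


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for cell/gene retention.

    ``max_fraction_in_top_gene`` removes cells dominated by a single gene
    (1.0 disables the filter). Defaults are conventional scRNA-seq choices
    and are meant to be overridden per study.
    """

    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    max_fraction_in_top_gene: float = 1.0

    def __post_init__(self):
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ValueError("QC thresholds must be >= 0")
        if not 0 <= self.max_fraction_in_top_gene <= 1:
            raise ValueError("max_fraction_in_top_gene must lie in [0, 1]")


def qc_filter(adata: ad.AnnData, cfg: QCConfig = QCConfig()) -> tuple[ad.AnnData, pd.DataFrame]:
    """Filter cells then genes; return the subset and a removal report.

    The report has one row per removed entity with columns
    (entity, id, reason, value, threshold).

    Raises ``ValueError`` if no cell survives.
    """
    validate_dataset(adata)
    X = sp.csr_matrix(adata.X)
    rows = []

    genes_per_cell = np.asarray((X > 0).sum(axis=1)).ravel()
    keep_cells = genes_per_cell >= cfg.min_genes_per_cell
    for i in np.flatnonzero(~keep_cells):
        rows.append(("cell", adata.obs_names[i], "min_genes_per_cell",
                     int(genes_per_cell[i]), cfg.min_genes_per_cell))
    if cfg.max_fraction_in_top_gene < 1.0:
        totals = np.asarray(X.sum(axis=1)).ravel()
        top = np.asarray(X.max(axis=1).todense()).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, top / np.maximum(totals, 1), 0.0)
        over = frac > cfg.max_fraction_in_top_gene
        for i in np.flatnonzero(over & keep_cells):
            rows.append(("cell", adata.obs_names[i], "max_fraction_in_top_gene",
                         float(frac[i]), cfg.max_fraction_in_top_gene))
        keep_cells &= ~over
    if not keep_cells.any():
        raise ValueError(
            f"QC removed all {adata.n_obs} cells "
            f"(min_genes_per_cell={cfg.min_genes_per_cell})"
        )

    sub = X[keep_cells]
    cells_per_gene = np.asarray((sub > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= cfg.min_cells_per_gene
    for j in np.flatnonzero(~keep_genes):
        rows.append(("gene", adata.var_names[j], "min_cells_per_gene",
                     int(cells_per_gene[j]), cfg.min_cells_per_gene))

    report = pd.DataFrame(
        rows, columns=["entity", "id", "reason", "value", "threshold"]
    )
    out = adata[keep_cells, keep_genes].copy()
    return out, report
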