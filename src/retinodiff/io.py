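"""Dataset construction, validation, and on-disk formats.

The in-memory container is :class:`anndata.AnnData` used with a fixed
convention:

* ``X``           raw counts (non-negative integers), cells x genes
* ``layers``      optional matrices of identical shape: ``normalized``
                  (non-negative reals), ``spliced`` / ``unspliced``
                  (non-negative integers)
* ``obs``         cell metadata keyed by barcode (``time_point``, ``line``,
                  ``cluster`` where present)
* ``var``         gene metadata keyed by case-sensitive gene symbol

Two disk formats are supported: a 10x-style Matrix Market directory
(``matrix.mtx`` stored genes x cells, plus ``genes.tsv`` and
``barcodes.tsv``; optional per-layer ``<layer>.mtx``), and a dense TSV with a
gene-symbol header row and barcodes in the first column.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

INTEGER_LAYERS = ("spliced", "unspliced")

CELL_META_FILE = "cell_meta.tsv"
GENE_META_FILE = "gene_meta.tsv"


class DatasetError(ValueError):
    """Raised when a dataset violates the container contract."""


def make_dataset(
    counts,
    barcodes,
    symbols,
    layers: dict | None = None,
    cell_meta: pd.DataFrame | None = None,
    gene_meta: pd.DataFrame | None = None,
) -> ad.AnnData:
    """Assemble a validated cells x genes dataset."""
    counts = sp.csr_matrix(counts) if not sp.issparse(counts) else counts.tocsr()
    obs = pd.DataFrame(index=pd.Index([str(b) for b in barcodes], name="barcode"))
    var = pd.DataFrame(index=pd.Index([str(g) for g in symbols], name="symbol"))
    if cell_meta is not None:
        cm = cell_meta.copy()
        cm.index = obs.index
        obs = cm
    if gene_meta is not None:
        gm = gene_meta.copy()
        gm.index = var.index
        var = gm
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    for name, mat in (layers or {}).items():
        adata.layers[name] = sp.csr_matrix(mat) if not sp.issparse(mat) else mat.tocsr()
    validate_dataset(adata)
    return adata


def _check_counts(mat, what: str) -> None:
    data = mat.data if sp.issparse(mat) else np.asarray(mat)
    if data.size and not np.all(np.isfinite(data)):
        raise DatasetError(f"{what}: non-finite entries")
    if data.size and data.min() < 0:
        raise DatasetError(f"{what}: negative entries")
    if data.size and np.any(data != np.round(data)):
        raise DatasetError(f"{what}: non-integer entries")


def validate_dataset(adata: ad.AnnData) -> ad.AnnData:
    """Check the container invariants; return the dataset unchanged."""
    if adata.obs_names.duplicated().any():
        raise DatasetError("duplicate cell barcodes")
    if adata.var_names.duplicated().any():
        raise DatasetError("duplicate gene symbols")
    _check_counts(adata.X, "counts")
    for name, mat in adata.layers.items():
        if mat.shape != adata.shape:
            raise DatasetError(f"layer {name!r}: shape {mat.shape} != {adata.shape}")
        if name in INTEGER_LAYERS:
            _check_counts(mat, f"layer {name!r}")
        else:
            data = mat.data if sp.issparse(mat) else np.asarray(mat)
            if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
                raise DatasetError(f"layer {name!r}: negative or non-finite entries")
    return adata


def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _orient(mat: sp.spmatrix, n_cells: int, n_genes: int, path) -> sp.csr_matrix:
    """Return the matrix oriented cells x genes regardless of disk layout."""
    if mat.shape == (n_genes, n_cells):
        # 10x convention: rows are genes
        return sp.csr_matrix(mat.T)
    if mat.shape == (n_cells, n_genes):
        if n_cells == n_genes:
            # square and ambiguous: fall back to the 10x convention
            return sp.csr_matrix(mat.T)
        return sp.csr_matrix(mat)
    raise DatasetError(
        f"{path}: matrix shape {mat.shape} matches neither "
        f"{n_genes} genes x {n_cells} barcodes nor its transpose"
    )


def read_dataset(path, format: str = "mtx_dir") -> ad.AnnData:
    """Read a dataset from disk.

    ``mtx_dir`` expects ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` and
    picks up any ``<layer>.mtx`` companions plus the metadata TSVs written by
    :func:`write_dataset`. ``dense_tsv`` expects a single table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "mtx_dir":
        for fname in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
            if not (path / fname).exists():
                raise FileNotFoundError(str(path / fname))
        symbols = _read_lines(path / "genes.tsv")
        barcodes = _read_lines(path / "barcodes.tsv")
        mat = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
        counts = _orient(mat, len(barcodes), len(symbols), path / "matrix.mtx")
        layers = {}
        for f in sorted(path.glob("*.mtx")):
            if f.name == "matrix.mtx":
                continue
            lmat = sp.csr_matrix(scipy.io.mmread(f))
            layers[f.stem] = _orient(lmat, len(barcodes), len(symbols), f)
        cell_meta = gene_meta = None
        if (path / CELL_META_FILE).exists():
            cell_meta = pd.read_csv(path / CELL_META_FILE, sep="\t", index_col=0)
        if (path / GENE_META_FILE).exists():
            gene_meta = pd.read_csv(path / GENE_META_FILE, sep="\t", index_col=0)
        return make_dataset(counts, barcodes, symbols, layers, cell_meta, gene_meta)
    if format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return make_dataset(df.to_numpy(), df.index, df.columns)
    raise ValueError(f"unknown format {format!r}")


def write_dataset(adata: ad.AnnData, path, format: str = "mtx_dir") -> None:
    """Write a dataset; counts and identifiers round-trip bit-exactly."""
    validate_dataset(adata)
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        def _write_mtx(fname, mat, integer):
            coo = sp.coo_matrix(mat.T)  # genes x cells on disk
            if integer:
                coo = coo.astype(np.int64)
            scipy.io.mmwrite(
                str(path / fname), coo,
                field="integer" if integer else "real", precision=17,
            )
        _write_mtx("matrix.mtx", adata.X, integer=True)
        for name, mat in adata.layers.items():
            _write_mtx(f"{name}.mtx", mat, integer=name in INTEGER_LAYERS)
        (path / "barcodes.tsv").write_text("".join(f"{b}\n" for b in adata.obs_names))
        (path / "genes.tsv").write_text("".join(f"{g}\n" for g in adata.var_names))
        if adata.obs.shape[1]:
            adata.obs.to_csv(path / CELL_META_FILE, sep="\t")
        if adata.var.shape[1]:
            adata.var.to_csv(path / GENE_META_FILE, sep="\t")
        return
    if format == "dense_tsv":
        dense = np.asarray(adata.X.todense()) if sp.issparse(adata.X) else adata.X
        df = pd.DataFrame(
            dense.astype(np.int64), index=adata.obs_names, columns=adata.var_names
        )
        df.to_csv(path, sep="\t")
        return
    raise ValueError(f"unknown format {format!r}")
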