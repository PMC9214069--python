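"""Shared fixtures: programmatically generated datasets with known truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from retinodiff import preprocess
from retinodiff.io import make_dataset
from retinodiff.simulate import CellTypeSpec, SimConfig, simulate_timecourse


def normalized_dataset(values, barcodes=None, genes=None):
    """Wrap a dense matrix as a dataset whose normalized layer is `values`."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    barcodes = barcodes or [f"c{i:04d}" for i in range(n)]
    genes = genes or [f"g{j:04d}" for j in range(p)]
    adata = make_dataset(np.zeros((n, p), dtype=int), barcodes, genes)
    adata.layers["normalized"] = values
    return adata


def count_dataset(counts, barcodes=None, genes=None, cell_meta=None, normalize=True):
    counts = np.asarray(counts)
    n, p = counts.shape
    barcodes = barcodes or [f"c{i:04d}" for i in range(n)]
    genes = genes or [f"g{j:04d}" for j in range(p)]
    adata = make_dataset(counts, barcodes, genes, cell_meta=cell_meta)
    if normalize:
        preprocess.normalize_log(adata)
    return adata


def screen_mixture(seed, n_cells=2000):
    """D30-like progenitor / RPE / neural-tube mixture for the marker screen."""
    types = (
        CellTypeSpec("RetProg", 0, (0.4,)),
        CellTypeSpec("RPE", 1, (0.4,)),
        CellTypeSpec("NeuralTube", 2, (0.2,)),
    )
    cfg = SimConfig(
        n_cells_per_timepoint=n_cells,
        time_points=("D30",),
        cell_types=types,
        cycling_fraction=(0.15,),
        seed=seed,
    )
    adata, truth = simulate_timecourse(cfg)
    preprocess.normalize_log(adata)
    return adata, truth


def type_mixture(seed, n_types=5, n_cells=1500):
    """Balanced multi-type mixture with cluster labels (for label transfer)."""
    types = tuple(
        CellTypeSpec(f"T{i}", i, (1.0 / n_types,)) for i in range(n_types)
    )
    cfg = SimConfig(
        n_cells_per_timepoint=n_cells,
        time_points=("D0",),
        cell_types=types,
        cycling_fraction=(0.0,),
        seed=seed,
    )
    adata, truth = simulate_timecourse(cfg)
    preprocess.normalize_log(adata)
    adata.obs["cluster"] = adata.obs["cell_type"]
    return adata, truth


VELOCITY_GRID_ALPHA = (20.0, 40.0, 80.0)
VELOCITY_GRID_GAMMA = (0.25, 0.5, 1.0)
VELOCITY_BETA = 2.0


def velocity_grid_rates(seed, n_background=91):
    """3x3 (alpha, gamma) grid genes embedded in a background panel."""
    rng = np.random.default_rng(seed)
    grid = [(a, g) for a in VELOCITY_GRID_ALPHA for g in VELOCITY_GRID_GAMMA]
    alpha = np.array([a for a, _ in grid] + list(rng.uniform(10, 80, n_background)))
    gamma = np.array([g for _, g in grid] + list(rng.uniform(0.25, 1, n_background)))
    beta = np.full(alpha.size, VELOCITY_BETA)
    return alpha, beta, gamma, len(grid)


@pytest.fixture(scope="session")
def timecourse():
    """One default differentiation time course shared across tests."""
    adata, truth = simulate_timecourse(SimConfig(seed=5))
    preprocess.normalize_log(adata)
    return adata, truth
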