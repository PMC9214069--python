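"""Synthetic differentiation time courses with full ground truth.

The generator emulates the statistical structure of a staged hESC-to-RPE
differentiation experiment: a mixture of discrete cell types whose
composition shifts across ordered time points (diversity expanding early and
collapsing onto the RPE lineage late), marker gene programs per type,
correlated gene modules (low-rank log-mean perturbations), cell-cycle
programs in a cycling subpopulation, and spliced/unspliced layers drawn from
a transcription-splicing-degradation kinetic model.

Counts are negative binomial, parameterized by mean ``mu`` and a shared
inverse-dispersion ``theta`` (variance ``mu + mu**2 / theta``), sampled as a
gamma-Poisson mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .io import make_dataset

# Default composition: seven profiled time points from pluripotency (hESC)
# through replating (D38) to the D60 endpoint. Type diversity peaks at
# intermediate days and the late-RPE fraction rises 17.1% -> 55.7% -> 77.7%
# over the final three time points, mirroring the protocol's
# divergence-convergence dynamics.
DEFAULT_TIME_POINTS = ("hESC", "D7", "D14", "D30", "D38", "D45", "D60")

DEFAULT_COMPOSITION = {
    #               hESC   D7    D14   D30    D38    D45    D60
    "Pluri":      (1.00, 0.50, 0.10, 0.000, 0.009, 0.000, 0.000),
    "NeuralFold": (0.00, 0.20, 0.25, 0.050, 0.030, 0.000, 0.000),
    "RetProg":    (0.00, 0.30, 0.50, 0.300, 0.200, 0.093, 0.018),
    "EarlyRPE":   (0.00, 0.00, 0.15, 0.450, 0.300, 0.150, 0.005),
    "MidRPE":     (0.00, 0.00, 0.00, 0.200, 0.290, 0.200, 0.200),
    "LateRPE":    (0.00, 0.00, 0.00, 0.000, 0.171, 0.557, 0.777),
}

# Ordinal maturation index per default type (Pluri -> LateRPE).
DEFAULT_STAGES = {
    "Pluri": 0, "NeuralFold": 1, "RetProg": 2,
    "EarlyRPE": 3, "MidRPE": 4, "LateRPE": 5,
}

# Cycling fraction per time point: high in pluripotency, declining to D30,
# transiently up after replating, low at the endpoint.
DEFAULT_CYCLING = (0.60, 0.45, 0.35, 0.15, 0.30, 0.10, 0.05)


@dataclass(frozen=True)
class CellTypeSpec:
    """One simulated cell type: name, maturation stage, mixing proportions."""

    name: str
    stage: int
    proportions: tuple  # aligned with time_points, each in [0, 1]


@dataclass
class SimConfig:
    """Parameters of the time-course generator.

    Defaults are the study conditions the package is exercised under:
    ~400 cells per time point across seven time points, 1,000 genes with a
    baseline mean of 0.5 counts, 8-fold marker programs of 30 genes per
    type, three 50-gene correlated modules, and moderate NB overdispersion
    (theta = 2).
    """

    n_cells_per_timepoint: int = 400
    time_points: tuple = DEFAULT_TIME_POINTS
    cell_types: tuple = tuple(
        CellTypeSpec(name, DEFAULT_STAGES[name], props)
        for name, props in DEFAULT_COMPOSITION.items()
    )
    n_genes: int = 1000
    baseline_mean: float = 0.5
    # per-gene baselines are lognormal around baseline_mean (median), as
    # real transcriptomes span orders of magnitude in expression
    baseline_log_sd: float = 1.0
    marker_fold_change: float = 8.0
    program_size: int = 30
    nb_dispersion: float = 2.0
    n_modules: int = 3
    module_size: int = 50
    module_strength: float = 1.0
    cycling_fraction: tuple = DEFAULT_CYCLING
    cycle_fold_change: float = 6.0
    cycle_program_size: int = 20
    # canonical cycle genes (MKI67, TOP2A, ...) are strongly repressed in
    # non-cycling cells; this bimodality is what phase assignment relies on
    cycle_offstate_factor: float = 0.2
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_cells_per_timepoint <= 0 or self.n_genes <= 0:
            raise ValueError("cell and gene counts must be > 0")
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("baseline_mean and nb_dispersion must be > 0")
        if self.module_strength < 0:
            raise ValueError("module_strength must be >= 0")
        if len(self.cycling_fraction) != len(self.time_points):
            raise ValueError("cycling_fraction must align with time_points")
        for ct in self.cell_types:
            if len(ct.proportions) != len(self.time_points):
                raise ValueError(f"proportions of {ct.name!r} misaligned")
        props = np.array([ct.proportions for ct in self.cell_types])
        sums = props.sum(axis=0)
        if np.any(np.abs(sums - 1) > 1e-9):
            raise ValueError(f"type proportions must sum to 1 per time point, got {sums}")
        n_program = (len(self.cell_types) * self.program_size
                     + 2 * self.cycle_program_size)
        if self.n_modules * self.module_size + n_program > self.n_genes:
            raise ValueError("module and program genes exceed n_genes")
        return self


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    cells: pd.DataFrame  # cell_type, true_stage, time_point, cycle_phase
    module_scores: pd.DataFrame | None = None  # cells x modules factor scores
    programs: dict = field(default_factory=dict)  # type -> list of gene symbols
    kinetics: pd.DataFrame | None = None  # per gene alpha, beta, gamma


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return rng.poisson(lam)


def _gene_symbols(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_timecourse(cfg: SimConfig = SimConfig()) -> tuple[ad.AnnData, SimTruth]:
    """Draw a staged time course; identical cfg + seed gives identical output."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    symbols = _gene_symbols(cfg.n_genes)
    baselines = cfg.baseline_mean * np.exp(
        cfg.baseline_log_sd * rng.standard_normal(cfg.n_genes)
    )

    # Disjoint gene blocks: one marker program per type, S and G2M cycle
    # programs, then module blocks; the remainder follows the baseline only.
    cursor = 0
    programs: dict[str, list[str]] = {}
    prog_idx: dict[str, np.ndarray] = {}
    for ct in cfg.cell_types:
        idx = np.arange(cursor, cursor + cfg.program_size)
        prog_idx[ct.name] = idx
        programs[ct.name] = [symbols[i] for i in idx]
        cursor += cfg.program_size
    cycle_idx = {}
    for phase in ("S", "G2M"):
        idx = np.arange(cursor, cursor + cfg.cycle_program_size)
        cycle_idx[phase] = idx
        programs[f"cycle_{phase}"] = [symbols[i] for i in idx]
        cursor += cfg.cycle_program_size
    module_loadings = np.zeros((cfg.n_genes, cfg.n_modules))
    for m in range(cfg.n_modules):
        idx = np.arange(cursor, cursor + cfg.module_size)
        module_loadings[idx, m] = cfg.module_strength
        cursor += cfg.module_size

    n_total = cfg.n_cells_per_timepoint * len(cfg.time_points)
    counts = np.zeros((n_total, cfg.n_genes), dtype=np.int64)
    meta_rows = []
    factor_scores = np.zeros((n_total, cfg.n_modules))
    type_names = [ct.name for ct in cfg.cell_types]

    row = 0
    for t, tp in enumerate(cfg.time_points):
        props = np.array([ct.proportions[t] for ct in cfg.cell_types])
        assignment = rng.choice(len(type_names), size=cfg.n_cells_per_timepoint, p=props)
        cycling = rng.random(cfg.n_cells_per_timepoint) < cfg.cycling_fraction[t]
        phases = np.where(
            cycling, np.where(rng.random(cfg.n_cells_per_timepoint) < 0.5, "S", "G2M"),
            "G1_G0",
        )
        for c in range(cfg.n_cells_per_timepoint):
            ct = cfg.cell_types[assignment[c]]
            mean = baselines.copy()
            mean[prog_idx[ct.name]] *= cfg.marker_fold_change
            if phases[c] != "G1_G0":
                mean[cycle_idx[phases[c]]] *= cfg.cycle_fold_change
            else:
                for idx in cycle_idx.values():
                    mean[idx] *= cfg.cycle_offstate_factor
            z = rng.standard_normal(cfg.n_modules)
            factor_scores[row] = z
            mean = mean * np.exp(module_loadings @ z)
            counts[row] = _nb_counts(rng, mean, cfg.nb_dispersion)
            meta_rows.append((tp, ct.name, ct.stage, phases[c]))
            row += 1

    barcodes = [f"cell{i:06d}" for i in range(n_total)]
    cell_meta = pd.DataFrame(
        meta_rows, columns=["time_point", "cell_type", "true_stage", "cycle_phase"]
    )
    program_of = np.array(["" for _ in range(cfg.n_genes)], dtype=object)
    for name, syms in programs.items():
        for s_ in syms:
            program_of[symbols.index(s_)] = name
    gene_meta = pd.DataFrame({"baseline_mean": baselines, "program": program_of})
    adata = make_dataset(
        counts, barcodes, symbols, cell_meta=cell_meta, gene_meta=gene_meta
    )
    truth = SimTruth(
        cells=cell_meta.set_axis(pd.Index(barcodes, name="barcode")),
        module_scores=pd.DataFrame(
            factor_scores, index=barcodes,
            columns=[f"module{m}" for m in range(cfg.n_modules)],
        ),
        programs=programs,
    )
    return adata, truth


def _induction_moments(alpha, beta, gamma, t):
    """Expected (u, s) along the induction transient from (0, 0)."""
    u = alpha / beta * (1 - np.exp(-beta * t))
    if abs(gamma - beta) < 1e-8 * max(gamma, beta):
        s = alpha / gamma * (1 - np.exp(-gamma * t)) - alpha * t * np.exp(-gamma * t)
    else:
        s = alpha / gamma * (1 - np.exp(-gamma * t)) + alpha / (gamma - beta) * (
            np.exp(-gamma * t) - np.exp(-beta * t)
        )
    return u, s


def _repression_moments(u0, s0, beta, gamma, t):
    """Expected (u, s) decaying from (u0, s0) with transcription shut off."""
    u = u0 * np.exp(-beta * t)
    if abs(gamma - beta) < 1e-8 * max(gamma, beta):
        s = (s0 + beta * u0 * t) * np.exp(-gamma * t)
    else:
        s = s0 * np.exp(-gamma * t) + beta * u0 / (gamma - beta) * (
            np.exp(-beta * t) - np.exp(-gamma * t)
        )
    return u, s


def simulate_kinetics(
    alpha,
    beta,
    gamma,
    regime: str = "steady",
    n_cells: int = 2000,
    seed: int = 0,
    size_factor_sd: float = 0.3,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Sample spliced/unspliced layers from the splicing kinetic model.

    The model is ``du/dt = alpha - beta * u``, ``ds/dt = beta * u - gamma * s``.
    ``steady`` draws Poisson counts around the fixed point
    ``u* = alpha / beta``, ``s* = alpha / gamma``; ``induction`` samples cells
    uniformly along the transient from (0, 0); ``repression`` along the decay
    from the steady state with transcription shut off. Rates are per-gene
    arrays (broadcast against each other).

    Per-cell lognormal size factors (unit mean, ``sigma = size_factor_sd``)
    scale both expectations, emulating library-size variation: this spreads
    steady-state cells along the phase-portrait diagonal as in real data.
    Expectations are unchanged (``E[u] = u*``, ``E[s] = s*`` at steady state).

    Returns ``(unspliced, spliced, params)`` with cells x genes integer
    matrices and the per-gene rate table.
    """
    alpha, beta, gamma = np.broadcast_arrays(
        np.atleast_1d(np.asarray(alpha, dtype=float)),
        np.atleast_1d(np.asarray(beta, dtype=float)),
        np.atleast_1d(np.asarray(gamma, dtype=float)),
    )
    if np.any(alpha <= 0) or np.any(beta <= 0) or np.any(gamma <= 0):
        raise ValueError("kinetic rates must be > 0")
    if regime not in ("steady", "induction", "repression"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    n_genes = alpha.size
    u_mean = np.zeros((n_cells, n_genes))
    s_mean = np.zeros((n_cells, n_genes))
    for g in range(n_genes):
        a, b, c = alpha[g], beta[g], gamma[g]
        if regime == "steady":
            u_mean[:, g] = a / b
            s_mean[:, g] = a / c
        else:
            # sample the active phase of the transient (~3 slowest time
            # constants, by which point expression reaches ~95% of steady)
            t = rng.uniform(0, 3.0 / min(b, c), size=n_cells)
            if regime == "induction":
                u_mean[:, g], s_mean[:, g] = _induction_moments(a, b, c, t)
            else:
                u_mean[:, g], s_mean[:, g] = _repression_moments(a / b, a / c, b, c, t)
    if size_factor_sd > 0:
        sf = rng.lognormal(-size_factor_sd**2 / 2, size_factor_sd, size=n_cells)
        u_mean *= sf[:, None]
        s_mean *= sf[:, None]
    unspliced = rng.poisson(u_mean)
    spliced = rng.poisson(s_mean)
    params = pd.DataFrame({"alpha": alpha, "beta": beta, "gamma": gamma})
    return unspliced, spliced, params


def kinetic_dataset(
    alpha, beta, gamma, regime="steady", n_cells=2000, seed=0, size_factor_sd=0.3
) -> tuple[ad.AnnData, SimTruth]:
    """Wrap :func:`simulate_kinetics` output as a dataset with both layers."""
    u, s, params = simulate_kinetics(
        alpha, beta, gamma, regime, n_cells, seed, size_factor_sd
    )
    symbols = _gene_symbols(u.shape[1])
    barcodes = [f"cell{i:06d}" for i in range(n_cells)]
    adata = make_dataset(s, barcodes, symbols, layers={"spliced": s, "unspliced": u})
    params.index = pd.Index(symbols, name="symbol")
    truth = SimTruth(
        cells=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        kinetics=params,
    )
    return adata, truth


DEFAULT_STAGE_LABELS = ("W5", "W6-8", "W9-13", "W17-24", "Adult")


def simulate_ordinal_reference(
    n_stages: int = 5,
    cells_per_stage: int = 200,
    separation: float = 3.0,
    n_genes: int = 500,
    baseline_mean: float = 1.0,
    nb_dispersion: float = 2.0,
    stage_labels: tuple | None = None,
    seed: int = 0,
) -> tuple[ad.AnnData, SimTruth]:
    """Reference with gene programs shifting smoothly along an ordinal axis.

    Each gene is assigned a peak position on the maturation axis; its
    log-mean in stage ``k`` is boosted by a Gaussian bump
    ``separation * exp(-(k - peak)^2 / (2 * 0.75^2))``, so adjacent stages
    share more program overlap than distant ones and ``separation`` sets the
    between-stage distance (0 means no signal).
    """
    if n_stages < 2:
        raise ValueError("need at least 2 stages")
    if cells_per_stage < 2:
        raise ValueError("need at least 2 cells per stage")
    if stage_labels is None:
        stage_labels = (
            DEFAULT_STAGE_LABELS if n_stages == len(DEFAULT_STAGE_LABELS)
            else tuple(f"S{k}" for k in range(n_stages))
        )
    if len(stage_labels) != n_stages:
        raise ValueError("stage_labels must match n_stages")
    rng = np.random.default_rng(seed)
    symbols = _gene_symbols(n_genes)
    peaks = rng.uniform(-0.5, n_stages - 0.5, size=n_genes)
    width = 0.75
    n_total = n_stages * cells_per_stage
    counts = np.zeros((n_total, n_genes), dtype=np.int64)
    stages = np.repeat(np.arange(n_stages), cells_per_stage)
    for k in range(n_stages):
        bump = separation * np.exp(-((k - peaks) ** 2) / (2 * width**2))
        mean = baseline_mean * np.exp(bump)
        block = slice(k * cells_per_stage, (k + 1) * cells_per_stage)
        counts[block] = _nb_counts(
            rng, np.tile(mean, (cells_per_stage, 1)), nb_dispersion
        )
    barcodes = [f"ref{i:06d}" for i in range(n_total)]
    cell_meta = pd.DataFrame({
        "stage": [stage_labels[k] for k in stages],
        "true_stage": stages,
    })
    adata = make_dataset(counts, barcodes, symbols, cell_meta=cell_meta)
    truth = SimTruth(cells=cell_meta.set_axis(pd.Index(barcodes, name="barcode")))
    return adata, truth
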