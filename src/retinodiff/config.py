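"""Structured run configuration and the multi-stage pipeline driver.

A run is declared as nested key-value blocks (one block per stage plus
``global`` settings). Unknown keys are rejected by name. A single global
seed fans out to per-stage seeds by stable hashing of the stage name, so
inserting a stage does not perturb the randomness of the others. Every TSV
artifact is stamped with a header comment carrying the config hash and the
stage seed; identical config + seed reproduces artifacts byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import pandas as pd
import yaml

from . import dynamics, heterogeneity, markers, preprocess, qc, signatures, simulate
from .io import write_dataset

STAGE_KEYS = {
    "global": {"seed", "out_dir", "log_level"},
    "simulate": {"n_cells_per_timepoint", "n_genes", "baseline_mean",
                 "marker_fold_change", "nb_dispersion", "n_modules",
                 "module_size", "module_strength"},
    "qc": {"min_genes_per_cell", "min_cells_per_gene", "max_fraction_in_top_gene"},
    "preprocess": {"n_hvg", "n_pcs", "n_neighbors"},
    "score": {"signatures_file", "n_bins", "n_ctrl"},
    "cellcycle": {"threshold"},
    "positivity": {"genes", "group_by", "min_count"},
    "heterogeneity": {"group_by", "K", "n_perm"},
    "markers": {"cluster_key", "min_cells"},
    "velocity": {"quantile"},
}

PIPELINE_ORDER = list(STAGE_KEYS)[1:]


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping of stage blocks")
    bad_stages = sorted(set(cfg) - set(STAGE_KEYS))
    if bad_stages:
        raise ConfigError(f"unknown config block(s): {bad_stages}")
    for stage, block in cfg.items():
        if block is None:
            continue
        if not isinstance(block, dict):
            raise ConfigError(f"block {stage!r} must be a mapping")
        bad = sorted(set(block) - STAGE_KEYS[stage])
        if bad:
            raise ConfigError(f"unknown key(s) in block {stage!r}: {bad}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def stage_seed(global_seed: int, stage: str) -> int:
    return int((global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31))


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t")


def run_pipeline(cfg: dict, stages=None, out_dir=None) -> list[Path]:
    """Execute pipeline stages in declared order; return written artifacts.

    Stages that need inputs produced by earlier stages (everything after
    ``simulate``) consume the in-memory dataset as it flows through. The
    supported chain is simulate -> qc -> preprocess -> score / cellcycle /
    positivity / heterogeneity / markers / velocity.
    """
    validate_config(cfg)
    glob = cfg.get("global") or {}
    seed = int(glob.get("seed", 0))
    out = Path(out_dir or glob.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    stages = [s for s in (stages or PIPELINE_ORDER) if s in cfg or stages]
    unknown = sorted(set(stages) - set(STAGE_KEYS))
    if unknown:
        raise ConfigError(f"unknown stage(s): {unknown}")
    stages = [s for s in PIPELINE_ORDER if s in stages]

    artifacts: list[Path] = []
    adata = None
    hvg = None
    embedding = None

    def stamp(stage):
        return f"# retinodiff config_hash={chash} stage={stage} seed={stage_seed(seed, stage)}\n"

    for stage in stages:
        block = cfg.get(stage) or {}
        sseed = stage_seed(seed, stage)
        if stage == "simulate":
            sim_cfg = simulate.SimConfig(**block, seed=sseed)
            adata, truth = simulate.simulate_timecourse(sim_cfg)
            write_dataset(adata, out / "dataset")
            _write_tsv(truth.cells, out / "truth_cells.tsv", stamp(stage))
            artifacts += [out / "dataset", out / "truth_cells.tsv"]
        elif stage == "qc":
            _require(adata, stage)
            adata, report = qc.qc_filter(adata, qc.QCConfig(**block))
            _write_tsv(report, out / "qc_report.tsv", stamp(stage))
            artifacts.append(out / "qc_report.tsv")
        elif stage == "preprocess":
            _require(adata, stage)
            preprocess.normalize_log(adata)
            hvg = preprocess.select_hvg_cv_mean(adata, n=block.get("n_hvg", 2000))
            d = min(block.get("n_pcs", 50), adata.n_obs - 1, len(hvg.selected_genes))
            embedding = preprocess.pca(adata, genes=hvg.selected_genes, d=d)
            _write_tsv(hvg.stats, out / "hvg.tsv", stamp(stage))
            coords = pd.DataFrame(
                embedding.coordinates, index=adata.obs_names,
                columns=[f"PC{i+1}" for i in range(embedding.coordinates.shape[1])],
            )
            _write_tsv(coords, out / "pca.tsv", stamp(stage))
            artifacts += [out / "hvg.tsv", out / "pca.tsv"]
        elif stage == "score":
            _require(adata, stage, normalized=True)
            sigs = (signatures.read_signatures(block["signatures_file"])
                    if "signatures_file" in block else signatures.builtin_signatures())
            scores = {}
            for i, (name, sig) in enumerate(sigs.items()):
                try:
                    scores[name] = signatures.score_signature(
                        adata, sig, n_bins=block.get("n_bins", 25),
                        n_ctrl=block.get("n_ctrl", 50), seed=sseed + i,
                    )
                except ValueError:
                    continue  # signature absent from the panel
            df = pd.DataFrame(scores, index=adata.obs_names)
            _write_tsv(df, out / "signature_scores.tsv", stamp(stage))
            artifacts.append(out / "signature_scores.tsv")
        elif stage == "cellcycle":
            _require(adata, stage, normalized=True)
            sigs = signatures.builtin_signatures()
            try:
                cc = signatures.assign_cell_cycle(
                    adata, sigs["S"], sigs["G2M"],
                    threshold=block.get("threshold", 0.0), seed=sseed,
                )
            except ValueError:
                continue  # cycle genes absent from the panel
            _write_tsv(cc.to_frame(adata.obs_names), out / "cell_cycle.tsv", stamp(stage))
            artifacts.append(out / "cell_cycle.tsv")
        elif stage == "positivity":
            _require(adata, stage)
            frames = []
            for gene in block.get("genes", []):
                df = signatures.positive_fraction(
                    adata, gene, group_by=block.get("group_by", "time_point"),
                    min_count=block.get("min_count", 1),
                )
                df.insert(0, "gene", gene)
                frames.append(df)
            if frames:
                _write_tsv(pd.concat(frames), out / "positivity.tsv", stamp(stage))
                artifacts.append(out / "positivity.tsv")
        elif stage == "heterogeneity":
            _require(adata, stage, normalized=True)
            genes = hvg.selected_genes if hvg is not None else None
            df = heterogeneity.heterogeneity_by_group(
                adata, group_by=block.get("group_by", "time_point"),
                genes=genes, K=block.get("K", 50),
                n_perm=block.get("n_perm", 20), seed=sseed,
            )
            _write_tsv(df, out / "heterogeneity.tsv", stamp(stage))
            artifacts.append(out / "heterogeneity.tsv")
        elif stage == "markers":
            _require(adata, stage, normalized=True)
            key = block.get("cluster_key", "cell_type")
            table = markers.enriched_genes(
                adata, cluster_key=key, min_cells=block.get("min_cells", 3)
            )
            _write_tsv(table.set_index("gene"), out / "enriched_genes.tsv", stamp(stage))
            artifacts.append(out / "enriched_genes.tsv")
        elif stage == "velocity":
            _require(adata, stage)
            if "spliced" not in adata.layers:
                continue
            fit = dynamics.fit_steady_state(adata, quantile=block.get("quantile", 0.05))
            _write_tsv(fit.genes, out / "velocity_fit.tsv", stamp(stage))
            artifacts.append(out / "velocity_fit.tsv")
    return artifacts


def _require(adata, stage, normalized=False):
    if adata is None:
        raise ConfigError(f"stage {stage!r} needs a dataset from an earlier stage")
    if normalized and "normalized" not in adata.layers:
        preprocess.normalize_log(adata)
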