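"""End-to-end orchestration of the cellular-program workflow.

``run`` executes the stage chain simulate -> qc -> compose -> programs ->
roe -> entropy -> signatures -> score -> lr from one configuration, writing
every stage's output plus a manifest with the config hash, seed and
per-output checksums.  Reruns with the same configuration and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import simulate as sim
from . import io_qc, composition, enrichment, signatures as sigmod, communication

log = logging.getLogger("cellprograms")

__all__ = ["PipelineConfig", "PipelineError", "run", "load_config"]

STAGES = (
    "simulate", "qc", "compose", "programs", "roe",
    "entropy", "signatures", "score", "lr",
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "cp_output"
    seed: int = 0
    # simulate mode: SyntheticConfig field overrides; run mode: input paths
    simulate: dict[str, Any] | None = None
    cells_path: str | None = None
    expression_path: str | None = None
    # stage parameters
    level: str = "level1"
    k: int = 6
    min_cells_per_sample: int = 50
    qc_min_genes: int = 200
    qc_max_mito_fraction: float = 0.20
    qc_mito_prefix: str = "MT-"
    normalize_scale: float = 1e4
    entropy_label: str = "cnv_cluster"
    entropy_base: Any = "e"
    entropy_normalized: bool = False
    signature_level: str = "level1"
    signature_top_n: int = 20
    signature_min_lfc: float = 0.25
    signature_max_padj: float = 0.05
    rank_ceiling: int = 1500
    lr_pairs_path: str | None = None
    lr_cluster_pairs: list[list[str]] | None = None
    lr_n_perm: int = 1000
    lr_min_fraction: float = 0.20
    lr_alpha: float = 0.05
    lr_gate_mode: str = "both"
    lr_within_sample: bool = False

    def canonical(self) -> dict[str, Any]:
        d = {k: v for k, v in self.__dict__.items()}
        return json.loads(json.dumps(d, sort_keys=True, default=str))

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML (or JSON) pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "cellprograms",
        "version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": config.canonical(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }

    def record(stage: str, outputs: dict[str, int]) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "outputs": [
                    {"path": p, "sha256": _sha256(outdir / p), "rows": rows}
                    for p, rows in outputs.items()
                ],
            }
        )
        log.info("stage %s complete (%d outputs)", stage, len(outputs))

    def guard(stage: str):
        class _Guard:
            def __enter__(self):
                log.info("stage %s starting", stage)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(stage, str(exc)) from exc
                return False

        return _Guard()

    # -- simulate ------------------------------------------------------------
    with guard("simulate"):
        if config.simulate is None:
            if not (config.cells_path and config.expression_path):
                raise ValueError(
                    "provide either a 'simulate' block or cells/expression paths"
                )
            cells = io_qc.read_cells(config.cells_path)
            adata = io_qc.read_expression(config.expression_path)
            truth = None
            record("simulate", {})
        else:
            syn = sim.SyntheticConfig(**{**config.simulate, "seed": config.seed})
            cells, truth = sim.generate_cohort(syn)
            adata = sim.generate_expression(syn, cells)
            sim.write_cohort(cells, truth, outdir, adata)
            record(
                "simulate",
                {
                    "cells.tsv": len(cells),
                    "ground_truth.json": len(truth.program_of_sample),
                    "expression/matrix.mtx": adata.n_obs,
                },
            )

    # -- qc ------------------------------------------------------------------
    with guard("qc"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adata, cells, report = io_qc.qc_filter(
                adata, cells,
                min_genes=config.qc_min_genes,
                max_mito_fraction=config.qc_max_mito_fraction,
                mito_prefix=config.qc_mito_prefix,
            )
            adata = io_qc.normalize_log1p(adata, scale=config.normalize_scale)
        if adata.n_obs == 0:
            raise ValueError("QC removed every cell; lower qc_min_genes?")
        io_qc.write_cells(cells, outdir / "cells_qc.tsv")
        report.to_json(outdir / "qc_report.json")
        record("qc", {"cells_qc.tsv": len(cells), "qc_report.json": 1})

    # -- compose -------------------------------------------------------------
    with guard("compose"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = composition.infiltration_matrix(
                cells, level=config.level,
                min_cells_per_sample=config.min_cells_per_sample,
            )
        comp.to_csv(outdir / "composition.csv")
        record("compose", {"composition.csv": comp.shape[0]})

    # -- programs ------------------------------------------------------------
    with guard("programs"):
        if config.k > comp.shape[0]:
            raise ValueError(
                f"k={config.k} programs requested but only {comp.shape[0]} "
                f"samples survive composition; lower k or add samples"
            )
        similarity = composition.sample_similarity(comp)
        partition = composition.discover_programs(similarity, k=config.k)
        similarity.to_csv(outdir / "correlation.csv")
        partition.to_csv(outdir / "programs.csv")
        partition.dendrogram_json(outdir / "dendrogram.json")
        record(
            "programs",
            {
                "programs.csv": len(partition.labels),
                "correlation.csv": similarity.shape[0],
                "dendrogram.json": len(partition.linkage),
            },
        )

    # -- roe -----------------------------------------------------------------
    with guard("roe"):
        scored_cells = cells[cells["sample_id"].isin(partition.labels.index)]
        table = enrichment.contingency(
            scored_cells, row_level=config.signature_level,
            col_by="program", partition=partition,
        )
        roe_table = enrichment.roe(table)
        roe_table.roe.to_csv(outdir / "roe.csv")
        roe_table.to_long_csv(outdir / "enriched.csv")
        record("roe", {"roe.csv": roe_table.roe.shape[0],
                       "enriched.csv": roe_table.roe.size})

    # -- entropy -------------------------------------------------------------
    with guard("entropy"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ent = enrichment.sample_entropy(
                cells, label=config.entropy_label,
                base=config.entropy_base,
                normalized=config.entropy_normalized,
            )
        ent.to_csv(outdir / "entropy.csv")
        record("entropy", {"entropy.csv": len(ent)})

    # -- signatures ----------------------------------------------------------
    with guard("signatures"):
        level = config.signature_level
        targets = sorted(cells[level].dropna().unique())
        sigs, de_frames = [], []
        for t in targets:
            de = sigmod.rank_sum_de(adata, cells, target=t, level=level)
            de_frames.append(de.assign(cluster=t))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    sigs.append(
                        sigmod.build_signature(
                            de, name=t,
                            top_n=config.signature_top_n,
                            min_lfc=config.signature_min_lfc,
                            max_padj=config.signature_max_padj,
                        )
                    )
                except ValueError:
                    log.warning("no signature for cluster %s", t)
        if not sigs:
            raise ValueError("no cluster yielded a signature")
        pd.concat(de_frames).to_csv(outdir / "de.csv")
        sigmod.write_gmt(sigs, outdir / "signatures.gmt")
        record("signatures", {"de.csv": sum(map(len, de_frames)),
                              "signatures.gmt": len(sigs)})

    # -- score ---------------------------------------------------------------
    with guard("score"):
        ceiling = min(config.rank_ceiling, adata.n_vars)
        scores = sigmod.score_signatures(adata, sigs, rank_ceiling=ceiling)
        scores.rename_axis("cell_id").to_csv(outdir / "module_scores.csv")
        record("score", {"module_scores.csv": len(scores)})

    # -- lr ------------------------------------------------------------------
    with guard("lr"):
        if config.lr_pairs_path is not None:
            pairs = communication.read_lr_pairs(config.lr_pairs_path)
        elif truth is not None and truth.planted_lr:
            pairs = [
                communication.LRPair(f"{l}-{r}", (l,), (r,))
                for l, r, _, _, _ in truth.planted_lr
            ]
        else:
            pairs = []
        if config.lr_cluster_pairs is not None:
            cluster_pairs = [tuple(cp) for cp in config.lr_cluster_pairs]
        elif truth is not None and truth.planted_lr:
            cluster_pairs = sorted(
                {(s, r) for _, _, s, r, _ in truth.planted_lr}
            )
        else:
            cluster_pairs = []
        if pairs and cluster_pairs:
            results = communication.permutation_test(
                adata, cells, pairs, cluster_pairs,
                level=config.level,
                n_perm=config.lr_n_perm,
                seed=config.seed,
                alpha=config.lr_alpha,
                min_fraction=config.lr_min_fraction,
                gate_mode=config.lr_gate_mode,
                within_sample=config.lr_within_sample,
            )
            frame = communication.results_to_frame(results)
        else:
            frame = communication.results_to_frame([])
            log.warning("no LR pairs configured; writing empty results")
        frame.to_csv(outdir / "lr_results.csv", index=False)
        record("lr", {"lr_results.csv": len(frame)})

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
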