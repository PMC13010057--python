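"""Synthetic multi-sample single-cell cohorts with known ground truth.

Cohorts emulate the compositional structure of a tumor-microenvironment
atlas: each sample belongs to one of K latent cellular programs, its
cell-type composition is drawn from a Dirichlet centred on the program's
characteristic composition, and expression counts follow a Gamma-Poisson
(negative binomial) model with planted marker genes and optional planted
ligand-receptor interactions.  Every random draw is routed through a
counter-based per-sample substream of one global seed, so generated
samples are stable under cohort extension.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse

__all__ = [
    "ConfigurationError",
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_expression",
    "ground_truth_entropy",
    "write_cohort",
]

# substream tags for SeedSequence spawn keys
_STREAM_COMPOSITION = 0
_STREAM_CNV = 1
_STREAM_EXPRESSION = 2


class ConfigurationError(ValueError):
    """Raised when a synthetic-cohort configuration is internally inconsistent."""


def default_program_centers(
    n_programs: int, n_types: int, elevation_fold: float = 8.0
) -> np.ndarray:
    """Separable program centers: program k elevates a disjoint block of
    ``n_types // n_programs`` cell types by ``elevation_fold`` over a uniform
    baseline, then renormalizes.

    With block size m and fold f the total-variation distance between any two
    centers is ``m (f - 1) / (T + m (f - 1))`` (0.507 for T=34, K=6, f=8).
    """
    if n_programs < 1 or n_types < 2:
        raise ConfigurationError("need n_programs >= 1 and >= 2 cell types")
    m = n_types // n_programs
    if m < 1:
        raise ConfigurationError(
            f"cannot auto-generate centers: {n_programs} programs need at "
            f"least {n_programs} cell types, got {n_types}"
        )
    centers = np.ones((n_programs, n_types), dtype=float)
    for k in range(n_programs):
        centers[k, k * m : (k + 1) * m] = elevation_fold
    return centers / centers.sum(axis=1, keepdims=True)


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic cohort.

    Defaults describe a cohort of 6 programs x 10 samples over 34 cell types
    with moderate compositional noise (Dirichlet concentration 100) and
    2,000 cells per sample, i.e. the scale at which program structure in
    liver-related tumor cohorts is typically resolvable.
    """

    n_programs: int = 6
    samples_per_program: int = 10
    cell_types: Sequence[str] = ()
    program_centers: np.ndarray | None = None
    dirichlet_concentration: float = 100.0
    cells_per_sample: tuple[int, int] = (2000, 2000)
    n_genes: int = 1000
    markers_per_type: int = 20
    marker_fold: float = 4.0
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    planted_lr: list[tuple[str, str, str, str, float]] = field(default_factory=list)
    cnv_clusters: int = 6
    cnv_diversity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cell_types:
            self.cell_types = tuple(f"CT{i + 1:02d}" for i in range(34))
        self.cell_types = tuple(self.cell_types)
        if self.n_programs < 1:
            raise ConfigurationError("n_programs must be >= 1")
        if self.samples_per_program < 1:
            raise ConfigurationError("samples_per_program must be >= 1")
        if len(self.cell_types) < 2:
            raise ConfigurationError("need at least 2 cell types")
        if self.program_centers is None:
            self.program_centers = default_program_centers(
                self.n_programs, len(self.cell_types)
            )
        self.program_centers = np.asarray(self.program_centers, dtype=float)
        if self.program_centers.shape != (self.n_programs, len(self.cell_types)):
            raise ConfigurationError(
                "program_centers must have shape (n_programs, n_cell_types)"
            )
        if np.any(self.program_centers < 0) or np.any(
            np.abs(self.program_centers.sum(axis=1) - 1.0) > 1e-9
        ):
            raise ConfigurationError(
                "every program center must lie on the simplex "
                "(non-negative, summing to 1 within 1e-9)"
            )
        lo, hi = self.cells_per_sample
        if lo > hi or lo < 1:
            raise ConfigurationError("cells_per_sample must satisfy 1 <= min <= max")
        if self.dirichlet_concentration <= 0:
            raise ConfigurationError("dirichlet_concentration must be positive")
        if self.marker_fold <= 1:
            raise ConfigurationError("marker_fold must exceed 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ConfigurationError("baseline_mean and dispersion must be positive")
        if self.cnv_clusters < 1:
            raise ConfigurationError("cnv_clusters must be >= 1")
        if self.cnv_diversity <= 0:
            raise ConfigurationError("cnv_diversity must be positive")
        needed = len(self.cell_types) * self.markers_per_type
        if self.n_genes < needed:
            raise ConfigurationError(
                f"n_genes={self.n_genes} cannot hold {needed} disjoint marker genes"
            )

    # -- deterministic naming ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.n_programs * self.samples_per_program

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]

    def sample_program(self, sample_index: int) -> int:
        """True program index of the sample at a given global index."""
        return sample_index // self.samples_per_program

    def gene_names(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def marker_genes(self) -> dict[str, list[str]]:
        """Disjoint marker-gene blocks: type t owns genes
        [t*markers_per_type, (t+1)*markers_per_type)."""
        genes = self.gene_names()
        m = self.markers_per_type
        return {
            t: genes[i * m : (i + 1) * m] for i, t in enumerate(self.cell_types)
        }

    def _rng(self, sample_index: int, stream: int) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(sample_index, stream))
        return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """What the generator actually did, for downstream oracles."""

    program_of_sample: dict[str, str]
    composition: pd.DataFrame  # samples x cell types, the drawn Dirichlet vectors
    marker_genes: dict[str, list[str]]
    planted_lr: list[tuple[str, str, str, str, float]]
    cnv_proportions: pd.DataFrame  # samples x cnv clusters, drawn Dirichlet vectors

    def to_json(self, path: str | Path) -> None:
        payload = {
            "program_of_sample": self.program_of_sample,
            "composition": {
                s: self.composition.loc[s].round(12).to_dict()
                for s in self.composition.index
            },
            "marker_genes": self.marker_genes,
            "planted_lr": [list(t) for t in self.planted_lr],
            "cnv_proportions": {
                s: self.cnv_proportions.loc[s].round(12).to_dict()
                for s in self.cnv_proportions.index
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _sample_draws(config: SyntheticConfig, sample_index: int):
    """Composition, cell count, per-cell types and CNV labels for one sample.

    Everything is a pure function of (config, sample_index); the CNV labels
    additionally depend only on their dedicated substream so they can be
    regenerated in isolation by :func:`ground_truth_entropy`.
    """
    rng = config._rng(sample_index, _STREAM_COMPOSITION)
    program = config.sample_program(sample_index)
    alpha = config.dirichlet_concentration * config.program_centers[program]
    composition = rng.dirichlet(alpha)
    lo, hi = config.cells_per_sample
    n_cells = int(rng.integers(lo, hi + 1))
    type_counts = rng.multinomial(n_cells, composition)

    rng_cnv = config._rng(sample_index, _STREAM_CNV)
    cnv_props = rng_cnv.dirichlet(
        np.full(config.cnv_clusters, config.cnv_diversity)
    )
    cnv_labels = rng_cnv.choice(config.cnv_clusters, size=n_cells, p=cnv_props)
    return composition, type_counts, cnv_props, cnv_labels


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a cohort's cell-annotation table plus its ground truth.

    Each sample's cell-type composition is Dirichlet(alpha * center) with
    alpha the concentration and center its program's characteristic
    composition; cell-type counts are multinomial given the composition.
    Per-cell CNV-cluster labels come from a per-sample Dirichlet-multinomial
    with symmetric concentration ``cnv_diversity``.

    Returns a table with columns cell_id, sample_id, group, organ, level1,
    level2, level3, cnv_cluster (level2/level3 mirror level1 — the synthetic
    hierarchy is flat) and a :class:`GroundTruth`.
    """
    sample_ids = config.sample_ids()
    rows_cells = []
    comp_rows = []
    cnv_rows = []
    program_of_sample = {}
    types = np.asarray(config.cell_types, dtype=object)
    for i, sid in enumerate(sample_ids):
        composition, type_counts, cnv_props, cnv_labels = _sample_draws(config, i)
        program_of_sample[sid] = f"P{config.sample_program(i) + 1}"
        comp_rows.append(composition)
        cnv_rows.append(cnv_props)
        cell_types = np.repeat(types, type_counts)
        n = cell_types.size
        df = pd.DataFrame(
            {
                "cell_id": [f"{sid}_c{j:05d}" for j in range(n)],
                "sample_id": sid,
                "group": "HM",
                "organ": "liver",
                "level1": cell_types,
                "cnv_cluster": [f"C{c + 1}" for c in cnv_labels],
            }
        )
        rows_cells.append(df)
    cells = pd.concat(rows_cells, ignore_index=True)
    cells["level2"] = cells["level1"]
    cells["level3"] = cells["level1"]
    cells = cells[
        ["cell_id", "sample_id", "group", "organ",
         "level1", "level2", "level3", "cnv_cluster"]
    ]
    truth = GroundTruth(
        program_of_sample=program_of_sample,
        composition=pd.DataFrame(
            comp_rows, index=sample_ids, columns=list(config.cell_types)
        ),
        marker_genes=config.marker_genes(),
        planted_lr=list(config.planted_lr),
        cnv_proportions=pd.DataFrame(
            cnv_rows,
            index=sample_ids,
            columns=[f"C{c + 1}" for c in range(config.cnv_clusters)],
        ),
    )
    return cells, truth


def _type_mean_matrix(config: SyntheticConfig) -> pd.DataFrame:
    """Generative mean of every gene in every cell type (types x genes)."""
    genes = config.gene_names()
    mu = pd.DataFrame(
        config.baseline_mean,
        index=list(config.cell_types),
        columns=genes,
        dtype=float,
    )
    for t, marker_list in config.marker_genes().items():
        mu.loc[t, marker_list] *= config.marker_fold
    for ligand, receptor, sender, receiver, fold in config.planted_lr:
        for g, ct in ((ligand, sender), (receptor, receiver)):
            if g not in mu.columns:
                raise ConfigurationError(f"planted LR gene {g!r} not in gene panel")
            if ct not in mu.index:
                raise ConfigurationError(f"planted LR cell type {ct!r} unknown")
        mu.loc[sender, ligand] *= fold
        mu.loc[receiver, receptor] *= fold
    return mu


def generate_expression(config: SyntheticConfig, cells: pd.DataFrame) -> ad.AnnData:
    """Negative-binomial counts for a generated cohort.

    Counts are Gamma-Poisson: rate ~ Gamma(shape=dispersion,
    scale=mu/dispersion), count ~ Poisson(rate), so each gene has mean mu and
    variance mu + mu^2/dispersion.  mu is ``baseline_mean`` lifted by
    ``marker_fold`` for a type's markers in cells of that type and by the
    planted fold for ligand/receptor genes in sender/receiver types.
    """
    unknown = set(cells["level1"]) - set(config.cell_types)
    if unknown:
        raise ValueError(f"unknown cell types in table: {sorted(unknown)}")
    mu = _type_mean_matrix(config)
    sample_index = {sid: i for i, sid in enumerate(config.sample_ids())}
    blocks = []
    order = []
    for sid, sub in cells.groupby("sample_id", sort=False):
        if sid not in sample_index:
            raise ValueError(f"sample {sid!r} not generated by this config")
        rng = config._rng(sample_index[sid], _STREAM_EXPRESSION)
        cell_mu = mu.loc[sub["level1"]].to_numpy()
        lam = rng.gamma(
            shape=config.dispersion, scale=cell_mu / config.dispersion
        )
        counts = rng.poisson(lam)
        blocks.append(sparse.csr_matrix(counts))
        order.extend(sub.index)
    X = sparse.vstack(blocks, format="csr")
    obs_names = cells.loc[order, "cell_id"].to_numpy()
    adata = ad.AnnData(
        X=X.astype(np.float64),
        obs=pd.DataFrame(index=pd.Index(obs_names, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(config.gene_names(), name="gene")),
    )
    # restore the input cell order (groupby preserved it, but be explicit)
    adata = adata[cells["cell_id"].to_numpy()].copy()
    return adata


def ground_truth_entropy(config: SyntheticConfig, sample: str) -> float:
    """Shannon entropy (nats) of a generated sample's realized CNV labels.

    Recomputes the sample's CNV label draw from its dedicated RNG substream
    and tallies proportions with a plain Counter — deliberately sharing no
    code with the pipeline's entropy routine so the two act as mutual
    oracles.
    """
    try:
        i = config.sample_ids().index(sample)
    except ValueError:
        raise ValueError(f"sample {sample!r} does not exist in this config") from None
    _, _, _, cnv_labels = _sample_draws(config, i)
    n = len(cnv_labels)
    if n == 0:
        raise ValueError(f"sample {sample!r} is empty")
    h = 0.0
    for count in Counter(cnv_labels.tolist()).values():
        p = count / n
        h -= p * math.log(p)
    return h


def write_cohort(
    cells: pd.DataFrame,
    truth: GroundTruth,
    outdir: str | Path,
    adata: ad.AnnData | None = None,
) -> None:
    """Write cells as TSV, ground truth as JSON and (optionally) expression
    as MatrixMarket with genes/barcodes sidecars."""
    from . import io_qc

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_qc.write_cells(cells, outdir / "cells.tsv")
    truth.to_json(outdir / "ground_truth.json")
    if adata is not None:
        io_qc.write_expression_mtx(adata, outdir / "expression")
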