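"""Marker selection, gene signatures and rank-based module scoring.

Markers come from a two-sided Wilcoxon rank-sum test of a target cluster
against all other cells on log-normalized expression, with
Benjamini-Hochberg adjustment.  Signatures are the top genes by log2 fold
change passing effect-size and FDR filters (top 20 for subtype identity;
the spatial preset uses log2FC > 0.5, adjusted P < 1e-4, top 500).  Cells
or spots are scored with a Mann-Whitney U statistic on within-cell
expression ranks: score = 1 - U / (n * rank_ceiling), a depth-robust
number in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .io_qc import NORMALIZED_LAYER

__all__ = [
    "GeneSignature",
    "rank_sum_de",
    "build_signature",
    "module_score",
    "score_signatures",
    "read_gmt",
    "write_gmt",
    "SPATIAL_PRESET",
    "IDENTITY_PRESET",
]

# (top_n, min_lfc, max_padj)
IDENTITY_PRESET = dict(top_n=20, min_lfc=0.25, max_padj=0.05)
SPATIAL_PRESET = dict(top_n=500, min_lfc=0.5, max_padj=1e-4)

_EPS = 1e-9


def rank_sum_de(
    adata: ad.AnnData,
    cells: pd.DataFrame,
    target: str,
    level: str = "level3",
) -> pd.DataFrame:
    """Two-sided rank-sum DE of ``target`` cluster vs all other cells.

    Returns a per-gene table with log2 fold change
    log2((mean_target + eps) / (mean_rest + eps)) of the normalized layer,
    raw and BH-adjusted p-values, and the fraction of expressing cells on
    each side.  Genes at zero in both arms get p = 1, log2FC = 0.
    """
    if NORMALIZED_LAYER not in adata.layers:
        raise ValueError("normalized layer missing; run normalize_log1p first")
    labels = cells.set_index("cell_id").loc[list(adata.obs_names), level]
    in_target = (labels == target).to_numpy()
    if not in_target.any():
        raise ValueError(f"target cluster {target!r} is empty")
    if in_target.all():
        raise ValueError("target covers every cell; no complement to test against")
    X = sparse.csr_matrix(adata.layers[NORMALIZED_LAYER])
    xt = np.asarray(X[in_target].todense())
    xr = np.asarray(X[~in_target].todense())
    mean_t = xt.mean(axis=0)
    mean_r = xr.mean(axis=0)
    lfc = np.log2((mean_t + _EPS) / (mean_r + _EPS))
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(
            xt, xr, axis=0, alternative="two-sided", method="asymptotic"
        )
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (mean_t == 0) & (mean_r == 0)
    # zero-variance genes: the statistic is undefined, define the null result
    allsame = np.isnan(p) | degenerate
    p[allsame] = 1.0
    lfc[degenerate] = 0.0
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "pvalue": p,
            "padj": padj,
            "frac_target": (xt > 0).mean(axis=0),
            "frac_rest": (xr > 0).mean(axis=0),
        },
        index=pd.Index(adata.var_names, name="gene"),
    )


@dataclass
class GeneSignature:
    """A named, log2FC-ordered gene list."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")


def build_signature(
    de: pd.DataFrame,
    name: str,
    top_n: int = 20,
    min_lfc: float = 0.25,
    max_padj: float = 0.05,
) -> GeneSignature:
    """Genes with log2FC > min_lfc and adjusted p < max_padj (both strict),
    sorted by descending log2FC (ties by gene name), truncated to top_n."""
    pass_lfc = de["log2fc"] > min_lfc
    pass_p = de["padj"] < max_padj
    passing = de[pass_lfc & pass_p]
    if passing.empty:
        raise ValueError(
            f"no genes pass filters for {name!r} "
            f"(log2FC > {min_lfc}: {int(pass_lfc.sum())}; "
            f"padj < {max_padj}: {int(pass_p.sum())})"
        )
    # stable sort: gene name ascending first, then log2FC descending on top
    ordered = passing.sort_index().sort_values(
        "log2fc", ascending=False, kind="mergesort"
    )
    genes = list(ordered.index[:top_n])
    if len(genes) < top_n:
        warnings.warn(
            f"signature {name!r}: only {len(genes)} of {top_n} requested genes pass"
        )
    return GeneSignature(name=name, genes=genes)


def module_score(
    adata: ad.AnnData,
    sig: GeneSignature,
    rank_ceiling: int = 1500,
    layer: str | None = NORMALIZED_LAYER,
) -> pd.Series:
    """Rank-based (Mann-Whitney U) module score of a signature per cell.

    Per cell, genes are ranked by decreasing expression with average ranks
    for ties (so all zero-expression genes share one bottom tie block);
    ranks beyond ``rank_ceiling`` are set to rank_ceiling + 1.  With r_i the
    ranks of the n signature genes, U = sum r_i - n(n+1)/2 and
    score = 1 - U / (n * rank_ceiling), floored at 0.  Scores lie in [0, 1]
    and are invariant to positive per-cell scaling.
    """
    present = [g for g in sig.genes if g in adata.var_names]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} is in the matrix")
    if rank_ceiling < len(present):
        raise ValueError("rank_ceiling must be >= signature size")
    if layer is not None and layer in adata.layers:
        X = adata.layers[layer]
    else:
        X = adata.X
    X = np.asarray(sparse.csr_matrix(X).todense())
    ranks = stats.rankdata(-X, axis=1, method="average")
    ranks = np.minimum(ranks, rank_ceiling + 1)
    cols = [adata.var_names.get_loc(g) for g in present]
    n = len(present)
    u = ranks[:, cols].sum(axis=1) - n * (n + 1) / 2.0
    score = np.maximum(1.0 - u / (n * rank_ceiling), 0.0)
    return pd.Series(score, index=adata.obs_names, name=sig.name)


def score_signatures(
    adata: ad.AnnData,
    signatures: list[GeneSignature],
    rank_ceiling: int = 1500,
    layer: str | None = NORMALIZED_LAYER,
) -> pd.DataFrame:
    """Cells x signatures module-score table."""
    return pd.DataFrame(
        {s.name: module_score(adata, s, rank_ceiling, layer) for s in signatures}
    )


def write_gmt(signatures: list[GeneSignature], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, "cellprograms"] + list(s.genes)) for s in signatures
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> list[GeneSignature]:
    sigs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sigs.append(GeneSignature(name=fields[0], genes=fields[2:]))
    return sigs
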