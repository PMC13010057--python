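"""Sample-level composition profiles and cellular-program (CP) discovery.

A cohort's tumor microenvironment is summarized per sample as an
infiltration vector — the fraction of the sample's cells annotated to each
cell type at a chosen hierarchy level.  Samples with similar composition
are grouped into recurrent cellular programs by complete-linkage
hierarchical clustering of the Spearman correlation between infiltration
profiles, with the dendrogram cut at a user-chosen number of programs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .io_qc import NORMALIZED_LAYER

__all__ = [
    "ProgramPartition",
    "infiltration_matrix",
    "sample_similarity",
    "discover_programs",
    "program_stability",
    "pseudobulk_profiles",
    "cluster_pseudobulk",
]


def infiltration_matrix(
    cells: pd.DataFrame, level: str = "level2", min_cells_per_sample: int = 50
) -> pd.DataFrame:
    """Samples x cell-types matrix of infiltration rates.

    entry(s, t) = n(s, t) / n(s).  Samples with fewer than
    ``min_cells_per_sample`` cells are dropped with a warning; cell types
    absent from a sample get 0, so each retained row sums to 1.
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    if level not in cells.columns or cells[level].isna().any():
        raise ValueError(f"every cell needs a label at level {level!r}")
    counts = pd.crosstab(cells["sample_id"], cells[level])
    n = counts.sum(axis=1)
    small = n < min_cells_per_sample
    if small.any():
        warnings.warn(
            f"dropping {int(small.sum())} samples with < {min_cells_per_sample} "
            f"cells: {list(counts.index[small])}"
        )
        counts = counts.loc[~small]
        n = n.loc[~small]
    comp = counts.div(n, axis=0)
    comp.index.name = "sample_id"
    comp.columns.name = level
    return comp.astype(float)


def sample_similarity(comp: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation between sample composition rows
    (average ranks for ties).  Constant rows have undefined correlation:
    their entries are NaN and a warning is emitted."""
    if comp.shape[0] < 2 or comp.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 cell types")
    rho = stats.spearmanr(comp.to_numpy(), axis=1).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.asarray(rho, dtype=float)
    constant = comp.nunique(axis=1).to_numpy() == 1
    if constant.any():
        warnings.warn(
            f"constant composition rows have undefined correlation: "
            f"{list(comp.index[constant])}"
        )
        rho[constant, :] = np.nan
        rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=comp.index, columns=comp.index)


@dataclass
class ProgramPartition:
    """Result of cutting the sample dendrogram into k cellular programs."""

    labels: pd.Series  # sample_id -> "CP1".."CPk"
    correlation: pd.DataFrame
    linkage: np.ndarray  # scipy linkage matrix
    k: int

    def to_csv(self, path: str | Path) -> None:
        self.labels.rename("program").rename_axis("sample_id").to_csv(path)

    def dendrogram_json(self, path: str | Path) -> None:
        merges = [
            [int(a), int(b), float(h), int(size)]
            for a, b, h, size in self.linkage
        ]
        Path(path).write_text(json.dumps(merges))


def _order_labels(raw: np.ndarray, samples: pd.Index) -> pd.Series:
    """Relabel raw cluster ids as CP1.. in decreasing size order, breaking
    ties by the lexicographically smallest member sample."""
    clusters = {}
    for cid in np.unique(raw):
        members = samples[raw == cid]
        clusters[cid] = (-len(members), min(members))
    order = sorted(clusters, key=clusters.get)
    mapping = {cid: f"CP{i + 1}" for i, cid in enumerate(order)}
    return pd.Series([mapping[c] for c in raw], index=samples, name="program")


def discover_programs(
    similarity: pd.DataFrame, k: int, linkage: str = "complete"
) -> ProgramPartition:
    """Cut the complete-linkage dendrogram on distance 1 - rho into exactly
    k cellular programs.

    Program ids CP1..CPk are assigned in decreasing cluster-size order
    (ties broken by smallest member id) so the labeling is deterministic.
    """
    n = similarity.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} must satisfy 2 <= k <= n_samples={n}")
    if similarity.isna().any().any():
        bad = sorted(similarity.index[similarity.isna().any(axis=1)])
        raise ValueError(f"missing similarity entries for samples: {bad}")
    rho = similarity.to_numpy(dtype=float)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.maximum((d + d.T) / 2.0, 0.0)  # symmetrize fp noise
    Z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        raise ValueError(
            f"dendrogram cannot be cut into exactly {k} clusters "
            f"(got {len(np.unique(raw))}; tied merge heights)"
        )
    labels = _order_labels(raw, similarity.index)
    return ProgramPartition(labels=labels, correlation=similarity, linkage=Z, k=k)


def program_stability(
    comp: pd.DataFrame, k: int, n_boot: int = 50, seed: int = 0
) -> float:
    """Mean adjusted Rand index between the full-data partition and
    partitions recomputed on bootstrap-resampled sample sets (ARI taken on
    the unique resampled samples).  Replicates where k-clustering is
    infeasible are skipped."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    full = discover_programs(sample_similarity(comp), k).labels
    rng = np.random.default_rng(seed)
    aris, skipped = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, comp.shape[0], size=comp.shape[0])
        shared = comp.index[np.unique(idx)]
        if len(shared) <= k:
            skipped += 1
            continue
        sub = comp.loc[shared]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                part = discover_programs(sample_similarity(sub), k).labels
        except ValueError:
            skipped += 1
            continue
        aris.append(adjusted_rand_score(full.loc[shared], part))
    if skipped:
        warnings.warn(f"{skipped}/{n_boot} bootstrap replicates skipped")
    if not aris:
        raise ValueError("no feasible bootstrap replicates")
    return float(np.mean(aris))


def pseudobulk_profiles(
    adata: ad.AnnData, cells: pd.DataFrame, level: str = "level3"
) -> pd.DataFrame:
    """Groups x genes matrix of mean normalized expression per cell group."""
    if NORMALIZED_LAYER not in adata.layers:
        raise ValueError("normalized layer missing; run normalize_log1p first")
    labels = cells.set_index("cell_id").loc[list(adata.obs_names), level]
    X = sparse.csr_matrix(adata.layers[NORMALIZED_LAYER])
    groups = labels.dropna().unique()
    rows = {}
    for g in groups:
        mask = (labels == g).to_numpy()
        rows[g] = np.asarray(X[mask].mean(axis=0)).ravel()
    profiles = pd.DataFrame.from_dict(rows, orient="index", columns=adata.var_names)
    profiles.index.name = level
    return profiles.sort_index()


def cluster_pseudobulk(profiles: pd.DataFrame) -> np.ndarray:
    """Complete-linkage dendrogram of pseudo-bulk profiles on 1 - Spearman
    rho; returns the scipy linkage matrix."""
    sim = sample_similarity(profiles)
    if sim.isna().any().any():
        bad = sorted(sim.index[sim.isna().any(axis=1)])
        raise ValueError(f"constant profiles have undefined correlation: {bad}")
    d = 1.0 - sim.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.maximum((d + d.T) / 2.0, 0.0)
    return hierarchy.linkage(squareform(d, checks=False), method="complete")
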