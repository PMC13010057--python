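"""Ligand-receptor communication scoring with a permutation null.

The interaction score of a ligand-receptor pair between a sender and a
receiver cluster is the arithmetic mean of (a) the sender-cluster mean
normalized expression of the ligand and (b) the receiver-cluster mean of
the receptor, with multi-subunit complexes represented by their limiting
(minimum-expression) subunit.  A pair is tested only if every subunit
passes an expression-fraction gate in its cluster.  Significance comes
from shuffling cluster labels over cells (sizes preserved) and recomputing
scores, with the add-one estimator p = (1 + #{null >= observed}) / (n_perm
+ 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse

from .io_qc import NORMALIZED_LAYER

__all__ = [
    "LRPair",
    "InteractionResult",
    "read_lr_pairs",
    "interaction_score",
    "permutation_test",
    "recruitment_score",
    "results_to_frame",
]


@dataclass(frozen=True)
class LRPair:
    """A ligand-receptor pair; either side may be a multi-subunit complex."""

    pair_id: str
    ligand: tuple[str, ...]
    receptor: tuple[str, ...]

    def __post_init__(self):
        if not self.ligand or not self.receptor:
            raise ValueError(f"pair {self.pair_id!r} has an empty subunit list")


def read_lr_pairs(path: str | Path) -> list[LRPair]:
    """CSV with columns pair_id, ligand_subunits, receptor_subunits
    (pipe-separated subunit gene lists)."""
    df = pd.read_csv(path)
    for col in ("pair_id", "ligand_subunits", "receptor_subunits"):
        if col not in df.columns:
            raise ValueError(f"LR pair table is missing column {col!r}")
    return [
        LRPair(
            pair_id=str(r.pair_id),
            ligand=tuple(str(r.ligand_subunits).split("|")),
            receptor=tuple(str(r.receptor_subunits).split("|")),
        )
        for r in df.itertuples()
    ]


@dataclass
class InteractionResult:
    sender: str
    receiver: str
    pair_id: str
    score: float | None
    pvalue: float | None
    tested: bool
    significant: bool
    reason: str = ""


def results_to_frame(results: Iterable[InteractionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sender": r.sender,
                "receiver": r.receiver,
                "pair": r.pair_id,
                "score": r.score,
                "p": r.pvalue,
                "tested": r.tested,
                "significant": r.significant,
                "reason": r.reason,
            }
            for r in results
        ]
    )


class _ClusterSummary:
    """Per-cluster mean and expressing-fraction of the genes a pair list
    touches, on the normalized layer."""

    def __init__(self, adata: ad.AnnData, cells: pd.DataFrame, level: str,
                 genes: Sequence[str]):
        if NORMALIZED_LAYER not in adata.layers:
            raise ValueError("normalized layer missing; run normalize_log1p first")
        # canonical cell order (sorted ids) so results do not depend on the
        # storage order of the input matrix, including under a fixed seed
        canonical = sorted(adata.obs_names)
        adata = adata[canonical]
        labels = cells.set_index("cell_id").loc[canonical, level]
        if labels.isna().any():
            raise ValueError(f"every cell needs a label at level {level!r}")
        self.labels = labels.to_numpy()
        self.obs_names = list(canonical)
        self.clusters = sorted(pd.unique(labels.dropna()))
        self.cluster_index = {c: i for i, c in enumerate(self.clusters)}
        self.genes = [g for g in genes if g in adata.var_names]
        self.gene_index = {g: j for j, g in enumerate(self.genes)}
        cols = [adata.var_names.get_loc(g) for g in self.genes]
        X = sparse.csc_matrix(adata.layers[NORMALIZED_LAYER])[:, cols]
        self.X = np.asarray(X.todense())  # cells x relevant genes
        codes = labels.map(self.cluster_index).to_numpy()
        self.codes = codes.astype(int)
        self.sizes = np.bincount(self.codes, minlength=len(self.clusters))
        self.mean = self._group_means(np.arange(len(self.codes)))
        frac = np.zeros_like(self.mean)
        expressed = (self.X > 0).astype(float)
        np.add.at(frac, self.codes, expressed)
        self.frac = frac / self.sizes[:, None]

    def _group_means(self, cell_order: np.ndarray) -> np.ndarray:
        """Cluster x gene means when cluster labels are assigned to
        ``self.X[cell_order]`` blockwise by sorted code."""
        sums = np.zeros((len(self.clusters), self.X.shape[1]))
        np.add.at(sums, self.codes, self.X[cell_order])
        return sums / self.sizes[:, None]


def _pair_gate(
    summary: _ClusterSummary,
    pair: LRPair,
    sender: str,
    receiver: str,
    min_fraction: float,
    gate_mode: str,
) -> tuple[bool, str]:
    missing = [g for g in pair.ligand + pair.receptor
               if g not in summary.gene_index]
    if missing:
        return False, f"genes absent from matrix: {missing}"
    si = summary.cluster_index[sender]
    ri = summary.cluster_index[receiver]
    lig_ok = all(
        summary.frac[si, summary.gene_index[g]] >= min_fraction
        for g in pair.ligand
    )
    rec_ok = all(
        summary.frac[ri, summary.gene_index[g]] >= min_fraction
        for g in pair.receptor
    )
    if gate_mode == "both":
        ok = lig_ok and rec_ok
    elif gate_mode == "either":
        ok = lig_ok or rec_ok
    else:
        raise ValueError("gate_mode must be 'both' or 'either'")
    return ok, "" if ok else (
        f"expression fraction below {min_fraction} "
        f"(ligand gate {'passed' if lig_ok else 'failed'}, "
        f"receptor gate {'passed' if rec_ok else 'failed'})"
    )


def _pair_score(mean: np.ndarray, summary: _ClusterSummary, pair: LRPair,
                si: int, ri: int) -> float:
    lig = min(mean[si, summary.gene_index[g]] for g in pair.ligand)
    rec = min(mean[ri, summary.gene_index[g]] for g in pair.receptor)
    return (lig + rec) / 2.0


def interaction_score(
    adata: ad.AnnData,
    cells: pd.DataFrame,
    pair: LRPair,
    sender: str,
    receiver: str,
    level: str = "level1",
    min_fraction: float = 0.20,
    gate_mode: str = "both",
) -> tuple[float | None, bool]:
    """Observed interaction score and tested flag for one (pair, sender,
    receiver) triple.  Untested pairs carry no score."""
    genes = list(pair.ligand) + list(pair.receptor)
    summary = _ClusterSummary(adata, cells, level, genes)
    for c in (sender, receiver):
        if c not in summary.cluster_index:
            raise ValueError(f"cluster {c!r} not present at level {level!r}")
    ok, _reason = _pair_gate(summary, pair, sender, receiver, min_fraction,
                             gate_mode)
    if not ok:
        return None, False
    score = _pair_score(
        summary.mean, summary, pair,
        summary.cluster_index[sender], summary.cluster_index[receiver],
    )
    return float(score), True


def permutation_test(
    adata: ad.AnnData,
    cells: pd.DataFrame,
    pairs: Sequence[LRPair],
    cluster_pairs: Sequence[tuple[str, str]],
    level: str = "level1",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    min_fraction: float = 0.20,
    gate_mode: str = "both",
    within_sample: bool = False,
) -> list[InteractionResult]:
    """Permutation test of every (pair, sender, receiver) combination.

    The null shuffles cluster labels over cells globally (cluster sizes
    preserved; ``within_sample=True`` restricts shuffling to within each
    sample) and recomputes the mean-based score.  p-values use the add-one
    estimator, so they live in [1/(n_perm+1), 1].  ``significant`` means
    tested and p < alpha.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = sorted({g for p in pairs for g in p.ligand + p.receptor})
    summary = _ClusterSummary(adata, cells, level, genes)
    for s, r in cluster_pairs:
        for c in (s, r):
            if c not in summary.cluster_index:
                raise ValueError(f"cluster {c!r} not present at level {level!r}")

    combos: list[tuple[LRPair, str, str]] = [
        (p, s, r) for p in pairs for (s, r) in cluster_pairs
    ]
    gate: list[tuple[bool, str]] = [
        _pair_gate(summary, p, s, r, min_fraction, gate_mode)
        for p, s, r in combos
    ]
    observed = np.full(len(combos), np.nan)
    for i, (p, s, r) in enumerate(combos):
        if gate[i][0]:
            observed[i] = _pair_score(
                summary.mean, summary, p,
                summary.cluster_index[s], summary.cluster_index[r],
            )

    tested_idx = [i for i, (ok, _) in enumerate(gate) if ok]
    exceed = np.zeros(len(combos), dtype=np.int64)
    rng = np.random.default_rng(seed)
    n_cells = summary.X.shape[0]
    order = np.argsort(summary.codes, kind="stable")
    sorted_codes = summary.codes[order]
    boundaries = np.flatnonzero(np.r_[1, np.diff(sorted_codes)])
    present = sorted_codes[boundaries]
    if within_sample:
        sample_of_cell = (
            cells.set_index("cell_id").loc[summary.obs_names, "sample_id"]
            .to_numpy()
        )
        sample_groups = [
            np.flatnonzero(sample_of_cell == s)
            for s in pd.unique(sample_of_cell)
        ]
    for _ in range(n_perm):
        if within_sample:
            perm = np.empty(n_cells, dtype=int)
            for idx in sample_groups:
                perm[idx] = idx[rng.permutation(len(idx))]
        else:
            perm = rng.permutation(n_cells)
        # assigning shuffled labels == regrouping shuffled rows by sorted code
        sums = np.add.reduceat(summary.X[perm[order]], boundaries, axis=0)
        mean = np.zeros_like(summary.mean)
        mean[present] = sums / summary.sizes[present, None]
        for i in tested_idx:
            p, s, r = combos[i]
            null = _pair_score(
                mean, summary, p,
                summary.cluster_index[s], summary.cluster_index[r],
            )
            if null >= observed[i]:
                exceed[i] += 1

    results = []
    for i, (p, s, r) in enumerate(combos):
        ok, reason = gate[i]
        if ok:
            pval = (1.0 + exceed[i]) / (n_perm + 1.0)
            results.append(
                InteractionResult(
                    sender=s, receiver=r, pair_id=p.pair_id,
                    score=float(observed[i]), pvalue=float(pval),
                    tested=True, significant=bool(pval < alpha),
                )
            )
        else:
            results.append(
                InteractionResult(
                    sender=s, receiver=r, pair_id=p.pair_id,
                    score=None, pvalue=None, tested=False,
                    significant=False, reason=reason,
                )
            )
    return results


def recruitment_score(
    adata: ad.AnnData,
    cells: pd.DataFrame,
    ligand: str,
    receptor_genes: Sequence[str],
    senders: Sequence[str],
    receiver: str,
    level: str = "level1",
) -> pd.Series:
    """Chemokine recruitment potential of each sender cluster toward a
    receiver cluster.

    INTERPRETED DEFINITION: score(sender) = mean normalized ligand
    expression in the sender x max over receptor genes of mean normalized
    receptor expression in the receiver.  This product summary is an
    interpretation of the recruitment readout, not a formally published
    statistic; treat it as a relative ranking of sender clusters.
    """
    genes = [ligand] + list(receptor_genes)
    summary = _ClusterSummary(adata, cells, level, genes)
    if receiver not in summary.cluster_index:
        raise ValueError(f"receiver cluster {receiver!r} not present")
    if ligand not in summary.gene_index:
        warnings.warn(f"ligand {ligand!r} absent from matrix; scores are 0")
        return pd.Series(0.0, index=list(senders), name="recruitment_score")
    ri = summary.cluster_index[receiver]
    rec_means = [
        summary.mean[ri, summary.gene_index[g]]
        for g in receptor_genes if g in summary.gene_index
    ]
    rec = max(rec_means) if rec_means else 0.0
    out = {}
    for s in senders:
        if s not in summary.cluster_index:
            raise ValueError(f"sender cluster {s!r} not present")
        lig = summary.mean[summary.cluster_index[s], summary.gene_index[ligand]]
        out[s] = float(lig * rec)
    return pd.Series(out, name="recruitment_score")
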