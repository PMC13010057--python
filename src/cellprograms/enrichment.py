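"""R_o/e enrichment of cell clusters across programs and per-sample entropy.

R_o/e is the ratio of observed to expected cell counts in a cluster x
program contingency table, with expected counts taken from the chi-square
independence model E(i,j) = row_i * col_j / total.  A cluster is called
enriched in a program when R_o/e strictly exceeds 1.  Sample entropy is the
Shannon entropy of a sample's distribution over (CNV-)cluster labels — a
proxy for intratumoral genomic heterogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composition import ProgramPartition

__all__ = [
    "RoeTable",
    "contingency",
    "roe",
    "enriched_calls",
    "sample_entropy",
    "group_compare",
]


def contingency(
    cells: pd.DataFrame,
    row_level: str = "level3",
    col_by: str = "program",
    partition: ProgramPartition | None = None,
) -> pd.DataFrame:
    """Observed cell counts per (cluster, column class).

    ``col_by`` is "program" (requires a ProgramPartition covering every
    sample), "group" or "organ".  Empty intersections are kept as 0.
    """
    if col_by == "program":
        if partition is None:
            raise ValueError("col_by='program' requires a ProgramPartition")
        missing = sorted(set(cells["sample_id"]) - set(partition.labels.index))
        if missing:
            raise ValueError(f"samples missing from partition: {missing}")
        col = cells["sample_id"].map(partition.labels)
    elif col_by in ("group", "organ"):
        col = cells[col_by]
    else:
        raise ValueError(f"col_by must be program|group|organ, got {col_by!r}")
    table = pd.crosstab(cells[row_level], col)
    table.index.name = row_level
    table.columns.name = col_by
    return table


@dataclass
class RoeTable:
    """Observed/expected ratios plus the chi-square expected counts."""

    roe: pd.DataFrame
    expected: pd.DataFrame
    observed: pd.DataFrame

    def to_long_csv(self, path, threshold: float = 1.0) -> None:
        mask = enriched_calls(self, threshold)
        long = (
            self.roe.stack()
            .rename("roe")
            .to_frame()
            .join(mask.stack().rename("enriched"))
            .reset_index()
        )
        long.to_csv(path, index=False)


def roe(table: pd.DataFrame) -> RoeTable:
    """Ratio of observed to chi-square-expected counts.

    E(i,j) = row_total(i) * col_total(j) / grand_total;
    R_o/e(i,j) = O(i,j) / E(i,j).  Rows/columns with zero totals are
    excluded with a warning (their expectations are identically zero).
    """
    obs = table.astype(float)
    if (obs.to_numpy() < 0).any():
        raise ValueError("contingency table must be non-negative")
    zero_rows = obs.sum(axis=1) == 0
    zero_cols = obs.sum(axis=0) == 0
    if zero_rows.any() or zero_cols.any():
        warnings.warn(
            f"excluding {int(zero_rows.sum())} zero rows and "
            f"{int(zero_cols.sum())} zero columns from R_o/e"
        )
        obs = obs.loc[~zero_rows, ~zero_cols]
    grand = obs.to_numpy().sum()
    if grand <= 0:
        raise ValueError("grand total must be positive")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / grand
    expected = pd.DataFrame(expected, index=obs.index, columns=obs.columns)
    return RoeTable(roe=obs / expected, expected=expected, observed=obs)


def enriched_calls(roe_table: RoeTable, threshold: float = 1.0) -> pd.DataFrame:
    """Boolean mask: cluster enriched in a program iff R_o/e > threshold
    (strict)."""
    return roe_table.roe > threshold


def sample_entropy(
    cells: pd.DataFrame,
    label: str = "cnv_cluster",
    base: float | str = "e",
    normalized: bool = False,
) -> pd.Series:
    """Shannon entropy of each sample's distribution over ``label``.

    H(s) = -sum_c p(c|s) log p(c|s) over labels observed in the sample
    (0 log 0 := 0).  ``base`` is "e" (nats) or 2 (bits).  The normalized
    variant divides by log(#observed labels) and is 0 for single-label
    samples.  Samples with no labeled cells are omitted with a warning.
    """
    if label not in cells.columns:
        raise ValueError(f"no column {label!r} in cell table")
    logf = np.log if base in ("e", np.e) else (np.log2 if base == 2 else None)
    if logf is None:
        raise ValueError("base must be 'e' or 2")
    labeled = cells.dropna(subset=[label])
    omitted = set(cells["sample_id"]) - set(labeled["sample_id"])
    if omitted:
        warnings.warn(f"samples with no labeled cells omitted: {sorted(omitted)}")
    out = {}
    for sid, sub in labeled.groupby("sample_id"):
        p = sub[label].value_counts(normalize=True).to_numpy()
        h = float(-(p * logf(p)).sum())
        if normalized:
            h = 0.0 if len(p) < 2 else h / float(logf(len(p)))
        out[sid] = h
    return pd.Series(out, name="entropy").rename_axis("sample_id").sort_index()


def group_compare(
    values: pd.Series, groups: pd.Series
) -> tuple[float, float]:
    """Kruskal-Wallis H test of a per-sample statistic across groups.

    Returns (H, p).  Degenerate input where every value is identical gives
    H = 0, p = 1.
    """
    aligned = pd.DataFrame({"v": values, "g": groups}).dropna()
    parts = [sub["v"].to_numpy() for _, sub in aligned.groupby("g")]
    if len(parts) < 2 or any(len(p) < 1 for p in parts):
        raise ValueError("need >= 2 non-empty groups")
    if aligned["v"].nunique() == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*parts)
    return float(h), float(p)
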