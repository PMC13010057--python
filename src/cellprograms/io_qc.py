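"""Readers/writers for cohort inputs and the cell-level quality filters.

Cell metadata travels as TSV, expression as MatrixMarket triplets with
genes.tsv/barcodes.tsv sidecars (genes x cells orientation, as emitted by
common droplet pipelines) or as a small dense CSV.  QC removes cells with
fewer than 200 detected genes or more than 20% mitochondrial reads — the
conventional thresholds for droplet scRNA-seq — and a log1p library-size
normalization provides the normalized layer consumed downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse
from scipy.io import mmread, mmwrite

__all__ = [
    "SchemaError",
    "QCReport",
    "REQUIRED_CELL_COLUMNS",
    "read_cells",
    "write_cells",
    "read_expression",
    "read_expression_mtx",
    "write_expression_mtx",
    "qc_filter",
    "normalize_log1p",
]

REQUIRED_CELL_COLUMNS = ("cell_id", "sample_id", "level1")
OPTIONAL_CELL_COLUMNS = ("group", "organ", "level2", "level3", "cnv_cluster")
GROUP_VOCABULARY = ("HM", "PT", "NT/PN")

NORMALIZED_LAYER = "lognorm"


class SchemaError(ValueError):
    """An input table violates the declared schema."""


def _validate_cells(table: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_CELL_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"cell table is missing required column {col!r}")
    if table["cell_id"].duplicated().any():
        dupes = table.loc[table["cell_id"].duplicated(), "cell_id"].head(3).tolist()
        raise SchemaError(f"duplicate cell_id values (e.g. {dupes})")
    if table[list(REQUIRED_CELL_COLUMNS)].isna().any().any():
        raise SchemaError("cell_id, sample_id and level1 must be non-missing")
    if "group" in table.columns:
        bad = set(table["group"].dropna()) - set(GROUP_VOCABULARY)
        if bad:
            raise SchemaError(
                f"group values {sorted(bad)} outside vocabulary {GROUP_VOCABULARY}"
            )
    ordered = [c for c in REQUIRED_CELL_COLUMNS + OPTIONAL_CELL_COLUMNS
               if c in table.columns]
    extra = [c for c in table.columns if c not in ordered]
    return table[ordered + extra].reset_index(drop=True)


def read_cells(path: str | Path) -> pd.DataFrame:
    """Read a cell-annotation TSV and validate its schema."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    return _validate_cells(table)


def write_cells(table: pd.DataFrame, path: str | Path) -> None:
    _validate_cells(table).to_csv(path, sep="\t", index=False)


def write_expression_mtx(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write counts as MatrixMarket (genes x cells) with TSV sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sparse.csr_matrix(adata.X)
    mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())
    pd.Series(adata.var_names).to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )


def read_expression_mtx(path: str | Path) -> ad.AnnData:
    """Read a MatrixMarket triplet directory (matrix.mtx + genes.tsv +
    barcodes.tsv) into a cells x genes AnnData."""
    path = Path(path)
    X = sparse.csr_matrix(mmread(str(path / "matrix.mtx")))  # genes x cells
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if X.shape[0] != len(genes):
        raise SchemaError(
            f"matrix declares {X.shape[0]} genes but genes.tsv has {len(genes)}"
        )
    if X.shape[1] != len(barcodes):
        raise SchemaError(
            f"matrix declares {X.shape[1]} cells but barcodes.tsv has {len(barcodes)}"
        )
    return ad.AnnData(
        X=X.T.tocsr().astype(np.float64),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def read_expression(path: str | Path) -> ad.AnnData:
    """Read expression from an MTX triplet directory or a dense CSV
    (cells as rows, genes as columns, first column = cell id)."""
    path = Path(path)
    if path.is_dir():
        return read_expression_mtx(path)
    df = pd.read_csv(path, index_col=0)
    return ad.AnnData(
        X=df.to_numpy(dtype=np.float64),
        obs=pd.DataFrame(index=pd.Index(df.index.astype(str), name="cell_id")),
        var=pd.DataFrame(index=pd.Index(df.columns.astype(str), name="gene")),
    )


@dataclass
class QCReport:
    n_input: int = 0
    n_removed_min_genes: int = 0
    n_removed_mito: int = 0
    n_removed_total: int = 0
    n_retained: int = 0
    min_genes: int = 200
    max_mito_fraction: float = 0.20
    mito_prefix: str = "MT-"
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def qc_filter(
    adata: ad.AnnData,
    cells: pd.DataFrame,
    min_genes: int = 200,
    max_mito_fraction: float = 0.20,
    mito_prefix: str = "MT-",
) -> tuple[ad.AnnData, pd.DataFrame, QCReport]:
    """Remove low-quality cells.

    A cell is removed when it detects fewer than ``min_genes`` genes
    (count > 0) or when its mitochondrial read fraction strictly exceeds
    ``max_mito_fraction``.  Both criteria are evaluated on the input matrix,
    so the operation is idempotent and order-free.  Mitochondrial genes are
    recognized by name prefix; if none match, that criterion is skipped and
    a warning recorded.
    """
    cells = _validate_cells(cells)
    if not np.array_equal(adata.obs_names.to_numpy(), cells["cell_id"].to_numpy()):
        common = set(adata.obs_names) & set(cells["cell_id"])
        if len(common) != adata.n_obs or len(common) != len(cells):
            raise SchemaError("cell ids differ between expression and annotation")
        cells = cells.set_index("cell_id").loc[list(adata.obs_names)].reset_index()
    X = sparse.csr_matrix(adata.X)
    report = QCReport(
        n_input=adata.n_obs,
        min_genes=min_genes,
        max_mito_fraction=max_mito_fraction,
        mito_prefix=mito_prefix,
    )
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    fail_genes = detected < min_genes

    is_mito = np.asarray(
        [g.startswith(mito_prefix) for g in adata.var_names], dtype=bool
    )
    if not is_mito.any():
        report.warnings.append(
            f"no genes match mito prefix {mito_prefix!r}; mito criterion skipped"
        )
        fail_mito = np.zeros(adata.n_obs, dtype=bool)
    else:
        total = np.asarray(X.sum(axis=1)).ravel()
        mito = np.asarray(X[:, is_mito].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        fail_mito = frac > max_mito_fraction

    keep = ~(fail_genes | fail_mito)
    report.n_removed_min_genes = int(fail_genes.sum())
    report.n_removed_mito = int(fail_mito.sum())
    report.n_removed_total = int((~keep).sum())
    report.n_retained = int(keep.sum())
    return adata[keep].copy(), cells.loc[keep].reset_index(drop=True), report


def normalize_log1p(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Add a log1p library-size-normalized layer.

    normalized(c, g) = log(1 + scale * count(c, g) / library_size(c)).
    All-zero cells keep an all-zero row (a warning is emitted).  Returns the
    same AnnData with layer ``"lognorm"`` set.
    """
    X = sparse.csr_matrix(adata.X, copy=True).astype(np.float64)
    lib = np.asarray(X.sum(axis=1)).ravel()
    zero = lib == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cells left unnormalized")
    inv = np.where(zero, 0.0, scale / np.maximum(lib, 1e-300))
    Xn = sparse.diags(inv) @ X
    Xn.data = np.log1p(Xn.data)
    adata.layers[NORMALIZED_LAYER] = Xn.tocsr()
    return adata
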