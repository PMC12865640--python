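"""Readers/writers for the package's on-disk formats.

Cell metadata and LR pairs travel as CSV/TSV; expression as MatrixMarket MTX
with ``genes.tsv`` / ``barcodes.tsv`` sidecars (CellRanger-style genes x
cells orientation on disk, transposed to cells x genes in memory) or as a
dense CSV; ground truth and manifests as JSON.

Alignment of expression rows to the cell table is always by ``cell_id``,
never by file order.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    AlignmentError,
    CellTable,
    ExpressionMatrix,
    GroundTruth,
    LRPairTable,
    ValidationError,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_cells", "write_cells",
    "read_expression", "write_expression",
    "read_lr_pairs", "write_lr_pairs", "filter_lr_pairs",
    "read_ground_truth", "write_ground_truth",
]


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt in ("tsv",):
        return "\t"
    if fmt in ("csv",):
        return ","
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_cells(
    path: str | Path, fmt: str | None = None, drop_tumor: bool = False
) -> CellTable:
    """Read and validate a per-cell metadata table (CSV or TSV).

    With ``drop_tumor=True``, rows with ``region == "tumor"`` are removed,
    restricting the analysis to non-tumor tissue.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, fmt), dtype={"cell_id": str})
    table = CellTable(df)
    if drop_tumor:
        before = table.n_cells
        table = table.drop_tumor()
        log.info("dropped %d tumor cells of %d", before - table.n_cells, before)
    return table


def write_cells(cells: CellTable, path: str | Path) -> None:
    path = Path(path)
    cells.df.to_csv(path, sep=_sep_for(path, None), index=False)


def read_expression(
    path: str | Path,
    cells: CellTable | None = None,
    fmt: str | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from MTX (+ sidecars) or dense CSV.

    ``path`` is either the ``.mtx`` file (with ``genes.tsv`` and
    ``barcodes.tsv`` next to it) or a CSV with cell_id index and gene columns.
    If ``cells`` is given, the matrix is aligned to its row order by cell_id.
    """
    path = Path(path)
    if fmt == "mtx" or (fmt is None and path.suffix.lower() == ".mtx"):
        mat = scipy.io.mmread(path)  # genes x cells on disk
        genes = pd.read_csv(path.parent / "genes.tsv", sep="\t", header=None)[0]
        barcodes = pd.read_csv(path.parent / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
        values = sp.csr_matrix(mat).T  # -> cells x genes
        if values.shape != (len(barcodes), len(genes)):
            raise ValidationError(
                f"MTX shape {mat.shape} (genes x cells) inconsistent with "
                f"{len(genes)} genes / {len(barcodes)} barcodes"
            )
        expr = ExpressionMatrix(values, pd.Index(genes), pd.Index(barcodes))
    else:
        df = pd.read_csv(path, sep=_sep_for(path, fmt), index_col=0)
        expr = ExpressionMatrix(
            df.to_numpy(float), pd.Index(df.columns), pd.Index(df.index.astype(str))
        )
    if cells is not None:
        expr = expr.align_to(cells)
    return expr


def write_expression(expr: ExpressionMatrix, path: str | Path, fmt: str = "mtx") -> None:
    """Write MTX (genes x cells, with genes.tsv / barcodes.tsv sidecars) or
    dense CSV (cells x genes with cell_id index)."""
    path = Path(path)
    if fmt == "mtx":
        mat = sp.coo_matrix(
            expr.values.T if sp.issparse(expr.values) else sp.csr_matrix(expr.values).T
        )
        scipy.io.mmwrite(path, mat)
        pd.Series(expr.gene_names).to_csv(
            path.parent / "genes.tsv", sep="\t", index=False, header=False
        )
        pd.Series(expr.cell_ids).to_csv(
            path.parent / "barcodes.tsv", sep="\t", index=False, header=False
        )
    elif fmt == "csv":
        pd.DataFrame(expr.dense(), index=expr.cell_ids, columns=expr.gene_names).to_csv(path)
    else:
        raise ValueError(f"unknown expression format {fmt!r}")


def read_lr_pairs(path: str | Path, fmt: str | None = None) -> LRPairTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, fmt))
    if "pair_id" not in df.columns:
        df["pair_id"] = df["ligand_gene"] + "_" + df["receptor_gene"]
    return LRPairTable(df)


def write_lr_pairs(pairs: LRPairTable, path: str | Path) -> None:
    path = Path(path)
    pairs.df.to_csv(path, sep=_sep_for(path, None), index=False)


def filter_lr_pairs(db: LRPairTable, panel_genes: set[str]) -> LRPairTable:
    """Keep the pairs whose ligand AND receptor are both on the panel,
    preserving input order (the panel-restriction step applied to a
    CellChat-style one-to-one pair database)."""
    panel = set(panel_genes)
    keep = db.df["ligand_gene"].isin(panel) & db.df["receptor_gene"].isin(panel)
    out = LRPairTable(db.df.loc[keep].reset_index(drop=True).copy())
    if len(out) == 0:
        log.warning("no LR pairs survive panel filtering (panel size %d)", len(panel))
    return out


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_json_dict(json.load(fh))


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
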