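"""Shared data model for spatial single-cell crosstalk analysis.

All downstream modules consume the validated containers defined here:

* :class:`CellTable` — per-cell spatial metadata (global micrometer
  coordinates, field-of-view id, cell-type label, optional niche / region).
* :class:`ExpressionMatrix` — cells x genes non-negative values, row-aligned
  to a :class:`CellTable` by ``cell_id``.
* :class:`LRPairTable` — one-to-one ligand->receptor gene pairs.
* :class:`GroundTruth` — planted structure of a synthetic dataset (true zone
  labels, planted-pair flags, distance to the landmark anchor).

Coordinates are always micrometers in a single global frame; cells from
different fields of view (FOVs) are never spatially comparable, which every
distance computation in the package enforces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class SpaxtalkError(Exception):
    """Base class for all package errors."""


class ValidationError(SpaxtalkError):
    """Raised when an input table or matrix violates the data model."""


class AlignmentError(SpaxtalkError):
    """Raised when expression rows cannot be aligned to the cell table."""


class UnknownTypeError(SpaxtalkError):
    """Raised when a cell-type name is absent from the cell table."""


class UnknownGeneError(SpaxtalkError):
    """Raised when a gene name is absent from the expression matrix."""


CELL_COLUMNS = ("cell_id", "x_um", "y_um", "fov_id", "cell_type")
OPTIONAL_CELL_COLUMNS = ("niche_id", "region")
REGION_VALUES = frozenset({"tumor", "non_tumor"})


@dataclass
class CellTable:
    """Validated per-cell spatial metadata.

    Wraps a :class:`pandas.DataFrame` with columns ``cell_id``, ``x_um``,
    ``y_um``, ``fov_id``, ``cell_type`` and optionally ``niche_id`` and
    ``region`` (``tumor`` / ``non_tumor``).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in CELL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cell table missing required columns: {missing}")
        dup = df["cell_id"][df["cell_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate cell_id values: {sorted(set(dup.astype(str)))[:10]}"
            )
        for col in ("x_um", "y_um"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.loc[~np.isfinite(vals), "cell_id"]
            if len(bad):
                raise ValidationError(
                    f"non-finite or non-numeric {col} for cells: "
                    f"{list(bad.astype(str))[:10]}"
                )
            df[col] = vals.astype(float)
        if df["cell_type"].isna().any():
            bad = df.loc[df["cell_type"].isna(), "cell_id"]
            raise ValidationError(
                f"missing cell_type for cells: {list(bad.astype(str))[:10]}"
            )
        if "region" in df.columns:
            present = set(df["region"].dropna().unique())
            unknown = present - REGION_VALUES
            if unknown:
                raise ValidationError(f"unknown region values: {sorted(unknown)}")
        df["cell_id"] = df["cell_id"].astype(str)
        df["fov_id"] = df["fov_id"].astype(str)
        df["cell_type"] = df["cell_type"].astype(str)
        self.df = df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.df)

    @property
    def cell_ids(self) -> pd.Index:
        return pd.Index(self.df["cell_id"])

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.df["cell_type"].unique())

    @property
    def fov_ids(self) -> list[str]:
        return sorted(self.df["fov_id"].unique())

    def coords(self) -> np.ndarray:
        """(n_cells, 2) array of global x/y coordinates in micrometers."""
        return self.df[["x_um", "y_um"]].to_numpy(float)

    def type_mask(self, cell_type: str) -> np.ndarray:
        if cell_type not in set(self.df["cell_type"]):
            raise UnknownTypeError(
                f"cell type {cell_type!r} not present; available: {self.cell_types}"
            )
        return (self.df["cell_type"] == cell_type).to_numpy()

    def drop_tumor(self) -> "CellTable":
        """Restrict to non-tumor cells (no-op if no region column)."""
        if "region" not in self.df.columns:
            return self
        keep = self.df["region"] != "tumor"
        return CellTable(self.df.loc[keep].reset_index(drop=True).copy())

    def subset(self, mask: np.ndarray) -> "CellTable":
        return CellTable(self.df.loc[np.asarray(mask, bool)].reset_index(drop=True).copy())


@dataclass
class ExpressionMatrix:
    """Cells x genes non-negative expression values.

    ``values`` may be dense or CSR sparse; rows are aligned to a
    :class:`CellTable` by ``cell_id`` (never by file order).
    """

    values: np.ndarray | sp.spmatrix
    gene_names: pd.Index
    cell_ids: pd.Index

    def __post_init__(self) -> None:
        self.gene_names = pd.Index([str(g) for g in self.gene_names])
        self.cell_ids = pd.Index([str(c) for c in self.cell_ids])
        if self.gene_names.has_duplicates:
            dup = self.gene_names[self.gene_names.duplicated()]
            raise ValidationError(f"duplicate gene names: {sorted(set(dup))[:10]}")
        if self.cell_ids.has_duplicates:
            dup = self.cell_ids[self.cell_ids.duplicated()]
            raise ValidationError(f"duplicate cell ids: {sorted(set(dup))[:10]}")
        if sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
            if (self.values.data < 0).any():
                raise ValidationError("expression matrix contains negative entries")
        else:
            self.values = np.asarray(self.values, float)
            if (self.values < 0).any():
                raise ValidationError("expression matrix contains negative entries")
        if self.values.shape != (len(self.cell_ids), len(self.gene_names)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_names)} genes"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), float)
        return self.values

    def gene_index(self, gene: str) -> int:
        try:
            return int(self.gene_names.get_loc(gene))
        except KeyError:
            raise UnknownGeneError(
                f"gene {gene!r} not present in the expression matrix"
            ) from None

    def gene_column(self, gene: str) -> np.ndarray:
        """Dense 1-D expression vector of one gene across all cells."""
        j = self.gene_index(gene)
        if sp.issparse(self.values):
            return np.asarray(self.values[:, j].todense(), float).ravel()
        return self.values[:, j]

    def align_to(self, cells: CellTable) -> "ExpressionMatrix":
        """Reorder rows to match the cell table's cell order (by cell_id)."""
        missing = cells.cell_ids.difference(self.cell_ids)
        extra = self.cell_ids.difference(cells.cell_ids)
        if len(missing) or len(extra):
            raise AlignmentError(
                f"cell_id mismatch between matrix and cell table; "
                f"missing from matrix: {list(missing[:10])}, "
                f"absent from cell table: {list(extra[:10])}"
            )
        order = self.cell_ids.get_indexer(cells.cell_ids)
        return ExpressionMatrix(self.values[order], self.gene_names, cells.cell_ids)

    def row_totals(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.sum(axis=1), float).ravel()
        return self.values.sum(axis=1)


@dataclass
class LRPairTable:
    """One-to-one ligand->receptor gene pairs (no multi-subunit complexes)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ("ligand_gene", "receptor_gene", "pair_id")
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"LR pair table missing columns: {missing}")
        if self.df["pair_id"].duplicated().any():
            dup = self.df["pair_id"][self.df["pair_id"].duplicated()]
            raise ValidationError(f"duplicate pair_ids: {sorted(set(dup))[:10]}")
        for col in required:
            self.df[col] = self.df[col].astype(str)
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "LRPairTable":
        rows = [
            {"ligand_gene": l, "receptor_gene": r, "pair_id": f"{l}_{r}"}
            for l, r in pairs
        ]
        return cls(pd.DataFrame(rows, columns=["ligand_gene", "receptor_gene", "pair_id"]))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def pair_ids(self) -> list[str]:
        return list(self.df["pair_id"])

    def genes(self) -> set[str]:
        return set(self.df["ligand_gene"]) | set(self.df["receptor_gene"])


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset.

    ``zone_of`` maps cell_id -> true zone label (zones partition all cells);
    ``planted_pairs`` flags each pair_id as planted or decoy;
    ``landmark_distance`` maps cell_id -> distance to its FOV's landmark
    anchor point (micrometers).
    """

    zone_of: dict[str, str]
    planted_pairs: dict[str, bool]
    landmark_distance: dict[str, float]
    planted: list[dict] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "zone_of": self.zone_of,
            "planted_pairs": self.planted_pairs,
            "landmark_distance": self.landmark_distance,
            "planted": self.planted,
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "GroundTruth":
        return cls(
            zone_of=dict(d["zone_of"]),
            planted_pairs={k: bool(v) for k, v in d["planted_pairs"].items()},
            landmark_distance={k: float(v) for k, v in d["landmark_distance"].items()},
            planted=list(d.get("planted", [])),
        )
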