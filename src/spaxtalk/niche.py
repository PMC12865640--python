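"""Neighborhood (niche) analysis.

Each cell is described by the cell-type composition of its k nearest
same-FOV neighbors; composition vectors are clustered with seeded k-means
into niches, which are then profiled: cell-type proportions, mean
nearest-landmark distance, and mean normalized expression of a gene panel
(by default the inflammation/fibrosis transcripts CCL2, CXCL10, ITGAM,
CCR2, COL1A1, IL1B, IL1R1).

This is an open re-implementation of the neighborhood-annotation step that
commercial spatial platforms perform with undisclosed algorithms; k-NN
composition plus centroid clustering is the standard community approach.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .datatypes import CellTable, ExpressionMatrix, SpaxtalkError, UnknownGeneError
from .proximity import nearest_landmark_distance

log = logging.getLogger(__name__)

__all__ = [
    "NicheModel",
    "neighborhood_composition",
    "assign_niches",
    "niche_summaries",
    "DEFAULT_GENE_PANEL",
]

DEFAULT_K_NEIGHBORS = 30
DEFAULT_N_NICHES = 6
DEFAULT_GENE_PANEL = ("CCL2", "CXCL10", "ITGAM", "CCR2", "COL1A1", "IL1B", "IL1R1")


@dataclass
class NicheModel:
    """A fitted niche partition.

    ``composition`` is the cells x cell-types neighbor-frequency matrix
    (rows sum to 1); ``niche_of`` maps each cell_id to a niche label.
    Labels are ordered by descending cluster size ("niche_1" largest);
    empty clusters are dropped.
    """

    k_neighbors: int
    n_niches: int
    composition: pd.DataFrame
    niche_of: pd.Series
    seed: int

    @property
    def niche_labels(self) -> list[str]:
        return sorted(self.niche_of.unique(), key=lambda s: int(s.rsplit("_", 1)[1]))


def neighborhood_composition(
    cells: CellTable, k_neighbors: int = DEFAULT_K_NEIGHBORS
) -> pd.DataFrame:
    """Cell-type frequency vector of each cell's k nearest same-FOV
    neighbors (self excluded); rows sum to 1.

    In FOVs with fewer than k+1 cells, k is truncated to the available
    neighbor count (logged).
    """
    if k_neighbors < 1:
        raise SpaxtalkError("k_neighbors must be positive")
    types = cells.cell_types
    tpos = {t: i for i, t in enumerate(types)}
    comp = np.zeros((cells.n_cells, len(types)))
    df = cells.df
    for fov, sub in df.groupby("fov_id"):
        xy = sub[["x_um", "y_um"]].to_numpy(float)
        labels = sub["cell_type"].to_numpy()
        rows = sub.index.to_numpy()
        k = min(k_neighbors, len(sub) - 1)
        if k < 1:
            raise SpaxtalkError(f"FOV {fov} has a single cell; no neighborhood exists")
        if k < k_neighbors:
            log.warning("FOV %s has %d cells; k truncated to %d", fov, len(sub), k)
        tree = cKDTree(xy)
        _, nn = tree.query(xy, k=k + 1)  # first neighbor is the cell itself
        nn = np.atleast_2d(nn)[:, 1:]
        for r, neigh in zip(rows, nn):
            for t in labels[neigh]:
                comp[r, tpos[t]] += 1.0
        comp[rows] /= k
    return pd.DataFrame(comp, index=cells.cell_ids, columns=types)


def assign_niches(
    composition: pd.DataFrame, n_niches: int = DEFAULT_N_NICHES, seed: int = 0,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
) -> NicheModel:
    """Partition composition vectors into at most ``n_niches`` clusters with
    seeded k-means; niches renamed "niche_1", "niche_2", ... by descending
    size.  Deterministic given the seed."""
    if n_niches < 2:
        raise SpaxtalkError("n_niches must be at least 2")
    if n_niches > len(composition):
        raise SpaxtalkError(
            f"n_niches={n_niches} exceeds the number of cells ({len(composition)})"
        )
    X = composition.to_numpy(float)
    # fit on a canonical row ordering so the partition is invariant to
    # cell-row permutation (k-means++ init depends on row order)
    canon = np.lexsort(X.T[::-1])
    km = KMeans(n_clusters=n_niches, random_state=seed, n_init=10)
    km.fit(X[canon])
    raw = km.predict(X)
    # order surviving clusters by size (ties broken by raw label)
    counts = pd.Series(raw).value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], c))
    rename = {c: f"niche_{i + 1}" for i, c in enumerate(order)}
    labels = pd.Series(
        [rename[c] for c in raw], index=composition.index, name="niche_id"
    )
    if len(counts) < n_niches:
        log.info("%d of %d niches are empty and were dropped",
                 n_niches - len(counts), n_niches)
    return NicheModel(
        k_neighbors=k_neighbors,
        n_niches=n_niches,
        composition=composition,
        niche_of=labels,
        seed=seed,
    )


def niche_summaries(
    model: NicheModel,
    cells: CellTable,
    expr: ExpressionMatrix | None = None,
    landmark_type: str | None = None,
    gene_panel: tuple[str, ...] = DEFAULT_GENE_PANEL,
) -> dict[str, pd.DataFrame]:
    """Per-niche profiles.

    Returns a dict with:

    * ``"proportions"`` — niches x cell-types member-type proportions
      (rows sum to 1);
    * ``"landmark_distance"`` — mean/median/n of the nearest-landmark
      distance over member cells (requires ``landmark_type``; landmark-type
      cells themselves are excluded from the distances);
    * ``"expression"`` — niches x panel-genes mean expression (requires
      ``expr``, which should be normalized).
    """
    df = cells.df.copy()
    niche = model.niche_of.reindex(df["cell_id"]).to_numpy()
    if pd.isna(niche).any():
        raise SpaxtalkError("niche model does not cover all cells in the table")
    df["niche_id"] = niche
    out: dict[str, pd.DataFrame] = {}

    prop = (
        df.groupby("niche_id")["cell_type"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=cells.cell_types, fill_value=0.0)
    )
    out["proportions"] = prop

    if landmark_type is not None:
        dist_rows = []
        for q in cells.cell_types:
            if q == landmark_type:
                continue
            summ = nearest_landmark_distance(cells, q, landmark_type)
            dist_rows.append(summ.values)
        per_cell = pd.concat(dist_rows).groupby(level=0).first()
        per_cell = per_cell.reindex(df["cell_id"])
        grp = pd.DataFrame(
            {"niche_id": df["niche_id"].to_numpy(), "d": per_cell.to_numpy()}
        ).dropna().groupby("niche_id")["d"]
        out["landmark_distance"] = pd.DataFrame(
            {"mean_um": grp.mean(), "median_um": grp.median(), "n": grp.size()}
        )

    if expr is not None:
        missing = [g for g in gene_panel if g not in expr.gene_names]
        if missing:
            raise UnknownGeneError(f"panel genes absent from matrix: {missing}")
        cols = {g: expr.gene_column(g) for g in gene_panel}
        gdf = pd.DataFrame(cols, index=expr.cell_ids).reindex(df["cell_id"])
        gdf["niche_id"] = df["niche_id"].to_numpy()
        out["expression"] = gdf.groupby("niche_id").mean()
    return out
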