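"""Distance-derived spatial statistics.

Three statistics, all FOV-restricted (cells in different imaging tiles are
never compared):

* nearest-landmark distance — for each query-type cell, the Euclidean
  distance to the nearest landmark-type cell in the same FOV (e.g. each
  endothelial cell's shortest distance to a cholangiocyte, the portal-tract
  proxy);
* radius-neighbor counts — for each center-type cell, the number of
  neighbor-type cells within a radius (default 20 um);
* the directional spatial proximity score — a source-type x target-type
  matrix quantifying physical adjacency, built from a Gaussian kernel
  ``w_ij = exp(-d_ij^2 / (2 b^2))`` over same-FOV cell pairs.  With
  ``normalize=True`` the weights of each source cell are scaled to sum to 1
  over all other cells, so each row of the matrix is the mean neighborhood
  composition (kernel-weighted) seen from that source type and sums to 1.
  The score is directional: averaging is over source cells, so
  score(S->T) != score(T->S) in general.

The kernel is evaluated over all same-FOV pairs without truncation, so
results agree with the O(n^2) brute-force definition to machine precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .datatypes import CellTable, SpaxtalkError, UnknownTypeError

log = logging.getLogger(__name__)

__all__ = [
    "DistanceSummary",
    "ProximityMatrix",
    "nearest_landmark_distance",
    "neighbors_within_radius",
    "directional_proximity",
    "kernel_weights",
]

DEFAULT_BANDWIDTH_UM = 20.0
DEFAULT_RADIUS_UM = 20.0


@dataclass
class DistanceSummary:
    """Per-cell distance or count values with a grouping label and summaries.

    ``values`` is indexed by cell_id; NaN marks cells excluded because their
    FOV lacks the partner type (these do not enter the summaries).
    """

    values: pd.Series
    label: str

    @property
    def valid(self) -> pd.Series:
        return self.values.dropna()

    @property
    def n(self) -> int:
        return int(self.valid.shape[0])

    @property
    def mean(self) -> float:
        return float(self.valid.mean())

    @property
    def median(self) -> float:
        return float(self.valid.median())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.values.index, "value": self.values.to_numpy(), "label": self.label}
        )


@dataclass
class ProximityMatrix:
    """Directional source-type x target-type spatial adjacency scores."""

    score: pd.DataFrame  # index = source type, columns = target type
    bandwidth_um: float
    per_cell_normalized: bool

    def __post_init__(self) -> None:
        vals = self.score.to_numpy(float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise SpaxtalkError("proximity scores must be non-negative")


def _check_types(cells: CellTable, *names: str) -> None:
    present = set(cells.df["cell_type"])
    for name in names:
        if name not in present:
            raise UnknownTypeError(
                f"cell type {name!r} not present; available: {sorted(present)}"
            )


def nearest_landmark_distance(
    cells: CellTable, query_type: str, landmark_type: str
) -> DistanceSummary:
    """Per query-type cell, Euclidean distance to the nearest landmark-type
    cell in the same FOV.

    Query cells in FOVs without any landmark cell get NaN and are excluded
    from the summary statistics (logged).
    """
    _check_types(cells, query_type, landmark_type)
    if query_type == landmark_type:
        raise SpaxtalkError(
            "query_type and landmark_type must differ (self-distance is 0 everywhere)"
        )
    df = cells.df
    out = pd.Series(np.nan, index=cells.cell_ids, name="distance_um")
    n_skipped = 0
    for _, sub in df.groupby("fov_id"):
        q = sub[sub["cell_type"] == query_type]
        lm = sub[sub["cell_type"] == landmark_type]
        if len(q) == 0:
            continue
        if len(lm) == 0:
            n_skipped += len(q)
            continue
        tree = cKDTree(lm[["x_um", "y_um"]].to_numpy(float))
        d, _ = tree.query(q[["x_um", "y_um"]].to_numpy(float), k=1)
        out.loc[q["cell_id"].to_numpy()] = d
    if n_skipped:
        log.info(
            "%d %s cells lie in FOVs without %s cells; excluded from summaries",
            n_skipped, query_type, landmark_type,
        )
    return DistanceSummary(out, label=f"{query_type}->nearest {landmark_type}")


def neighbors_within_radius(
    cells: CellTable,
    center_type: str,
    neighbor_type: str,
    radius_um: float = DEFAULT_RADIUS_UM,
) -> DistanceSummary:
    """Per center-type cell, the count of neighbor-type cells within
    ``radius_um`` in the same FOV (the center cell itself is excluded)."""
    if radius_um <= 0:
        raise SpaxtalkError("radius_um must be positive")
    _check_types(cells, center_type, neighbor_type)
    df = cells.df
    out = pd.Series(np.nan, index=cells.cell_ids, name="n_neighbors")
    for _, sub in df.groupby("fov_id"):
        centers = sub[sub["cell_type"] == center_type]
        neigh = sub[sub["cell_type"] == neighbor_type]
        if len(centers) == 0:
            continue
        if len(neigh) == 0:
            out.loc[centers["cell_id"].to_numpy()] = 0.0
            continue
        tree = cKDTree(neigh[["x_um", "y_um"]].to_numpy(float))
        counts = tree.query_ball_point(
            centers[["x_um", "y_um"]].to_numpy(float), r=radius_um,
            return_length=True,
        ).astype(float)
        if center_type == neighbor_type:
            counts -= 1.0  # each center finds itself at distance 0
        out.loc[centers["cell_id"].to_numpy()] = counts
    return DistanceSummary(
        out, label=f"{neighbor_type} within {radius_um} um of {center_type}"
    )


def kernel_weights(
    xy_source: np.ndarray, xy_target: np.ndarray, bandwidth_um: float
) -> np.ndarray:
    """Gaussian adjacency kernel exp(-d^2 / (2 b^2)) between two point sets."""
    d2 = cdist(xy_source, xy_target, "sqeuclidean")
    return np.exp(-d2 / (2.0 * bandwidth_um**2))


def directional_proximity(
    cells: CellTable,
    bandwidth_um: float = DEFAULT_BANDWIDTH_UM,
    normalize: bool = True,
) -> ProximityMatrix:
    """Directional spatial proximity score between all cell-type pairs.

    For each source cell i, Gaussian kernel weights to every other same-FOV
    cell j (self excluded, cross-FOV weight 0); with ``normalize`` each
    cell's weights are divided by their sum, making the weight vector the
    cell's kernel-smoothed neighborhood composition.  score(S->T) is the
    mean over S cells of the summed weight to T cells.

    Source cells with no same-FOV neighbor (or all weights underflowing to
    zero) are excluded from their type's average; a source type with only
    such cells gets a NaN row (logged).
    """
    if bandwidth_um <= 0:
        raise SpaxtalkError("bandwidth_um must be positive")
    if cells.n_cells < 2:
        raise SpaxtalkError("need at least 2 cells")
    types = cells.cell_types
    df = cells.df
    sums = pd.DataFrame(0.0, index=types, columns=types)  # sum over source cells
    n_used = pd.Series(0, index=types, dtype=int)
    for _, sub in df.groupby("fov_id"):
        xy = sub[["x_um", "y_um"]].to_numpy(float)
        W = kernel_weights(xy, xy, bandwidth_um)
        np.fill_diagonal(W, 0.0)
        totals = W.sum(axis=1)
        ok = totals > 0.0
        if normalize:
            Wn = np.zeros_like(W)
            Wn[ok] = W[ok] / totals[ok, None]
            W = Wn
        tlabels = sub["cell_type"].to_numpy()
        # per-target-type summed weight for each source cell, then pooled by
        # source type
        for t in np.unique(tlabels):
            col = W[:, tlabels == t].sum(axis=1)
            for s in np.unique(tlabels):
                rows = (tlabels == s) & ok
                sums.loc[s, t] += float(col[rows].sum())
        for s in np.unique(tlabels):
            n_used[s] += int(((tlabels == s) & ok).sum())

    score = pd.DataFrame(np.nan, index=types, columns=types)
    for s in types:
        if n_used[s] == 0:
            log.warning("source type %s has no cells with neighbors; NaN row", s)
            continue
        score.loc[s] = sums.loc[s] / n_used[s]
    return ProximityMatrix(score, bandwidth_um=bandwidth_um, per_cell_normalized=normalize)
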