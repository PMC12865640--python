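"""Spatially weighted ligand-receptor interaction scoring.

For an ordered cell-type direction S -> T and a one-to-one LR pair (L, R),
the spatial LR score is the kernel-weighted mean of ligand x receptor
expression products over same-FOV source/target cell pairs::

    score = sum_{i in S} sum_{j in T, same FOV} x_iL * x_jR * w_ij
            ---------------------------------------------------------
            sum_{i in S} sum_{j in T, same FOV} w_ij

with ``w_ij = exp(-d_ij^2 / (2 b^2))`` the Gaussian adjacency kernel.  The
denominator makes scores comparable across directions with different cell
abundances.  Self-self cell-type directions (S == T) are excluded
throughout: the analysis targets intercellular, not autocrine, signaling.

Significance is assessed by a permutation null that shuffles cell-type
labels within each FOV, keeping coordinates and expression fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import (
    CellTable,
    ExpressionMatrix,
    LRPairTable,
    SpaxtalkError,
    UnknownTypeError,
)
from .proximity import DEFAULT_BANDWIDTH_UM, kernel_weights

log = logging.getLogger(__name__)

__all__ = [
    "LRScoreResult",
    "normalize_expression",
    "spatial_lr_score",
    "score_all",
    "rank_pairs",
    "permutation_null",
]


class SelfSelfError(SpaxtalkError):
    """Self-self cell-type directions are excluded from LR scoring."""


def normalize_expression(
    expr: ExpressionMatrix, scale: float = 1e4
) -> ExpressionMatrix:
    """Library-size normalization: each cell's values divided by its total
    and multiplied by ``scale`` (counts-per-10k by default).

    Cells with zero totals are left as all-zero rows and logged; they
    contribute nothing to any downstream score.
    """
    if scale <= 0:
        raise SpaxtalkError("scale must be positive")
    totals = expr.row_totals()
    zero = totals == 0
    if zero.any():
        log.warning("%d cells have zero total counts; left as zero rows", int(zero.sum()))
    factors = np.where(zero, 0.0, scale / np.where(zero, 1.0, totals))
    if sp.issparse(expr.values):
        values = sp.diags(factors) @ expr.values
    else:
        values = expr.values * factors[:, None]
    return ExpressionMatrix(values, expr.gene_names, expr.cell_ids)


@dataclass
class LRScoreResult:
    """Scores for every ordered (source, target) type direction and LR pair.

    ``table`` columns: source_type, target_type, pair_id, ligand, receptor,
    score, n_source, n_target, and optionally perm_z / perm_p.
    """

    table: pd.DataFrame
    bandwidth_um: float

    def __post_init__(self) -> None:
        if (self.table["source_type"] == self.table["target_type"]).any():
            raise SelfSelfError("LRScoreResult must not contain self-self directions")
        finite = self.table["score"].dropna()
        if (finite < 0).any():
            raise SpaxtalkError("LR scores must be non-negative")

    def direction(self, source_type: str, target_type: str) -> pd.DataFrame:
        sub = self.table[
            (self.table["source_type"] == source_type)
            & (self.table["target_type"] == target_type)
        ]
        if len(sub) == 0:
            raise UnknownTypeError(
                f"direction {source_type} -> {target_type} not present in result"
            )
        return sub

    def heatmap(self, pair_id: str) -> pd.DataFrame:
        """Source x target score matrix for one LR pair (NaN on the diagonal
        and for directions without a score)."""
        sub = self.table[self.table["pair_id"] == pair_id]
        if len(sub) == 0:
            raise SpaxtalkError(f"pair_id {pair_id!r} not present in result")
        return sub.pivot(index="source_type", columns="target_type", values="score")


def _direction_arrays(
    expr: ExpressionMatrix, cells: CellTable, source_type: str, target_type: str
):
    """Per-FOV (source xy, target xy, source expr rows, target expr rows)."""
    df = cells.df
    X = expr.values
    for _, sub in df.groupby("fov_id"):
        src = sub.index[(sub["cell_type"] == source_type).to_numpy()].to_numpy()
        tgt = sub.index[(sub["cell_type"] == target_type).to_numpy()].to_numpy()
        if len(src) == 0 or len(tgt) == 0:
            continue
        yield (
            df.loc[src, ["x_um", "y_um"]].to_numpy(float),
            df.loc[tgt, ["x_um", "y_um"]].to_numpy(float),
            X[src],
            X[tgt],
        )


def spatial_lr_score(
    expr: ExpressionMatrix,
    cells: CellTable,
    pair: tuple[str, str],
    source_type: str,
    target_type: str,
    bandwidth_um: float = DEFAULT_BANDWIDTH_UM,
) -> float:
    """Spatial LR score for one pair and one S -> T direction.

    ``expr`` should already be library-normalized (see
    :func:`normalize_expression`); the function scores whatever values it is
    given.  Returns NaN (logged) when no same-FOV source/target pair exists.
    """
    if source_type == target_type:
        raise SelfSelfError(
            f"self-self direction {source_type} -> {target_type} is excluded"
        )
    for t in (source_type, target_type):
        if t not in set(cells.df["cell_type"]):
            raise UnknownTypeError(f"cell type {t!r} not present")
    ligand, receptor = pair
    xl_all = expr.gene_column(ligand)
    xr_all = expr.gene_column(receptor)
    num = 0.0
    den = 0.0
    df = cells.df
    for _, sub in df.groupby("fov_id"):
        src = sub.index[(sub["cell_type"] == source_type).to_numpy()].to_numpy()
        tgt = sub.index[(sub["cell_type"] == target_type).to_numpy()].to_numpy()
        if len(src) == 0 or len(tgt) == 0:
            continue
        W = kernel_weights(
            df.loc[src, ["x_um", "y_um"]].to_numpy(float),
            df.loc[tgt, ["x_um", "y_um"]].to_numpy(float),
            bandwidth_um,
        )
        num += float(xl_all[src] @ W @ xr_all[tgt])
        den += float(W.sum())
    if den == 0.0:
        log.warning(
            "no same-FOV %s/%s pairs within kernel support; score undefined",
            source_type, target_type,
        )
        return float("nan")
    return num / den


def score_all(
    expr: ExpressionMatrix,
    cells: CellTable,
    pairs: LRPairTable,
    bandwidth_um: float = DEFAULT_BANDWIDTH_UM,
) -> LRScoreResult:
    """Score every LR pair in every ordered type direction (source != target).

    Equivalent to calling :func:`spatial_lr_score` for each combination, but
    shares the kernel matrix across pairs within a direction.
    """
    for g in pairs.genes():
        expr.gene_index(g)  # raises UnknownGeneError naming the gene
    types = cells.cell_types
    type_counts = cells.df["cell_type"].value_counts()
    lig = pairs.df["ligand_gene"].to_numpy()
    rec = pairs.df["receptor_gene"].to_numpy()
    ligand_idx = np.array([expr.gene_index(g) for g in lig])
    receptor_idx = np.array([expr.gene_index(g) for g in rec])

    rows = []
    for s, t in permutations(types, 2):
        num = np.zeros(len(pairs))
        den = 0.0
        for xy_s, xy_t, Xs, Xt in _direction_arrays(expr, cells, s, t):
            W = kernel_weights(xy_s, xy_t, bandwidth_um)
            A = np.asarray(Xs.todense() if sp.issparse(Xs) else Xs, float)
            B = np.asarray(Xt.todense() if sp.issparse(Xt) else Xt, float)
            # products (gene_a in source)^T W (gene_b in target) for the
            # needed gene pairs only
            WB = W @ B  # (n_src, n_genes)
            num += np.einsum("ij,ij->j", A[:, ligand_idx], WB[:, receptor_idx])
            den += float(W.sum())
        scores = num / den if den > 0 else np.full(len(pairs), np.nan)
        for k, pid in enumerate(pairs.pair_ids):
            rows.append(
                {
                    "source_type": s,
                    "target_type": t,
                    "pair_id": pid,
                    "ligand": lig[k],
                    "receptor": rec[k],
                    "score": scores[k],
                    "n_source": int(type_counts[s]),
                    "n_target": int(type_counts[t]),
                }
            )
    table = pd.DataFrame(rows)
    return LRScoreResult(table, bandwidth_um=bandwidth_um)


def rank_pairs(
    result: LRScoreResult, source_type: str, target_type: str, top_n: int = 20
) -> pd.DataFrame:
    """Top-n LR pairs for one direction, descending by score; ties broken by
    pair_id lexicographic order for determinism."""
    sub = result.direction(source_type, target_type).copy()
    sub = sub.sort_values(
        ["score", "pair_id"], ascending=[False, True], kind="mergesort"
    )
    return sub.head(top_n).reset_index(drop=True)


def permutation_null(
    expr: ExpressionMatrix,
    cells: CellTable,
    pair: tuple[str, str],
    source_type: str,
    target_type: str,
    bandwidth_um: float = DEFAULT_BANDWIDTH_UM,
    n_perm: int = 99,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation significance of one direction's spatial LR score.

    Cell-type labels are shuffled within each FOV ``n_perm`` times
    (coordinates and expression stay fixed).  Returns ``(perm_z, perm_p)``
    with ``perm_p = (1 + #{null >= observed}) / (n_perm + 1)`` and
    ``perm_z = (observed - null mean) / null SD`` (NaN when the null is
    degenerate).  Deterministic given ``seed``.
    """
    if n_perm < 19:
        raise SpaxtalkError("n_perm must be at least 19")
    if source_type == target_type:
        raise SelfSelfError(
            f"self-self direction {source_type} -> {target_type} is excluded"
        )
    for t in (source_type, target_type):
        if t not in set(cells.df["cell_type"]):
            raise UnknownTypeError(f"cell type {t!r} not present")
    ligand, receptor = pair
    xl = expr.gene_column(ligand)
    xr = expr.gene_column(receptor)
    df = cells.df
    xy = df[["x_um", "y_um"]].to_numpy(float)
    labels = df["cell_type"].to_numpy()
    fov_groups = [idx.to_numpy() for _, idx in df.groupby("fov_id").groups.items()]

    def score(lab: np.ndarray) -> float:
        num = 0.0
        den = 0.0
        for idx in fov_groups:
            s = idx[lab[idx] == source_type]
            t = idx[lab[idx] == target_type]
            if len(s) == 0 or len(t) == 0:
                continue
            W = kernel_weights(xy[s], xy[t], bandwidth_um)
            num += float(xl[s] @ W @ xr[t])
            den += float(W.sum())
        return num / den if den > 0 else float("nan")

    observed = score(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = labels.copy()
        for idx in fov_groups:
            perm[idx] = perm[idx[rng.permutation(len(idx))]]
        null[b] = score(perm)
    valid = null[~np.isnan(null)]
    # tolerate float rounding when null scores tie the observed value
    eps = 1e-12 * max(1.0, abs(observed))
    perm_p = (1.0 + float((valid >= observed - eps).sum())) / (len(valid) + 1.0)
    sd = float(valid.std(ddof=1)) if len(valid) > 1 else 0.0
    degenerate = sd <= 1e-12 * max(1.0, abs(observed), abs(float(valid.mean())))
    perm_z = float("nan") if degenerate else (observed - float(valid.mean())) / sd
    return perm_z, perm_p
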