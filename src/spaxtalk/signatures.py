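"""Gene-set "total expression" scores and small derived-count utilities.

The gene-set score for a cell is simply the sum of its (normalized)
expression over the genes of the set — the natural reading of a
total-expression enrichment score for a pathway gene list.  Group
comparisons use the two-sided Mann-Whitney rank-sum test.

``momf_count`` converts flow-cytometry frequencies into an absolute count
of monocyte-derived macrophages (MoMFs):
total live non-parenchymal cells x (%CD45+ of live) x (%MoMF of CD45+).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .datatypes import ExpressionMatrix, SpaxtalkError, UnknownGeneError

log = logging.getLogger(__name__)

__all__ = ["GeneSetScore", "geneset_score", "compare_scores", "momf_count"]


@dataclass
class GeneSetScore:
    """Per-cell total-expression scores for one gene set."""

    scores: pd.Series  # indexed by cell_id
    gene_set_name: str
    n_genes_used: int
    groups: pd.Series | None = None  # optional group label per cell

    def group_values(self, group: str) -> np.ndarray:
        if self.groups is None:
            raise SpaxtalkError("no group labels attached to this score")
        vals = self.scores[self.groups == group]
        if len(vals) == 0:
            raise SpaxtalkError(f"group {group!r} is empty")
        return vals.to_numpy(float)


def geneset_score(
    expr: ExpressionMatrix,
    gene_set: list[str],
    cell_mask: np.ndarray | None = None,
    name: str = "gene_set",
    groups: pd.Series | None = None,
    zscore: bool = False,
) -> GeneSetScore:
    """Per-cell sum of expression over the set's genes present in the matrix.

    Missing genes are skipped with a log message; if none are present an
    error is raised.  With ``zscore=True`` each gene is standardized across
    the selected cells before summing (variant scoring, off by default).
    """
    present = [g for g in gene_set if g in expr.gene_names]
    missing = [g for g in gene_set if g not in expr.gene_names]
    if missing:
        log.warning("genes absent from matrix and skipped: %s", missing)
    if not present:
        raise UnknownGeneError(f"no genes of the set present: {sorted(gene_set)}")
    cols = np.column_stack([expr.gene_column(g) for g in present])
    ids = expr.cell_ids
    if cell_mask is not None:
        cell_mask = np.asarray(cell_mask, bool)
        cols = cols[cell_mask]
        ids = ids[cell_mask]
    if zscore:
        sd = cols.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        cols = (cols - cols.mean(axis=0)) / sd
    scores = pd.Series(cols.sum(axis=1), index=ids, name=name)
    if groups is not None:
        groups = groups.reindex(ids)
    return GeneSetScore(
        scores=scores, gene_set_name=name, n_genes_used=len(present), groups=groups
    )


def compare_scores(
    scores: GeneSetScore, group_a: str, group_b: str
) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney comparison of the score between two groups.

    Returns (difference of means a - b, U statistic, p-value).
    """
    a = scores.group_values(group_a)
    b = scores.group_values(group_b)
    stat, p = mannwhitneyu(a, b, alternative="two-sided")
    return float(a.mean() - b.mean()), float(stat), float(p)


def momf_count(
    total_live_npcs: float, pct_cd45_of_live: float, pct_momf_of_cd45: float
) -> int:
    """Absolute number of isolated MoMFs from flow-cytometry frequencies.

    ``total_live_npcs x pct_cd45_of_live x pct_momf_of_cd45``, with the two
    percentages given as fractions in [0, 1]; rounded to the nearest cell.
    """
    if total_live_npcs < 0:
        raise SpaxtalkError("total_live_npcs must be non-negative")
    for name, frac in (
        ("pct_cd45_of_live", pct_cd45_of_live),
        ("pct_momf_of_cd45", pct_momf_of_cd45),
    ):
        if not 0.0 <= frac <= 1.0:
            raise SpaxtalkError(f"{name} must lie in [0, 1], got {frac}")
    return int(round(total_live_npcs * pct_cd45_of_live * pct_momf_of_cd45))
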