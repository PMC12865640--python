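"""Synthetic CosMx-like spatial single-cell datasets with planted ground truth.

The generator emulates the statistical structure of a multi-FOV in-situ
single-cell run on zonated liver tissue:

* FOVs tile a global coordinate grid; every cell carries global micrometer
  coordinates and an FOV id.
* One landmark anchor per FOV (a stand-in for a portal tract): cells of the
  landmark type (cholangiocyte analog) are Gaussian-scattered around it.
* Spatial zonation: in the ``radial_gradient`` layout a designated
  "periportal" cell type is placed with density decaying with distance from
  the anchor; in the ``two_block`` layout each FOV is split into two
  half-blocks with distinct cell-type compositions (for niche-recovery
  testing).
* Counts follow a Poisson-lognormal model: per-cell library factor x
  per-gene baseline rate, giving negative-binomial-like overdispersion.
* Planted ligand-receptor interactions act multiplicatively on rates: the
  ligand rate is boosted in source-type cells lying within the interaction
  range of a target-type cell, and the receptor rate symmetrically in
  target-type cells near a source-type cell. With ``effect_size = 1`` the
  output is exactly the no-interaction null.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .datatypes import CellTable, ExpressionMatrix, GroundTruth, LRPairTable, ValidationError

__all__ = ["PlantedInteraction", "SimConfig", "default_config", "generate_dataset"]

# Landmark cells scatter around their anchor with this Gaussian sigma;
# approximates the footprint of a portal tract.
LANDMARK_SIGMA_UM = 25.0
# Length scale of the periportal placement-density decay exp(-d / tau).
PERIPORTAL_DECAY_UM = 75.0
# Cells within this distance of the anchor are labeled "periportal" in the
# radial ground truth.
PERIPORTAL_ZONE_RADIUS_UM = 150.0


@dataclass(frozen=True)
class PlantedInteraction:
    """A ground-truth spatial ligand-receptor interaction.

    ``effect_size`` multiplies the ligand rate in source-type cells within
    ``interaction_range_um`` of a target-type cell (and the receptor rate in
    target-type cells near a source-type cell). ``effect_size = 1`` is the
    null.
    """

    ligand: str
    receptor: str
    source_type: str
    target_type: str
    effect_size: float = 5.0
    interaction_range_um: float = 30.0

    @property
    def pair_id(self) -> str:
        return f"{self.ligand}_{self.receptor}"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_fovs: int = 2
    fov_size_um: float = 500.0
    cells_per_fov: int = 300
    cell_types: dict[str, float] = field(
        default_factory=lambda: {
            "Cholangiocytes": 0.05,
            "ECs_periportal": 0.15,
            "ECs_pericentral": 0.15,
            "Macrophages": 0.20,
            "Hepatocytes": 0.30,
            "T_cells": 0.15,
        }
    )
    landmark_type: str = "Cholangiocytes"
    periportal_type: str | None = "ECs_periportal"
    zone_layout: str = "radial_gradient"  # or "two_block"
    genes: tuple[str, ...] = ()
    baseline_rate: float = 2.5
    library_size_dispersion: float = 0.35
    planted_interactions: tuple[PlantedInteraction, ...] = ()
    decoy_pairs: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.n_fovs <= 0 or self.cells_per_fov <= 0:
            raise ValidationError("n_fovs and cells_per_fov must be positive")
        if self.fov_size_um <= 0:
            raise ValidationError("fov_size_um must be positive")
        if self.baseline_rate <= 0:
            raise ValidationError("baseline_rate must be positive")
        if self.library_size_dispersion < 0:
            raise ValidationError("library_size_dispersion must be non-negative")
        if self.zone_layout not in ("radial_gradient", "two_block"):
            raise ValidationError(f"unknown zone_layout {self.zone_layout!r}")
        weights = np.array(list(self.cell_types.values()), float)
        if not (np.isfinite(weights).all() and (weights >= 0).all() and weights.sum() > 0):
            raise ValidationError("cell-type abundance weights must be non-negative with positive sum")
        if self.landmark_type not in self.cell_types:
            raise ValidationError(f"landmark_type {self.landmark_type!r} not in cell_types")
        if self.periportal_type is not None and self.periportal_type not in self.cell_types:
            raise ValidationError(f"periportal_type {self.periportal_type!r} not in cell_types")
        gene_set = set(self.genes)
        for pi in self.planted_interactions:
            if pi.effect_size < 1:
                raise ValidationError(f"effect_size must be >= 1 (got {pi.effect_size})")
            if pi.interaction_range_um <= 0:
                raise ValidationError("interaction_range_um must be positive")
            for g in (pi.ligand, pi.receptor):
                if g not in gene_set:
                    raise ValidationError(f"planted gene {g!r} not in genes")
            for t in (pi.source_type, pi.target_type):
                if t not in self.cell_types:
                    raise ValidationError(f"planted cell type {t!r} not in cell_types")
        if self.decoy_pairs < 0:
            raise ValidationError("decoy_pairs must be non-negative")


# Inflammation / fibrosis transcripts used for default signature panels.
SIGNATURE_GENES = ("CCL2", "CXCL10", "ITGAM", "CCR2", "COL1A1", "IL1B", "IL1R1")


def default_config(
    n_fovs: int = 2,
    cells_per_fov: int = 300,
    n_genes: int = 120,
    decoy_pairs: int = 50,
    effect_size: float = 5.0,
    interaction_range_um: float = 30.0,
    zone_layout: str = "radial_gradient",
    seed: int = 0,
) -> SimConfig:
    """Standard study conditions: one IL1B->IL1R1 macrophage-to-periportal-EC
    interaction planted among decoy pairs of background genes.

    The gene panel holds the named signature transcripts plus numbered filler
    genes up to ``n_genes``; the baseline rate puts the median per-cell total
    around 300 counts, the scale of a ~1000-plex in-situ panel restricted to
    this panel size.
    """
    planted = PlantedInteraction(
        "IL1B", "IL1R1", "Macrophages", "ECs_periportal",
        effect_size=effect_size, interaction_range_um=interaction_range_um,
    )
    n_filler = max(0, n_genes - len(SIGNATURE_GENES))
    genes = SIGNATURE_GENES + tuple(f"GENE{i:04d}" for i in range(n_filler))
    if 2 * decoy_pairs > n_filler:
        raise ValidationError(
            f"{decoy_pairs} decoy pairs need {2 * decoy_pairs} filler genes; "
            f"only {n_filler} available — increase n_genes"
        )
    return SimConfig(
        n_fovs=n_fovs,
        cells_per_fov=cells_per_fov,
        genes=genes,
        planted_interactions=(planted,),
        decoy_pairs=decoy_pairs,
        zone_layout=zone_layout,
        seed=seed,
    )


def null_config(**kwargs) -> SimConfig:
    """Same conditions as :func:`default_config` but with effect_size 1 (the
    no-interaction null)."""
    return default_config(effect_size=1.0, **kwargs)


def _fov_offsets(n_fovs: int, fov_size: float) -> list[tuple[float, float]]:
    """FOVs tile a near-square global grid with fixed offsets."""
    ncols = int(math.ceil(math.sqrt(n_fovs)))
    return [
        ((i % ncols) * fov_size, (i // ncols) * fov_size) for i in range(n_fovs)
    ]


def _sample_periportal_positions(
    rng: np.random.Generator, n: int, fov_size: float, anchor: np.ndarray
) -> np.ndarray:
    """Rejection-sample positions with density exp(-d(anchor)/tau) in the FOV."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        batch = max(64, 4 * (n - filled))
        cand = rng.uniform(0, fov_size, size=(batch, 2))
        d = np.hypot(cand[:, 0] - anchor[0], cand[:, 1] - anchor[1])
        accept = rng.random(batch) < np.exp(-d / PERIPORTAL_DECAY_UM)
        good = cand[accept]
        take = min(len(good), n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def _two_block_weights(config: SimConfig) -> tuple[dict[str, float], dict[str, float]]:
    """Split non-landmark types into two composition blocks.

    Block 1 (the anchor-containing half) is dominated by the first half of
    the non-landmark type list (which includes the periportal type when one
    is configured); block 2 by the rest, with a 10% cross-leak so the blocks
    are distinct but not artificially pure.
    """
    non_landmark = [t for t in config.cell_types if t != config.landmark_type]
    half = max(1, len(non_landmark) // 2)
    if config.periportal_type in non_landmark:
        # put the periportal type into block 1's dominant group
        non_landmark.remove(config.periportal_type)
        non_landmark.insert(0, config.periportal_type)
    group1, group2 = non_landmark[:half], non_landmark[half:]
    leak = 0.10
    w1 = {t: (1 - leak) if t in group1 else leak for t in non_landmark}
    w2 = {t: (1 - leak) if t in group2 else leak for t in non_landmark}
    return w1, w2


def _place_cells(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place all cells, returning the cell table plus per-cell true zone and
    anchor distance columns (dropped from the public table later)."""
    fov_size = config.fov_size_um
    offsets = _fov_offsets(config.n_fovs, fov_size)
    types = list(config.cell_types)
    weights = np.array([config.cell_types[t] for t in types], float)
    weights = weights / weights.sum()
    n_landmark = max(1, int(round(config.cell_types[config.landmark_type]
                                  / sum(config.cell_types.values())
                                  * config.cells_per_fov)))
    rows: list[dict] = []
    for f, (ox, oy) in enumerate(offsets):
        fov_id = f"F{f:03d}"
        # anchor at a seeded random interior point (central 60% of the FOV in
        # radial layout; in the left half-block for two_block)
        if config.zone_layout == "two_block":
            anchor = np.array([
                rng.uniform(0.10 * fov_size, 0.40 * fov_size),
                rng.uniform(0.20 * fov_size, 0.80 * fov_size),
            ])
        else:
            anchor = rng.uniform(0.20 * fov_size, 0.80 * fov_size, size=2)

        # landmark cells: Gaussian scatter around the anchor, clipped to FOV
        lm_xy = rng.normal(anchor, LANDMARK_SIGMA_UM, size=(n_landmark, 2))
        lm_xy = np.clip(lm_xy, 0.0, fov_size)

        n_other = config.cells_per_fov - n_landmark
        other_types_all = [t for t in types if t != config.landmark_type]
        w_other = np.array([config.cell_types[t] for t in other_types_all], float)
        w_other = w_other / w_other.sum()

        if config.zone_layout == "two_block":
            xy = rng.uniform(0, fov_size, size=(n_other, 2))
            in_block1 = xy[:, 0] < fov_size / 2
            w1, w2 = _two_block_weights(config)
            names = np.empty(n_other, object)
            for block_mask, wmap in ((in_block1, w1), (~in_block1, w2)):
                k = int(block_mask.sum())
                p = np.array([wmap[t] for t in other_types_all], float)
                p = p / p.sum()
                names[block_mask] = rng.choice(other_types_all, size=k, p=p)
        else:
            names = rng.choice(other_types_all, size=n_other, p=w_other)
            xy = rng.uniform(0, fov_size, size=(n_other, 2))
            if config.periportal_type is not None:
                pp = names == config.periportal_type
                if pp.any():
                    xy[pp] = _sample_periportal_positions(
                        rng, int(pp.sum()), fov_size, anchor
                    )

        all_xy = np.vstack([lm_xy, xy])
        all_types = [config.landmark_type] * n_landmark + list(names)
        d_anchor = np.hypot(all_xy[:, 0] - anchor[0], all_xy[:, 1] - anchor[1])
        if config.zone_layout == "two_block":
            zones = np.where(all_xy[:, 0] < fov_size / 2, "block_1", "block_2")
        else:
            zones = np.where(
                d_anchor <= PERIPORTAL_ZONE_RADIUS_UM, "periportal", "distal"
            )
        for i in range(config.cells_per_fov):
            rows.append(
                {
                    "cell_id": f"{fov_id}_c{i:05d}",
                    "x_um": all_xy[i, 0] + ox,
                    "y_um": all_xy[i, 1] + oy,
                    "fov_id": fov_id,
                    "cell_type": all_types[i],
                    "_zone": zones[i],
                    "_d_anchor": d_anchor[i],
                }
            )
    return pd.DataFrame(rows)


def _interaction_masks(
    df: pd.DataFrame, pi: PlantedInteraction
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of source cells near a target cell and vice versa,
    within the interaction range, per FOV."""
    near_src = np.zeros(len(df), bool)
    near_tgt = np.zeros(len(df), bool)
    for _, idx in df.groupby("fov_id").groups.items():
        sub = df.loc[idx]
        src = sub.index[sub["cell_type"] == pi.source_type]
        tgt = sub.index[sub["cell_type"] == pi.target_type]
        if len(src) == 0 or len(tgt) == 0:
            continue
        src_xy = df.loc[src, ["x_um", "y_um"]].to_numpy(float)
        tgt_xy = df.loc[tgt, ["x_um", "y_um"]].to_numpy(float)
        tree_t = cKDTree(tgt_xy)
        tree_s = cKDTree(src_xy)
        d_s, _ = tree_t.query(src_xy, k=1)
        d_t, _ = tree_s.query(tgt_xy, k=1)
        near_src[df.index.get_indexer(src)] = d_s <= pi.interaction_range_um
        near_tgt[df.index.get_indexer(tgt)] = d_t <= pi.interaction_range_um
    return near_src, near_tgt


def _build_pair_table(config: SimConfig, rng: np.random.Generator) -> LRPairTable:
    """Planted pairs plus decoy pairs drawn from unused genes."""
    planted = [(pi.ligand, pi.receptor) for pi in config.planted_interactions]
    used = {g for lr in planted for g in lr}
    free = [g for g in config.genes if g not in used]
    if 2 * config.decoy_pairs > len(free):
        raise ValidationError(
            f"not enough unused genes ({len(free)}) for {config.decoy_pairs} decoy pairs"
        )
    perm = rng.permutation(len(free))
    decoys = [
        (free[perm[2 * k]], free[perm[2 * k + 1]]) for k in range(config.decoy_pairs)
    ]
    return LRPairTable.from_pairs(planted + decoys)


def generate_dataset(
    config: SimConfig,
) -> tuple[CellTable, ExpressionMatrix, LRPairTable, GroundTruth]:
    """Generate one synthetic dataset under the given study conditions.

    Returns the cell table, the raw count matrix (cells x genes, sparse),
    the ligand-receptor pair table (planted + decoys), and the ground truth.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    df = _place_cells(config, rng)

    genes = list(config.genes)
    n_cells, n_genes = len(df), len(genes)
    sigma = config.library_size_dispersion
    # mean-1 lognormal library factors, so gene means stay at baseline_rate
    lib = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_cells)) if sigma > 0 else np.ones(n_cells)

    rates = np.full((n_cells, n_genes), config.baseline_rate)
    gene_pos = {g: j for j, g in enumerate(genes)}
    for pi in config.planted_interactions:
        near_src, near_tgt = _interaction_masks(df, pi)
        rates[near_src, gene_pos[pi.ligand]] *= pi.effect_size
        rates[near_tgt, gene_pos[pi.receptor]] *= pi.effect_size
    rates *= lib[:, None]
    counts = rng.poisson(rates).astype(np.int64)

    pairs = _build_pair_table(config, rng)

    cells = CellTable(
        df[["cell_id", "x_um", "y_um", "fov_id", "cell_type"]].copy()
    )
    expr = ExpressionMatrix(
        sp.csr_matrix(counts), pd.Index(genes), cells.cell_ids
    )
    planted_ids = {pi.pair_id for pi in config.planted_interactions}
    truth = GroundTruth(
        zone_of=dict(zip(df["cell_id"], df["_zone"])),
        planted_pairs={pid: pid in planted_ids for pid in pairs.pair_ids},
        landmark_distance=dict(zip(df["cell_id"], df["_d_anchor"].astype(float))),
        planted=[
            {
                "pair_id": pi.pair_id,
                "ligand": pi.ligand,
                "receptor": pi.receptor,
                "source_type": pi.source_type,
                "target_type": pi.target_type,
                "effect_size": pi.effect_size,
                "interaction_range_um": pi.interaction_range_um,
            }
            for pi in config.planted_interactions
        ],
    )
    return cells, expr, pairs, truth
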