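"""End-to-end orchestration: simulate/load -> validate -> proximity ->
LR scoring -> niche -> signatures, with a machine-readable run manifest.

Every stage writes plain-text outputs (TSV/CSV/JSON) into the run
directory; the manifest records parameters, the seed, SHA-256 checksums and
row counts of every output, so a re-run with the same config is
byte-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lr_scoring, niche, proximity, signatures, spatial_io, synthetic_data
from .datatypes import CellTable, ExpressionMatrix, LRPairTable, SpaxtalkError

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Either ``sim`` (synthetic study conditions) or the three input paths
    must be given.  ``seed`` is mandatory: no stage may consume unseeded
    randomness.
    """

    out_dir: str
    seed: int
    sim: synthetic_data.SimConfig | None = None
    cells_path: str | None = None
    expr_path: str | None = None
    pairs_path: str | None = None
    drop_tumor: bool = False
    bandwidth_um: float = 20.0
    radius_um: float = 20.0
    k_neighbors: int = 30
    n_niches: int = 6
    top_n: int = 20
    n_perm: int = 0
    landmark_type: str = "Cholangiocytes"
    focus_source: str | None = None  # direction highlighted in ranking/permutation
    focus_target: str | None = None
    gene_panel: tuple[str, ...] = niche.DEFAULT_GENE_PANEL

    def validate(self) -> None:
        if self.seed is None:
            raise SpaxtalkError("seed must be set: no unseeded randomness is allowed")
        for name in ("bandwidth_um", "radius_um", "k_neighbors", "n_niches", "top_n"):
            if getattr(self, name) <= 0:
                raise SpaxtalkError(f"{name} must be positive")
        if self.sim is None and not (
            self.cells_path and self.expr_path and self.pairs_path
        ):
            raise SpaxtalkError(
                "either sim conditions or cells/expr/pairs input paths are required"
            )


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; a ``sim:`` block becomes a SimConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim_raw = raw.pop("sim", None)
    sim = None
    if sim_raw is not None:
        planted = tuple(
            synthetic_data.PlantedInteraction(**p)
            for p in sim_raw.pop("planted_interactions", [])
        )
        genes = tuple(sim_raw.pop("genes", ()))
        sim = synthetic_data.SimConfig(
            planted_interactions=planted, genes=genes, **sim_raw
        )
    cfg = RunConfig(sim=sim, **raw)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("sim",)
        },
        "stages": {},
        "outputs": {},
    }
    if config.sim is not None:
        manifest["parameters"]["sim"] = dataclasses.asdict(config.sim)

    def record(stage: str, name: str, path: Path, n_rows: int) -> None:
        manifest["outputs"][name] = {
            "path": path.name,
            "sha256": _sha256(path),
            "n_rows": int(n_rows),
        }
        manifest["stages"].setdefault(stage, []).append(name)

    def fail(stage: str, exc: Exception):
        raise SpaxtalkError(f"stage {stage!r} failed: {exc}") from exc

    # -- simulate / load -----------------------------------------------------
    try:
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            cells, expr, pairs, truth = synthetic_data.generate_dataset(sim)
            spatial_io.write_cells(cells, out / "cells.csv")
            spatial_io.write_expression(expr, out / "matrix.mtx", fmt="mtx")
            spatial_io.write_lr_pairs(pairs, out / "pairs.tsv")
            spatial_io.write_ground_truth(truth, out / "ground_truth.json")
            record("simulate", "cells", out / "cells.csv", cells.n_cells)
            record("simulate", "expression", out / "matrix.mtx", expr.n_cells)
            record("simulate", "pairs", out / "pairs.tsv", len(pairs))
            record("simulate", "ground_truth", out / "ground_truth.json", cells.n_cells)
        else:
            cells = spatial_io.read_cells(config.cells_path, drop_tumor=config.drop_tumor)
            expr = spatial_io.read_expression(config.expr_path, cells=cells)
            pairs = spatial_io.read_lr_pairs(config.pairs_path)
    except SpaxtalkError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        fail("input", exc)

    pairs = spatial_io.filter_lr_pairs(pairs, set(expr.gene_names))
    norm = lr_scoring.normalize_expression(expr)

    # -- proximity ------------------------------------------------------------
    try:
        prox = proximity.directional_proximity(
            cells, bandwidth_um=config.bandwidth_um, normalize=True
        )
        _write_tsv(prox.score, out / "proximity.tsv", index=True)
        record("proximity", "proximity_matrix", out / "proximity.tsv", len(prox.score))

        dist_rows = []
        for q in cells.cell_types:
            if q == config.landmark_type or config.landmark_type not in set(
                cells.df["cell_type"]
            ):
                continue
            s = proximity.nearest_landmark_distance(cells, q, config.landmark_type)
            dist_rows.append(
                {"query_type": q, "mean_um": s.mean, "median_um": s.median, "n": s.n}
            )
        if dist_rows:
            ddf = pd.DataFrame(dist_rows)
            _write_tsv(ddf, out / "landmark_distance.tsv")
            record("proximity", "landmark_distance", out / "landmark_distance.tsv", len(ddf))
    except SpaxtalkError:
        raise
    except Exception as exc:  # pragma: no cover
        fail("proximity", exc)

    # -- LR scoring -----------------------------------------------------------
    try:
        result = lr_scoring.score_all(norm, cells, pairs, bandwidth_um=config.bandwidth_um)
        _write_tsv(result.table, out / "lr_scores.tsv")
        record("lr_score", "lr_scores", out / "lr_scores.tsv", len(result.table))

        src, tgt = config.focus_source, config.focus_target
        if src is None or tgt is None:
            best = result.table.loc[result.table["score"].idxmax()]
            src, tgt = best["source_type"], best["target_type"]
        ranking = lr_scoring.rank_pairs(result, src, tgt, top_n=config.top_n)
        _write_tsv(ranking, out / "top_pairs.tsv")
        record("lr_score", "top_pairs", out / "top_pairs.tsv", len(ranking))

        if config.n_perm > 0:
            top = ranking.iloc[0]
            z, p = lr_scoring.permutation_null(
                norm, cells, (top["ligand"], top["receptor"]), src, tgt,
                bandwidth_um=config.bandwidth_um,
                n_perm=config.n_perm, seed=config.seed,
            )
            pdf = pd.DataFrame(
                [{
                    "source_type": src, "target_type": tgt,
                    "pair_id": top["pair_id"], "score": top["score"],
                    "perm_z": z, "perm_p": p, "n_perm": config.n_perm,
                }]
            )
            _write_tsv(pdf, out / "permutation.tsv")
            record("lr_score", "permutation", out / "permutation.tsv", 1)
    except SpaxtalkError:
        raise
    except Exception as exc:  # pragma: no cover
        fail("lr_score", exc)

    # -- niche ----------------------------------------------------------------
    try:
        comp = niche.neighborhood_composition(cells, k_neighbors=config.k_neighbors)
        model = niche.assign_niches(
            comp, n_niches=config.n_niches, seed=config.seed,
            k_neighbors=config.k_neighbors,
        )
        nd = model.niche_of.rename_axis("cell_id").reset_index()
        nd.to_csv(out / "niche_assignments.csv", index=False)
        record("niche", "niche_assignments", out / "niche_assignments.csv", len(nd))
        landmark = (
            config.landmark_type
            if config.landmark_type in set(cells.df["cell_type"])
            else None
        )
        panel = tuple(g for g in config.gene_panel if g in expr.gene_names)
        summaries = niche.niche_summaries(
            model, cells, expr=norm if panel else None,
            landmark_type=landmark, gene_panel=panel,
        )
        for key, sdf in summaries.items():
            path = out / f"niche_{key}.tsv"
            _write_tsv(sdf, path, index=True)
            record("niche", f"niche_{key}", path, len(sdf))
    except SpaxtalkError:
        raise
    except Exception as exc:  # pragma: no cover
        fail("niche", exc)

    # -- signatures -----------------------------------------------------------
    try:
        panel = [g for g in config.gene_panel if g in expr.gene_names]
        if panel:
            groups = pd.Series(
                cells.df["cell_type"].to_numpy(), index=cells.cell_ids
            )
            gs = signatures.geneset_score(
                norm, panel, name="inflammation_fibrosis", groups=groups
            )
            sdf = pd.DataFrame(
                {"cell_id": gs.scores.index, "score": gs.scores.to_numpy(),
                 "group": gs.groups.to_numpy()}
            )
            _write_tsv(sdf, out / "signature_scores.tsv")
            record("signatures", "signature_scores", out / "signature_scores.tsv", len(sdf))
    except SpaxtalkError:
        raise
    except Exception as exc:  # pragma: no cover
        fail("signatures", exc)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("pipeline complete: %d outputs in %s", len(manifest["outputs"]), out)
    return manifest
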