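"""Independent brute-force reference implementations.

Every function here is a deliberately naive O(n^2) double loop over plain
Python/NumPy scalars, kept free of any code path shared with the package,
so it can serve as an oracle for the optimized implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def bf_nearest_distance(
    df: pd.DataFrame, query_type: str, landmark_type: str
) -> dict[str, float]:
    """Per query cell, min Euclidean distance to a landmark cell in the same
    FOV; NaN when the FOV has no landmark."""
    out: dict[str, float] = {}
    for _, q in df[df["cell_type"] == query_type].iterrows():
        best = math.inf
        for _, l in df[df["cell_type"] == landmark_type].iterrows():
            if l["fov_id"] != q["fov_id"]:
                continue
            d = math.hypot(q["x_um"] - l["x_um"], q["y_um"] - l["y_um"])
            best = min(best, d)
        out[q["cell_id"]] = best if best < math.inf else float("nan")
    return out


def bf_radius_count(
    df: pd.DataFrame, center_type: str, neighbor_type: str, radius: float
) -> dict[str, int]:
    out: dict[str, int] = {}
    for _, c in df[df["cell_type"] == center_type].iterrows():
        n = 0
        for _, o in df[df["cell_type"] == neighbor_type].iterrows():
            if o["fov_id"] != c["fov_id"] or o["cell_id"] == c["cell_id"]:
                continue
            d = math.hypot(c["x_um"] - o["x_um"], c["y_um"] - o["y_um"])
            if d <= radius:
                n += 1
        out[c["cell_id"]] = n
    return out


def bf_proximity(
    df: pd.DataFrame, bandwidth: float, normalize: bool
) -> pd.DataFrame:
    """Source x target directional proximity matrix by double loop."""
    types = sorted(df["cell_type"].unique())
    rows = df.to_dict("records")
    per_cell: list[tuple[str, dict[str, float]]] = []  # (source type, weight by target type)
    for i, ci in enumerate(rows):
        w_by_type = {t: 0.0 for t in types}
        total = 0.0
        for j, cj in enumerate(rows):
            if i == j or ci["fov_id"] != cj["fov_id"]:
                continue
            d2 = (ci["x_um"] - cj["x_um"]) ** 2 + (ci["y_um"] - cj["y_um"]) ** 2
            w = math.exp(-d2 / (2 * bandwidth**2))
            w_by_type[cj["cell_type"]] += w
            total += w
        if total == 0.0:
            continue  # isolated source cell: excluded from its type's average
        if normalize:
            w_by_type = {t: w / total for t, w in w_by_type.items()}
        per_cell.append((ci["cell_type"], w_by_type))
    score = pd.DataFrame(np.nan, index=types, columns=types)
    for s in types:
        contrib = [w for (ct, w) in per_cell if ct == s]
        if not contrib:
            continue
        for t in types:
            score.loc[s, t] = sum(w[t] for w in contrib) / len(contrib)
    return score


def bf_lr_score(
    df: pd.DataFrame,
    xl: dict[str, float],
    xr: dict[str, float],
    source_type: str,
    target_type: str,
    bandwidth: float,
) -> float:
    """Kernel-weighted mean of ligand x receptor products; xl/xr map
    cell_id -> expression value."""
    num = 0.0
    den = 0.0
    for _, ci in df[df["cell_type"] == source_type].iterrows():
        for _, cj in df[df["cell_type"] == target_type].iterrows():
            if ci["fov_id"] != cj["fov_id"] or ci["cell_id"] == cj["cell_id"]:
                continue
            d2 = (ci["x_um"] - cj["x_um"]) ** 2 + (ci["y_um"] - cj["y_um"]) ** 2
            w = math.exp(-d2 / (2 * bandwidth**2))
            num += xl[ci["cell_id"]] * xr[cj["cell_id"]] * w
            den += w
    return num / den if den > 0 else float("nan")


def bf_knn_composition(df: pd.DataFrame, k: int) -> pd.DataFrame:
    """k-NN neighbor-type frequencies by sorting the full distance list."""
    types = sorted(df["cell_type"].unique())
    comp = pd.DataFrame(0.0, index=df["cell_id"], columns=types)
    for _, ci in df.iterrows():
        dists = []
        for _, cj in df.iterrows():
            if cj["cell_id"] == ci["cell_id"] or cj["fov_id"] != ci["fov_id"]:
                continue
            d = math.hypot(ci["x_um"] - cj["x_um"], ci["y_um"] - cj["y_um"])
            dists.append((d, cj["cell_id"], cj["cell_type"]))
        dists.sort()
        kk = min(k, len(dists))
        for _, _, t in dists[:kk]:
            comp.loc[ci["cell_id"], t] += 1.0 / kk
    return comp


def exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p by exhaustive enumeration of all group
    assignments (small n only)."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_stat(idx_a: tuple[int, ...]) -> float:
        xs = pooled[list(idx_a)]
        ys = np.delete(pooled, list(idx_a))
        u = 0.0
        for x in xs:
            for y in ys:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    obs = u_stat(tuple(range(n_a)))
    n_b = len(pooled) - n_a
    mean_u = n_a * n_b / 2.0
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_stat(idx) - mean_u) >= abs(obs - mean_u) - 1e-12:
            count += 1
    return count / total
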