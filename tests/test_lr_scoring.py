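import numpy as np
import pandas as pd
import pytest

from spaxtalk import (
    CellTable,
    ExpressionMatrix,
    LRPairTable,
    SpaxtalkError,
    UnknownGeneError,
    normalize_expression,
    permutation_null,
    rank_pairs,
    score_all,
    spatial_lr_score,
)
from spaxtalk.lr_scoring import LRScoreResult, SelfSelfError

from .conftest import random_cells, random_expression
from .oracles import bf_lr_score


def row(cid, x, y, t, fov="F0"):
    return {"cell_id": cid, "x_um": x, "y_um": y, "fov_id": fov, "cell_type": t}


def cells_from(rows):
    return CellTable(pd.DataFrame(rows))


def expr_from(cells, gene_values: dict[str, list[float]]):
    genes = list(gene_values)
    vals = np.column_stack([gene_values[g] for g in genes]).astype(float)
    return ExpressionMatrix(vals, pd.Index(genes), cells.cell_ids)


class TestNormalizeExpression:
    def test_already_at_scale_unchanged(self):
        cells = cells_from([row("c", 0, 0, "EC")])
        expr = expr_from(cells, {"g1": [2.0], "g2": [8.0]})
        out = normalize_expression(expr, scale=10)
        np.testing.assert_allclose(out.dense(), [[2.0, 8.0]])

    def test_zero_total_cell_left_as_zero_row(self):
        cells = cells_from([row("a", 0, 0, "EC"), row("b", 1, 1, "EC")])
        expr = expr_from(cells, {"g1": [0.0, 3.0], "g2": [0.0, 1.0]})
        out = normalize_expression(expr, scale=100)
        assert out.dense()[0].sum() == 0.0
        assert out.dense()[1].sum() == pytest.approx(100.0)

    def test_rows_sum_to_scale(self):
        cells = random_cells(80, seed=4)
        expr = random_expression(cells, [f"g{i}" for i in range(10)], seed=5)
        out = normalize_expression(expr, scale=1e4)
        np.testing.assert_allclose(out.row_totals(), 1e4, rtol=1e-9)


class TestSpatialLRScore:
    def test_zero_ligand_gives_zero_score(self):
        cells = cells_from([row("s", 0, 0, "S"), row("t", 5, 0, "T")])
        expr = expr_from(cells, {"L": [0.0, 9.0], "R": [4.0, 3.0]})
        assert spatial_lr_score(expr, cells, ("L", "R"), "S", "T") == 0.0

    def test_single_pair_kernel_cancels(self):
        # score = x_L * x_R regardless of the (finite) distance
        for d in (1.0, 37.5, 150.0):
            cells = cells_from([row("s", 0, 0, "S"), row("t", d, 0, "T")])
            expr = expr_from(cells, {"L": [2.0, 0.0], "R": [0.0, 3.0]})
            got = spatial_lr_score(expr, cells, ("L", "R"), "S", "T", bandwidth_um=20)
            assert got == pytest.approx(6.0, rel=1e-9)

    def test_self_self_direction_rejected(self):
        cells = cells_from([row("a", 0, 0, "S"), row("b", 1, 1, "S")])
        expr = expr_from(cells, {"L": [1, 1], "R": [1, 1]})
        with pytest.raises(SelfSelfError):
            spatial_lr_score(expr, cells, ("L", "R"), "S", "S")

    def test_missing_gene_error_names_gene(self):
        cells = cells_from([row("s", 0, 0, "S"), row("t", 1, 0, "T")])
        expr = expr_from(cells, {"L": [1, 1]})
        with pytest.raises(UnknownGeneError, match="NOPE"):
            spatial_lr_score(expr, cells, ("L", "NOPE"), "S", "T")

    def test_cross_fov_pairs_do_not_contribute(self):
        cells = cells_from([
            row("s", 0, 0, "S", fov="F0"), row("t", 1, 0, "T", fov="F1"),
        ])
        expr = expr_from(cells, {"L": [2, 0], "R": [0, 3]})
        assert np.isnan(spatial_lr_score(expr, cells, ("L", "R"), "S", "T"))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force(self, seed):
        cells = random_cells(200, seed=300 + seed, n_types=3)
        expr = random_expression(cells, ["L", "R", "other"], seed=400 + seed)
        got = spatial_lr_score(expr, cells, ("L", "R"), "T0", "T1", bandwidth_um=30)
        xl = dict(zip(cells.cell_ids, expr.gene_column("L")))
        xr = dict(zip(cells.cell_ids, expr.gene_column("R")))
        want = bf_lr_score(cells.df, xl, xr, "T0", "T1", 30)
        assert got == pytest.approx(want, rel=1e-10)

    def test_bilinear_in_ligand_expression(self):
        cells = random_cells(120, seed=8, n_types=2)
        expr = random_expression(cells, ["L", "R"], seed=9)
        base = spatial_lr_score(expr, cells, ("L", "R"), "T0", "T1")
        vals = expr.dense().copy()
        vals[cells.type_mask("T0"), 0] *= 2.0
        doubled = ExpressionMatrix(vals, expr.gene_names, expr.cell_ids)
        got = spatial_lr_score(doubled, cells, ("L", "R"), "T0", "T1")
        assert got == pytest.approx(2.0 * base, rel=1e-12)

    def test_invariant_to_cells_of_uninvolved_types(self):
        cells = random_cells(100, seed=10, n_types=2)
        expr = random_expression(cells, ["L", "R"], seed=11)
        base = spatial_lr_score(expr, cells, ("L", "R"), "T0", "T1")
        extra = pd.DataFrame([row(f"x{i}", i * 3.0, 50.0, "Bystander") for i in range(30)])
        bigger = CellTable(pd.concat([cells.df, extra], ignore_index=True))
        vals = np.vstack([expr.dense(), np.full((30, 2), 7.0)])
        bigger_expr = ExpressionMatrix(vals, expr.gene_names, bigger.cell_ids)
        got = spatial_lr_score(bigger_expr, bigger, ("L", "R"), "T0", "T1")
        assert got == pytest.approx(base, rel=1e-12)


class TestScoreAll:
    def test_combinatorial_entry_count_and_no_self_self(self):
        cells = random_cells(60, seed=12, n_types=3)
        expr = random_expression(cells, ["A", "B", "C", "D"], seed=13)
        pairs = LRPairTable.from_pairs([("A", "B"), ("C", "D")])
        res = score_all(expr, cells, pairs)
        assert len(res.table) == 3 * 2 * 2
        assert (res.table["source_type"] != res.table["target_type"]).all()

    def test_row_order_invariance(self):
        cells = random_cells(80, seed=14, n_types=3)
        expr = random_expression(cells, ["A", "B"], seed=15)
        pairs = LRPairTable.from_pairs([("A", "B")])
        res = score_all(expr, cells, pairs)
        perm = np.random.default_rng(1).permutation(cells.n_cells)
        cells2 = CellTable(cells.df.iloc[perm].reset_index(drop=True).copy())
        expr2 = ExpressionMatrix(
            expr.dense()[perm], expr.gene_names, cells.cell_ids[perm]
        ).align_to(cells2)
        res2 = score_all(expr2, cells2, pairs)
        key = ["source_type", "target_type", "pair_id"]
        a = res.table.set_index(key)["score"].sort_index()
        b = res2.table.set_index(key)["score"].sort_index()
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)

    def test_agrees_with_elementwise_scoring(self):
        cells = random_cells(100, seed=16, n_types=3)
        expr = random_expression(cells, ["A", "B", "C", "D"], seed=17)
        pairs = LRPairTable.from_pairs([("A", "B"), ("C", "D"), ("A", "D")])
        res = score_all(expr, cells, pairs, bandwidth_um=25)
        for _, r in res.table.iterrows():
            single = spatial_lr_score(
                expr, cells, (r["ligand"], r["receptor"]),
                r["source_type"], r["target_type"], bandwidth_um=25,
            )
            if np.isnan(single):
                assert np.isnan(r["score"])
            else:
                assert r["score"] == pytest.approx(single, rel=1e-10)

    def test_self_self_entries_cannot_be_constructed(self):
        bad = pd.DataFrame([
            {"source_type": "S", "target_type": "S", "pair_id": "A_B",
             "ligand": "A", "receptor": "B", "score": 1.0,
             "n_source": 1, "n_target": 1}
        ])
        with pytest.raises(SelfSelfError):
            LRScoreResult(bad, bandwidth_um=20)


class TestRankPairs:
    @staticmethod
    def _result(scores: dict[str, float]) -> LRScoreResult:
        rows = [
            {"source_type": "S", "target_type": "T", "pair_id": pid,
             "ligand": pid, "receptor": pid, "score": sc,
             "n_source": 5, "n_target": 5}
            for pid, sc in scores.items()
        ]
        return LRScoreResult(pd.DataFrame(rows), bandwidth_um=20)

    def test_ties_broken_lexicographically(self):
        res = self._result({"B": 1.0, "C": 3.0, "A": 3.0})
        ranked = rank_pairs(res, "S", "T", top_n=3)
        assert list(ranked["pair_id"]) == ["A", "C", "B"]

    def test_top_n_larger_than_available(self):
        res = self._result({"A": 2.0, "B": 1.0})
        assert len(rank_pairs(res, "S", "T", top_n=50)) == 2

    def test_random_scores_agree_with_sort_oracle(self):
        rng = np.random.default_rng(18)
        scores = {f"p{i:03d}": float(rng.choice([1.0, 2.0, 3.0, rng.random()]))
                  for i in range(40)}
        ranked = rank_pairs(self._result(scores), "S", "T", top_n=40)
        expected = [pid for pid, _ in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))]
        assert list(ranked["pair_id"]) == expected

    def test_unknown_direction_rejected(self):
        res = self._result({"A": 1.0})
        with pytest.raises(SpaxtalkError):
            rank_pairs(res, "T", "S")


class TestPermutationNull:
    def test_constant_expression_gives_p_one(self):
        # identical expression in every cell: label shuffles cannot change
        # the score, so every null draw equals the observed value
        cells = random_cells(60, seed=19, n_types=2)
        vals = np.full((cells.n_cells, 2), 3.0)
        expr = ExpressionMatrix(vals, pd.Index(["L", "R"]), cells.cell_ids)
        z, p = permutation_null(expr, cells, ("L", "R"), "T0", "T1", n_perm=49, seed=0)
        assert p == 1.0
        assert np.isnan(z)  # degenerate null SD

    def test_deterministic_given_seed(self):
        cells = random_cells(80, seed=20, n_types=2)
        expr = random_expression(cells, ["L", "R"], seed=21)
        a = permutation_null(expr, cells, ("L", "R"), "T0", "T1", n_perm=29, seed=7)
        b = permutation_null(expr, cells, ("L", "R"), "T0", "T1", n_perm=29, seed=7)
        assert a == b

    def test_too_few_permutations_rejected(self):
        cells = random_cells(20, seed=22, n_types=2)
        expr = random_expression(cells, ["L", "R"], seed=23)
        with pytest.raises(SpaxtalkError):
            permutation_null(expr, cells, ("L", "R"), "T0", "T1", n_perm=5)
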