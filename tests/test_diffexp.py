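"""Differential expression gates, preranked GSEA oracle, and the
hypergeometric over-representation test against exact enumeration."""

import math

import numpy as np
import pandas as pd
import pytest

from collangio.diffexp import (
    differential_expression,
    gsea_preranked,
    overrepresentation,
    signature_contrast_heatmap_stats,
)
from collangio.errors import ValidationError
from collangio.scoring import GeneSet


def make_expr(rows, samples):
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                        columns=samples)


class TestDifferentialExpression:
    def setup_method(self):
        self.a = [f"a{i}" for i in range(10)]
        self.b = [f"b{i}" for i in range(10)]

    def test_identical_gene_not_flagged(self):
        expr = make_expr([[5.0] * 20], self.a + self.b)
        deg = differential_expression(expr, self.a, self.b)
        assert not deg["flagged"].iloc[0]
        assert deg["p_value"].iloc[0] == 1.0

    def test_one_log2_unit_shift_flagged(self):
        rng = np.random.default_rng(0)
        vals = np.r_[np.full(10, 6.0), np.full(10, 5.0)] + rng.normal(0, 0.01, 20)
        deg = differential_expression(make_expr([vals], self.a + self.b),
                                      self.a, self.b)
        assert deg["fold_change"].iloc[0] == pytest.approx(2.0, rel=0.05)
        assert deg["flagged"].iloc[0]

    def test_small_fc_not_flagged_despite_tiny_p(self):
        rng = np.random.default_rng(1)
        delta = math.log2(1.4)
        vals = np.r_[np.full(10, 5 + delta), np.full(10, 5.0)]
        vals += rng.normal(0, 1e-4, 20)
        deg = differential_expression(make_expr([vals], self.a + self.b),
                                      self.a, self.b)
        assert deg["p_value"].iloc[0] < 1e-8
        assert not deg["flagged"].iloc[0]

    def test_flag_invariant_recomputable(self, small_bulk):
        expr, labels, _ = small_bulk
        ga = labels.index[labels == "armored_cold"].tolist()
        gb = labels.index[labels != "armored_cold"].tolist()
        deg = differential_expression(expr, ga, gb, direction="both")
        recomputed = (deg["p_value"] < 0.05) & (
            (deg["fold_change"] >= 1.5) | (deg["fold_change"] <= 1 / 1.5)
        )
        assert (deg["flagged"] == recomputed).all()
        assert np.allclose(deg["fold_change"],
                           np.exp2(deg["mean_a"] - deg["mean_b"]))

    def test_null_flag_rate_near_alpha(self, null_bulk):
        """Zero-effect cohort: fraction with p < 0.05 within 3 MC sd of 0.05."""
        expr, labels, _ = null_bulk
        half = expr.shape[1] // 2
        ga = list(expr.columns[:half])
        gb = list(expr.columns[half:])
        deg = differential_expression(expr, ga, gb, fc_threshold=1.0)
        rate = (deg["p_value"] < 0.05).mean()
        tol = 3 * np.sqrt(0.05 * 0.95 / expr.shape[0])
        assert abs(rate - 0.05) < tol

    def test_group_too_small(self):
        expr = make_expr([[1.0, 2.0, 3.0]], ["a0", "b0", "b1"])
        with pytest.raises(ValidationError):
            differential_expression(expr, ["a0"], ["b0", "b1"])


def gsea_hand_oracle(weights_desc, in_set_desc):
    """Position-by-position enumeration of the weighted KS running sum."""
    n = len(weights_desc)
    m = sum(in_set_desc)
    tot = sum(abs(w) for w, s in zip(weights_desc, in_set_desc) if s)
    hit = miss = 0.0
    best = 0.0
    for w, s in zip(weights_desc, in_set_desc):
        if s:
            hit += abs(w) / tot
        else:
            miss += 1.0 / (n - m)
        if abs(hit - miss) > abs(best):
            best = hit - miss
    return best


class TestGseaPreranked:
    def test_eight_gene_hand_enumeration(self):
        weights = [3.0, 2.5, 2.0, 1.0, -0.5, -1.0, -2.0, -3.0]
        genes = [f"g{i}" for i in range(8)]
        ranking = pd.Series(weights, index=genes)
        gs = GeneSet("S", ("g0", "g2", "g5"))
        res = gsea_preranked(ranking, gs, n_perm=100, seed=0)
        want = gsea_hand_oracle(weights, [g in gs.genes for g in genes])
        assert res.es == pytest.approx(want, abs=1e-12)

    def test_top_k_set_hits_permutation_floor(self):
        rng = np.random.default_rng(2)
        n = 300
        ranking = pd.Series(np.sort(rng.normal(size=n))[::-1],
                            index=[f"g{i}" for i in range(n)])
        gs = GeneSet("top", tuple(f"g{i}" for i in range(20)))
        res = gsea_preranked(ranking, gs, n_perm=1000, seed=1)
        assert res.es > 0
        # the floor is 1/(#same-sign nulls + 1); with ~half of 1000 nulls
        # positive it sits near 1/500
        assert res.p_value <= 0.005
        assert np.sign(res.nes) == np.sign(res.es)

    def test_leading_edge_subset_of_set(self):
        rng = np.random.default_rng(3)
        ranking = pd.Series(rng.normal(size=50),
                            index=[f"g{i}" for i in range(50)])
        gs = GeneSet("S", tuple(f"g{i}" for i in range(0, 50, 7)))
        res = gsea_preranked(ranking, gs, n_perm=100, seed=0)
        assert set(res.leading_edge) <= set(gs.genes)
        assert 1.0 / 101 <= res.p_value <= 1.0

    def test_random_sets_p_roughly_uniform(self):
        """Quick null sanity check; the full calibration runs in acceptance."""
        rng = np.random.default_rng(4)
        n = 200
        ranking = pd.Series(rng.normal(size=n),
                            index=[f"g{i}" for i in range(n)])
        ps = []
        for i in range(60):
            picked = rng.choice(ranking.index, size=15, replace=False)
            res = gsea_preranked(ranking, GeneSet(f"r{i}", tuple(picked)),
                                 n_perm=200, seed=i)
            ps.append(res.p_value)
        assert np.mean(np.array(ps) < 0.05) < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 60)


def hypergeom_tail_oracle(M, K, n, k):
    """Exact one-sided tail by direct combinatorial summation."""
    total = 0.0
    for kk in range(k, min(K, n) + 1):
        total += math.comb(K, kk) * math.comb(M - K, n - kk) / math.comb(M, n)
    return total


class TestOverrepresentation:
    def test_disjoint_hits(self):
        universe = {f"g{i}" for i in range(20)}
        gs = GeneSet("S", ("g0", "g1", "g2"))
        hits = {"g10", "g11"}
        _, p = overrepresentation(hits, universe, gs)
        assert p == pytest.approx(1.0)

    def test_degenerate_full_table(self):
        universe = {f"g{i}" for i in range(5)}
        gs = GeneSet("S", tuple(universe))
        _, p = overrepresentation(universe, universe, gs)
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_20_5_5_4(self):
        universe = {f"g{i}" for i in range(20)}
        gs = GeneSet("S", tuple(f"g{i}" for i in range(5)))
        hits = {"g0", "g1", "g2", "g3", "g10"}
        _, p = overrepresentation(hits, universe, gs)
        assert p == pytest.approx(hypergeom_tail_oracle(20, 5, 5, 4), abs=1e-12)

    @pytest.mark.parametrize("M,K,n,k", [(30, 10, 8, 5), (12, 4, 6, 2),
                                         (25, 12, 10, 10)])
    def test_matches_oracle_small_universes(self, M, K, n, k):
        universe = {f"g{i}" for i in range(M)}
        gs = GeneSet("S", tuple(f"g{i}" for i in range(K)))
        hits = {f"g{i}" for i in range(k)} | {f"g{K + i}" for i in range(n - k)}
        _, p = overrepresentation(hits, universe, gs)
        assert p == pytest.approx(hypergeom_tail_oracle(M, K, n, k), abs=1e-12)

    def test_empty_universe(self):
        with pytest.raises(ValidationError):
            overrepresentation(set(), set(), GeneSet("S", ("a",)))


class TestSignatureContrastHeatmap:
    def test_identical_groups_zero_difference(self, null_bulk):
        expr, _, blocks = null_bulk
        from collangio.synthetic import program_gene_sets

        # two "groups" that are literally the same samples, relabelled
        dup = pd.concat([expr, expr.add_suffix("_copy")], axis=1)
        groups = pd.Series(
            ["A"] * expr.shape[1] + ["B"] * expr.shape[1], index=dup.columns
        )
        table = signature_contrast_heatmap_stats(
            dup, groups, program_gene_sets(blocks)[:2]
        )
        assert np.allclose(table["A"], table["B"])

    def test_planted_collagen_shift_ranks_first(self, small_bulk):
        expr, labels, blocks = small_bulk
        from collangio.synthetic import program_gene_sets

        table = signature_contrast_heatmap_stats(
            expr, labels, program_gene_sets(blocks)
        )
        diff = (table["armored_cold"] - table["quiescent"]).abs()
        assert diff.idxmax() == "COLLAGEN_PROGRAM" or \
            table.loc["COLLAGEN_PROGRAM", "armored_cold"] > \
            table.loc["COLLAGEN_PROGRAM", "quiescent"]

    def test_single_signature_single_group(self, small_bulk):
        expr, _, blocks = small_bulk
        from collangio.scoring import ssgsea_score
        from collangio.synthetic import program_gene_sets

        gs = program_gene_sets(blocks)[0]
        groups = pd.Series("all", index=expr.columns)
        table = signature_contrast_heatmap_stats(expr, groups, [gs])
        assert table.loc[gs.name, "all"] == pytest.approx(
            ssgsea_score(expr, gs).mean()
        )
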