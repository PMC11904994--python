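"""Signature scoring: running-sum oracle, rank invariance, deconvolution and
the composite angiogenesis score."""

import numpy as np
import pandas as pd
import pytest

from collangio.errors import ScoringError, UndefinedStatisticError, ValidationError
from collangio.scoring import (
    GeneSet,
    ReferenceProfiles,
    angiogenesis_composite,
    correlate,
    deconvolve_endothelial,
    deconvolve_fractions,
    ssgsea_score,
)


def brute_force_running_sum(values, set_genes, gene_ids, alpha):
    """Independent position-by-position enumeration of the score."""
    G = len(values)
    order = sorted(range(G), key=lambda i: -values[i])
    # average descending ranks
    ranks = {}
    by_val = {}
    for i, v in enumerate(values):
        by_val.setdefault(v, []).append(i)
    pos = 1
    for v in sorted(by_val, reverse=True):
        idxs = by_val[v]
        avg = sum(range(pos, pos + len(idxs))) / len(idxs)
        for i in idxs:
            ranks[i] = avg
        pos += len(idxs)
    in_set = [gene_ids[i] in set_genes for i in range(G)]
    m = sum(in_set)
    w = {i: (G - ranks[i] + 1) ** alpha for i in range(G)}
    w_total = sum(w[i] for i in range(G) if in_set[i])
    hit = miss = score = 0.0
    for i in order:
        if in_set[i]:
            hit += w[i] / w_total
        else:
            miss += 1.0 / (G - m)
        score += hit - miss
    return score


class TestSsgsea:
    def test_five_gene_oracle(self):
        """5 genes, expression (5,4,3,2,1), set = top 2, alpha 0.25."""
        genes = [f"g{i}" for i in range(5)]
        expr = pd.DataFrame({"s": [5.0, 4.0, 3.0, 2.0, 1.0]}, index=genes)
        got = ssgsea_score(expr, GeneSet("top2", ("g0", "g1")), alpha=0.25)["s"]
        want = brute_force_running_sum([5, 4, 3, 2, 1], {"g0", "g1"}, genes, 0.25)
        assert got == pytest.approx(want, abs=1e-12)
        # closed form for this instance: 5^0.25/(5^0.25+4^0.25) + 2
        closed = 5**0.25 / (5**0.25 + 4**0.25) + 2.0
        assert got == pytest.approx(closed, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        vals = rng.normal(size=30)
        vals[5] = vals[7]  # force a tie
        expr = pd.DataFrame({"s": vals}, index=genes)
        picked = set(rng.choice(genes, size=8, replace=False))
        got = ssgsea_score(expr, GeneSet("S", tuple(sorted(picked))), alpha=0.25)["s"]
        want = brute_force_running_sum(list(vals), picked, genes, 0.25)
        assert got == pytest.approx(want, abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(40)]
        expr = pd.DataFrame(rng.normal(size=(40, 3)), index=genes,
                            columns=["a", "b", "c"])
        gs = GeneSet("S", tuple(genes[::5]))
        base = ssgsea_score(expr, gs)
        for f in (np.exp, lambda x: 3 * x + 7, lambda x: x**3):
            assert np.allclose(ssgsea_score(f(expr), gs), base)

    def test_gene_order_permutation_invariance(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(25)]
        expr = pd.DataFrame(rng.normal(size=(25, 2)), index=genes,
                            columns=["a", "b"])
        gs = GeneSet("S", ("g1", "g4", "g9"))
        shuffled = expr.sample(frac=1.0, random_state=1)
        assert np.allclose(ssgsea_score(expr, gs), ssgsea_score(shuffled, gs))

    def test_top_gene_beats_bottom_gene(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(20)]
        expr = pd.DataFrame(rng.normal(size=(20, 4)), index=genes,
                            columns=list("wxyz"))
        for s in expr.columns:
            top = expr[s].idxmax()
            bot = expr[s].idxmin()
            hi = ssgsea_score(expr, GeneSet("hi", (top,)), min_overlap=1)[s]
            lo = ssgsea_score(expr, GeneSet("lo", (bot,)), min_overlap=1)[s]
            assert hi > lo

    def test_insufficient_overlap_names_set(self):
        expr = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ScoringError, match="MISSING"):
            ssgsea_score(expr, GeneSet("MISSING", ("x", "y")))


@pytest.fixture()
def three_type_ref():
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(30)]
    prof = pd.DataFrame(
        rng.uniform(1, 50, size=(30, 3)),
        index=genes,
        columns=["endothelial", "fibroblast", "immune"],
    )
    return ReferenceProfiles(prof, min_overlap=5)


class TestDeconvolution:
    def test_pure_endothelial_sample(self, three_type_ref):
        b = three_type_ref.profiles["endothelial"]
        expr = pd.DataFrame({"s": b})
        frac = deconvolve_endothelial(expr, three_type_ref, log2_input=False)
        assert frac["s"] == pytest.approx(1.0, abs=1e-6)

    def test_noise_free_mixture(self, three_type_ref):
        p = three_type_ref.profiles
        b = 0.3 * p["endothelial"] + 0.7 * p["fibroblast"]
        expr = pd.DataFrame({"s": b})
        frac = deconvolve_fractions(expr, three_type_ref, log2_input=False)
        assert frac.loc["s", "endothelial"] == pytest.approx(0.3, abs=1e-4)
        assert frac.loc["s", "fibroblast"] == pytest.approx(0.7, abs=1e-4)
        # grid-search oracle over the endothelial/fibroblast face at step 1e-3
        R = p[["endothelial", "fibroblast"]].to_numpy()
        grid = np.arange(0, 1.0 + 1e-9, 1e-3)
        best = min(
            grid,
            key=lambda f: float(
                np.sum((R @ np.array([f, min(1 - f, 1.0)]) - b.to_numpy()) ** 2)
            ),
        )
        assert abs(best - 0.3) <= 1e-3
        assert frac.loc["s", "endothelial"] == pytest.approx(best, abs=2e-3)

    def test_zero_sample_gives_zero_fraction(self, three_type_ref):
        expr = pd.DataFrame({"s": np.zeros(30)},
                            index=three_type_ref.profiles.index)
        frac = deconvolve_fractions(expr, three_type_ref, log2_input=False)
        assert np.all(np.abs(frac.to_numpy()) < 1e-6)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_never_beaten_by_coarse_grid(self, three_type_ref, seed):
        """Implementation objective <= best objective on a 3-type grid."""
        rng = np.random.default_rng(seed)
        b = rng.uniform(0, 60, size=30)
        expr = pd.DataFrame({"s": b}, index=three_type_ref.profiles.index)
        frac = deconvolve_fractions(expr, three_type_ref, log2_input=False)
        R = three_type_ref.profiles.to_numpy()
        obj_impl = np.sum((R @ frac.loc["s"].to_numpy() - b) ** 2)
        step = 0.01
        fs = np.arange(0, 1 + 1e-9, step)
        best = np.inf
        for f1 in fs:
            for f2 in fs:
                if f1 + f2 > 1:
                    break
                f3s = fs[fs <= 1 - f1 - f2 + 1e-9]
                cand = R @ np.vstack(
                    [np.full(len(f3s), f1), np.full(len(f3s), f2), f3s]
                )
                best = min(best, float(((cand - b[:, None]) ** 2).sum(axis=0).min()))
        assert obj_impl <= best + 1e-6
        assert (frac.to_numpy() >= 0).all() and frac.to_numpy().sum() <= 1 + 1e-9

    def test_insufficient_overlap_errors(self, three_type_ref):
        expr = pd.DataFrame({"s": [1.0, 2.0]}, index=["g0", "g1"])
        with pytest.raises(ScoringError):
            deconvolve_fractions(expr, three_type_ref)


class TestComposite:
    def test_equal_features_no_standardize(self):
        feats = pd.DataFrame(
            {f"f{i}": [2.5, -1.0, 0.0] for i in range(6)},
            index=["a", "b", "c"],
        )
        score = angiogenesis_composite(feats, standardize=False)
        assert np.allclose(score, [2.5, -1.0, 0.0])

    def test_standardized_scores_have_mean_zero(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame(rng.normal(size=(10, 6)),
                             columns=[f"f{i}" for i in range(6)])
        score = angiogenesis_composite(feats, standardize=True)
        assert score.mean() == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_table(self):
        """3 samples x 2 features; z-score (ddof=1) then average, by hand."""
        feats = pd.DataFrame({"f1": [1.0, 2.0, 3.0], "f2": [10.0, 30.0, 20.0]},
                             index=["a", "b", "c"])
        import statistics

        cols = []
        for c in feats:
            mu = statistics.mean(feats[c])
            sd = statistics.stdev(feats[c])
            cols.append([(v - mu) / sd for v in feats[c]])
        want = [(cols[0][i] + cols[1][i]) / 2 for i in range(3)]
        got = angiogenesis_composite(feats, standardize=True)
        assert np.allclose(got, want)

    def test_constant_feature_dropped_with_warning(self):
        feats = pd.DataFrame({"f1": [1.0, 2.0, 3.0], "f2": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            score = angiogenesis_composite(feats, standardize=True)
        only_f1 = angiogenesis_composite(feats[["f1"]], standardize=True)
        assert np.allclose(score, only_f1)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        feats = pd.DataFrame(rng.normal(size=(8, 6)),
                             index=[f"s{i}" for i in range(8)])
        perm = rng.permutation(8)
        direct = angiogenesis_composite(feats.iloc[perm])
        assert np.allclose(direct, angiogenesis_composite(feats).iloc[perm])


class TestCorrelate:
    def test_affine_dependence(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x + 1, method="pearson")
        assert r == pytest.approx(1.0)

    def test_reversed_ranks(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, _ = correlate(x, x[::-1], method="spearman")
        assert r == pytest.approx(-1.0)

    def test_covariance_formula_oracle(self):
        x = [2.0, 4.0, 1.0, 7.0, 5.0]
        y = [3.0, 9.0, 2.0, 8.0, 4.0]
        n = 5
        mx, my = sum(x) / n, sum(y) / n
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
        vx = sum((a - mx) ** 2 for a in x)
        vy = sum((b - my) ** 2 for b in y)
        want = cov / (vx * vy) ** 0.5
        r, _ = correlate(x, y, method="pearson")
        assert r == pytest.approx(want, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short(self):
        with pytest.raises(ValidationError):
            correlate([1.0, 2.0], [3.0, 4.0])
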