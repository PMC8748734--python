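"""Diversity and group-difference statistics against hand-computed and
independent library oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from subshelf import ecology as eco
from subshelf.errors import ConfigError, NormalizationError


def table_from(arr, taxa=None, samples=None):
    arr = np.asarray(arr)
    taxa = taxa or [f"t{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=taxa, columns=samples)


# ---------------------------------------------------------------------------
# brute-force oracles (independent, loop-based)


def brute_bray_curtis(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def brute_indval_stats(x, labels, levels):
    """Loop-based group-equalized IndVal per taxon (max over groups)."""
    stats = []
    for t in range(x.shape[0]):
        means, pres = [], []
        for g in levels:
            cols = [j for j, lab in enumerate(labels) if lab == g]
            means.append(sum(x[t, j] for j in cols) / len(cols))
            pres.append(sum(1 for j in cols if x[t, j] > 0) / len(cols))
        total = sum(means)
        best = 0.0
        for m, b in zip(means, pres):
            a = m / total if total > 0 else 0.0
            best = max(best, math.sqrt(a * b))
        stats.append(best)
    return np.array(stats)


def brute_indval_exact_p(x, labels):
    levels = sorted(set(labels))
    obs = brute_indval_stats(x, labels, levels)
    perms = sorted(set(itertools.permutations(labels)))
    counts = np.zeros(x.shape[0])
    for perm in perms:
        stat = brute_indval_stats(x, perm, levels)
        counts += stat >= obs - 1e-9
    return counts / len(perms)


def brute_permanova_f(d, labels):
    levels = sorted(set(labels))
    n = len(labels)
    ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in levels:
        idx = [i for i, lab in enumerate(labels) if lab == g]
        ss_w += sum(
            d[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    k = len(levels)
    return ((ss_t - ss_w) / (k - 1)) / (ss_w / (n - k))


def brute_permanova_exact_p(d, labels):
    obs = brute_permanova_f(d, labels)
    perms = sorted(set(itertools.permutations(labels)))
    count = sum(brute_permanova_f(d, p) >= obs - 1e-9 for p in perms)
    return count / len(perms)


# ---------------------------------------------------------------------------


class TestRarefy:
    def test_column_sums_exact(self, rng):
        table = table_from(rng.integers(0, 200, (30, 4)))
        out = eco.rarefy(table, depth=100, seed=0)
        assert (out.sum(axis=0) == 100).all()

    def test_full_depth_preserves_counts(self, rng):
        table = table_from(rng.integers(0, 50, (10, 2)))
        depth = int(table["s0"].sum())
        out = eco.rarefy(table[["s0"]], depth=depth, seed=1)
        pd.testing.assert_series_equal(out["s0"], table["s0"], check_dtype=False)

    def test_depth_one(self, rng):
        table = table_from(rng.integers(1, 50, (10, 3)))
        out = eco.rarefy(table, depth=1, seed=2)
        assert ((out > 0).sum(axis=0) == 1).all()
        assert (out.sum(axis=0) == 1).all()

    def test_shallow_samples_dropped(self):
        table = table_from([[100, 3], [100, 2]])
        with pytest.warns(UserWarning, match="dropped"):
            out = eco.rarefy(table, depth=50, seed=0)
        assert list(out.columns) == ["s0"]

    def test_default_depth(self):
        import inspect

        assert inspect.signature(eco.rarefy).parameters["depth"].default == 15_400

    def test_invalid_depth(self):
        with pytest.raises(ConfigError):
            eco.rarefy(table_from([[1]]), depth=0)


class TestChao1:
    def test_no_singletons(self):
        s, est = eco.chao1([5, 3, 2, 8])
        assert (s, est) == (4, 4.0)

    def test_closed_form(self):
        # S_obs 5, two singletons, one doubleton -> 5 + 2*1/(2*2) = 5.5
        s, est = eco.chao1([1, 1, 2, 3, 4])
        assert s == 5
        assert est == pytest.approx(5.5)

    def test_all_zero(self):
        assert eco.chao1([0, 0, 0]) == (0, 0.0)

    def test_non_integer_rejected(self):
        with pytest.raises(ConfigError):
            eco.chao1([1.5, 2.0])


class TestBrayCurtis:
    def test_identity_disjoint_and_hand_value(self):
        table = table_from([[2, 1, 2, 0], [2, 1, 0, 3]], samples=list("wxyz"))
        bc = eco.bray_curtis(table)
        assert bc.loc["w", "w"] == 0.0
        assert bc.loc["y", "z"] == 1.0  # disjoint supports
        assert bc.loc["w", "x"] == pytest.approx(1 / 3)  # (2,2) vs (1,1)

    def test_against_scikit_bio(self, rng):
        from skbio.diversity import beta_diversity

        table = table_from(rng.integers(0, 100, (25, 6)))
        ours = eco.bray_curtis(table)
        ref = beta_diversity(
            "braycurtis", table.T.to_numpy(), ids=list(table.columns)
        )
        np.testing.assert_allclose(ours.to_numpy(), ref.data, atol=1e-12)

    def test_two_all_zero_samples_rejected(self):
        table = table_from([[0, 0, 1], [0, 0, 2]])
        with pytest.raises(NormalizationError):
            eco.bray_curtis(table)

    @given(hnp.arrays(np.float64, (5, 4), elements=st.floats(0, 100)).filter(
        lambda a: (a.sum(axis=0) > 0).all()))
    @settings(max_examples=50, deadline=None)
    def test_axioms(self, arr):
        bc = eco.bray_curtis(table_from(arr)).to_numpy()
        assert np.allclose(bc, bc.T)
        assert np.allclose(np.diag(bc), 0)
        assert (bc >= -1e-12).all() and (bc <= 1 + 1e-12).all()


class TestUpgma:
    def test_two_samples(self):
        d = pd.DataFrame([[0, 0.4], [0.4, 0]], index=list("ab"), columns=list("ab"))
        tree = eco.upgma(d)
        assert tree.linkage.shape == (1, 4)
        assert tree.heights[0] == pytest.approx(0.4)

    def test_three_sample_hand_merge(self):
        d = pd.DataFrame(
            [[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]],
            index=list("abc"), columns=list("abc"),
        )
        tree = eco.upgma(d)
        np.testing.assert_allclose(tree.heights, [0.1, 0.5])
        # newick: c joins the (a,b) cluster at 0.5
        assert "c:0.5" in tree.newick()

    def test_matches_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        x = rng.random((8, 8))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        frame = pd.DataFrame(d, index=list("abcdefgh"), columns=list("abcdefgh"))
        ours = eco.upgma(frame)
        ref = linkage(squareform(d), method="average")
        np.testing.assert_allclose(np.sort(ours.heights), np.sort(ref[:, 2]),
                                   atol=1e-12)

    def test_ultrametric_fixed_point(self):
        # ultrametric 4-point matrix: heights reproduce input levels
        d = np.array(
            [
                [0.0, 0.2, 0.6, 0.6],
                [0.2, 0.0, 0.6, 0.6],
                [0.6, 0.6, 0.0, 0.3],
                [0.6, 0.6, 0.3, 0.0],
            ]
        )
        tree = eco.upgma(pd.DataFrame(d, index=list("abcd"), columns=list("abcd")))
        np.testing.assert_allclose(np.sort(tree.heights), [0.2, 0.3, 0.6])

    def test_newick_is_ultrametric_and_parseable(self, rng):
        import io as _io

        from skbio import TreeNode

        x = rng.random((6, 6))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        frame = pd.DataFrame(d, index=[f"s{i}" for i in range(6)],
                             columns=[f"s{i}" for i in range(6)])
        tree = eco.upgma(frame)
        parsed = TreeNode.read(_io.StringIO(tree.newick()))
        depths = {tip.name: tip.accumulate_to_ancestor(parsed) for tip in parsed.tips()}
        root_height = tree.heights.max()
        for name, depth in depths.items():
            assert depth == pytest.approx(root_height, abs=1e-9)

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0, 0.1], [0.2, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ConfigError):
            eco.upgma(d)


class TestRowZscores:
    def test_hand_row(self):
        z = eco.row_zscores(table_from([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z.to_numpy()[0], [-1, 0, 1])

    def test_constant_row_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            z = eco.row_zscores(table_from([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        assert (z.iloc[0] == 0).all()

    def test_output_standardized(self, rng):
        z = eco.row_zscores(table_from(rng.random((10, 6))))
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_single_column_rejected(self):
        with pytest.raises(ConfigError):
            eco.row_zscores(table_from([[1.0]]))


class TestKruskalWallis:
    def test_separated_ranks_brute_force(self):
        # groups {1,2,3} vs {10,20,30}: rank sums 6 and 15
        h, p = eco.kruskal_wallis([1, 2, 3, 10, 20, 30], list("aaabbb"))
        expected = 12 / (6 * 7) * (36 / 3 + 225 / 3) - 3 * 7
        assert h == pytest.approx(expected)

    def test_against_scipy_with_ties(self, rng):
        from scipy import stats as sps

        vals = rng.integers(0, 5, 30).astype(float)  # heavy ties
        groups = np.repeat(list("abc"), 10)
        h, p = eco.kruskal_wallis(vals, groups)
        ref = sps.kruskal(*(vals[groups == g] for g in "abc"))
        assert h == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_all_tied(self):
        h, p = eco.kruskal_wallis([3, 3, 3, 3], list("aabb"))
        assert h == 0.0

    def test_single_group_rejected(self):
        with pytest.raises(ConfigError):
            eco.kruskal_wallis([1, 2], ["a", "a"])


class TestPermanova:
    def _clustered(self, rng, n_per=4, shift=10.0):
        a = rng.random((6, n_per))
        b = rng.random((6, n_per)) + shift
        table = table_from(np.hstack([a, b]))
        groups = ["g1"] * n_per + ["g2"] * n_per
        return eco.bray_curtis(table), groups

    def test_statistic_matches_scikit_bio(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        table = table_from(rng.integers(1, 100, (12, 9)))
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        d = eco.bray_curtis(table)
        ours = eco.permanova(d, groups, n_permutations=99, seed=0)
        ref = sk_permanova(DistanceMatrix(d.to_numpy(), ids=list(d.columns)),
                           grouping=groups, permutations=99)
        assert ours.statistic == pytest.approx(ref["test statistic"])

    def test_exact_enumeration_matches_brute_force(self, rng):
        table = table_from(rng.integers(0, 20, (5, 6)))
        groups = ["a", "a", "a", "b", "b", "b"]
        d = eco.bray_curtis(table)
        res = eco.permanova(d, groups, n_permutations="exact")
        assert res.p_value == pytest.approx(
            brute_permanova_exact_p(d.to_numpy(), groups)
        )
        assert res.method == "exact"

    def test_separated_clusters_minimal_p(self, rng):
        d, groups = self._clustered(rng)
        res = eco.permanova(d, groups, n_permutations=999, seed=42)
        # every permutation that reproduces the split ties with the observed F
        labelings = eco._random_labelings(
            np.array([0] * 4 + [1] * 4), 999, np.random.default_rng(42)
        )
        base = np.array([0] * 4 + [1] * 4)
        n_tied = int(
            np.sum((labelings == base).all(axis=1) | (labelings == 1 - base).all(axis=1))
        )
        assert res.p_value == pytest.approx((n_tied + 1) / 1000)

    def test_single_sample_group_warns(self, rng):
        table = table_from(rng.integers(1, 9, (4, 5)))
        d = eco.bray_curtis(table)
        with pytest.warns(UserWarning, match="single sample"):
            eco.permanova(d, ["a", "a", "a", "a", "b"], n_permutations=9, seed=0)


class TestIndval:
    def test_perfect_indicator(self):
        table = table_from([[5, 5, 5, 0, 0, 0]])
        res = eco.indval(table, ["g1"] * 3 + ["g2"] * 3, n_permutations=99, seed=0)
        row = res.iloc[0]
        assert row["A"] == 1.0 and row["B"] == 1.0 and row["stat"] == 1.0
        assert row["best_group"] == "g1"

    def test_equal_means_everywhere(self):
        table = table_from([[4, 4, 4, 4]])
        res = eco.indval(table, ["g1", "g1", "g2", "g2"], n_permutations=99, seed=0)
        row = res.iloc[0]
        assert row["A"] == pytest.approx(0.5)
        assert row["B"] == 1.0
        assert row["stat"] == pytest.approx(math.sqrt(0.5))

    def test_exact_enumeration_matches_brute_force(self, rng):
        x = rng.integers(0, 7, (5, 4))
        table = table_from(x)
        groups = ["a", "a", "b", "b"]
        res = eco.indval(table, groups, n_permutations="exact")
        expected = brute_indval_exact_p(x.astype(float), groups)
        np.testing.assert_allclose(res["p_value"].to_numpy(), expected)

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigError):
            eco.indval(table_from([[1, 2]]), ["a", "a"])

    def test_classic_variant_weights_group_sizes(self):
        # unbalanced design: one group of 1 site, one of 3; classic IndVal
        # weights by totals, group-equalized by means
        table = table_from([[9, 3, 3, 3]])
        groups = ["g1", "g2", "g2", "g2"]
        eq = eco.indval(table, groups, n_permutations=9, seed=0,
                        group_equalized=True).iloc[0]
        cl = eco.indval(table, groups, n_permutations=9, seed=0,
                        group_equalized=False).iloc[0]
        assert eq["A"] == pytest.approx(9 / 12)  # means 9 vs 3
        assert cl["A"] == pytest.approx(0.5)  # totals 9 vs 9


class TestSignatureShare:
    def _fixture(self):
        # 4+4 sites; t1/t2 perfect indicators, t3/t4 uniform background
        counts = np.array(
            [
                [10, 10, 10, 10, 0, 0, 0, 0],
                [0, 0, 0, 0, 6, 6, 6, 6],
                [5, 5, 5, 5, 5, 5, 5, 5],
                [8, 8, 8, 8, 8, 8, 8, 8],
            ],
            dtype=float,
        )
        groups = ["g1"] * 4 + ["g2"] * 4
        return table_from(counts), groups

    def test_planted_indicators_recovered_exactly(self):
        table, groups = self._fixture()
        res = eco.indval(table, groups, n_permutations="exact")
        # perfect splits: only 2 of the 70 distinct labelings reach stat 1
        assert res.loc["t0", "p_value"] == pytest.approx(2 / 70)
        assert res.loc["t2", "p_value"] == 1.0  # constant taxon
        rel = table / table.sum(axis=0)
        share = eco.signature_share(rel, res, groups=groups)
        expected = (table.loc[["t0", "t1"]] / table.sum(axis=0)).sum(axis=0)
        pd.testing.assert_series_equal(share.per_sample, expected)

    def test_no_taxa_pass(self):
        table, groups = self._fixture()
        res = eco.indval(table, groups, n_permutations="exact")
        rel = table / table.sum(axis=0)
        share = eco.signature_share(rel, res, p_max=1e-9)
        assert (share.per_sample == 0).all()

    def test_all_taxa_pass(self):
        table, groups = self._fixture()
        res = eco.indval(table, groups, n_permutations="exact")
        rel = table / table.sum(axis=0)
        share = eco.signature_share(rel, res, p_max=1.1, stat_min=0.0)
        np.testing.assert_allclose(share.per_sample, 1.0)


class TestSimper:
    def test_single_differing_taxon(self):
        table = table_from([[5, 5, 0, 0], [3, 3, 3, 3]])
        out = eco.simper(table, ["a", "a", "b", "b"])
        assert out.loc["t0", "pct"] == pytest.approx(100.0)

    def test_decomposition_identity(self, rng):
        table = table_from(rng.integers(1, 50, (12, 6)))
        groups = ["a"] * 3 + ["b"] * 3
        out = eco.simper(table, groups)
        bc = eco.bray_curtis(table)
        between = [
            bc.iloc[i, j] for i in range(3) for j in range(3, 6)
        ]
        assert out["contribution"].sum() == pytest.approx(np.mean(between), abs=1e-9)

    def test_two_by_two_hand_expansion(self):
        table = table_from([[4, 2, 1, 0], [0, 2, 3, 4]], samples=list("wxyz"))
        out = eco.simper(table, ["a", "a", "b", "b"])
        # pairs (w,y),(w,z),(x,y),(x,z): |xi-yi|/sum per pair, averaged
        t0 = np.mean([3 / 8, 4 / 8, 1 / 8, 2 / 8])
        t1 = np.mean([3 / 8, 4 / 8, 1 / 8, 2 / 8])
        assert out.loc["t0", "contribution"] == pytest.approx(t0)
        assert out.loc["t1", "contribution"] == pytest.approx(t1)


class TestFilterMinCount:
    def test_strict_threshold_all_samples(self):
        table = table_from([[5, 5], [4, 10], [9, 9]])
        out = eco.filter_min_count(table, min_reads=4)
        assert list(out.index) == ["t0", "t2"]
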