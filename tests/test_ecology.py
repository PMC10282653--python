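"""Alpha/beta diversity, ordination and PERMANOVA, cross-checked against
scikit-bio where it implements the same quantity."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import skbio
from skbio.diversity import alpha as skbio_alpha
from scipy.spatial.distance import pdist, squareform

from conftest import make_table
from twobrad.ecology import (
    DistanceMatrix,
    beta_distance,
    chao1,
    compare_alpha,
    pcoa,
    permanova,
    shannon,
    simpson,
)


class TestAlphaClosedForms:
    @pytest.mark.parametrize(
        "counts,expected",
        [((5, 5, 5), 3.0), ((1, 1, 2, 2, 5), 5 + 2 * 1 / (2 * 3)), ((0, 0, 0), 0.0)],
    )
    def test_chao1(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    def test_chao1_classic_form_diverges_without_doubletons(self):
        assert chao1((1, 1, 3), bias_corrected=False) == math.inf
        assert chao1((1, 1, 2, 3), bias_corrected=False) == pytest.approx(3 + 4 / 2 + 1)

    @pytest.mark.parametrize(
        "p,expected",
        [([0.25] * 4, math.log(4)), ([1.0], 0.0),
         ([0.5, 0.25, 0.25], 1.5 * math.log(2))],
    )
    def test_shannon(self, p, expected):
        assert shannon(p) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "p,expected",
        [([1.0], 0.0), ([0.2] * 5, 1 - 1 / 5), ([0.5, 0.5], 0.5)],
    )
    def test_simpson(self, p, expected):
        assert simpson(p) == pytest.approx(expected)


def test_alpha_metrics_match_skbio_on_random_counts():
    rng = np.random.default_rng(11)
    for _ in range(25):
        counts = rng.integers(0, 20, size=30)
        if counts.sum() == 0:
            continue
        assert chao1(counts) == pytest.approx(
            skbio_alpha.chao1(counts, bias_corrected=True)
        )
        p = counts / counts.sum()
        assert shannon(p) == pytest.approx(skbio_alpha.shannon(counts, base=math.e))
        assert simpson(p) == pytest.approx(skbio_alpha.simpson(counts))


def test_chao1_at_least_observed_richness():
    rng = np.random.default_rng(5)
    for _ in range(50):
        counts = rng.integers(0, 4, size=25)
        S = (counts > 0).sum()
        est = chao1(counts)
        assert est >= S
        F1 = (counts == 1).sum()
        assert (est == S) == (F1 <= 1)


def test_shannon_maximal_at_uniform_simpson_bounded():
    rng = np.random.default_rng(6)
    for n in (2, 5, 9):
        for _ in range(10):
            p = rng.dirichlet(np.ones(n))
            assert shannon(p) <= math.log(n) + 1e-12
            assert 0 <= simpson(p) <= 1 - 1 / n + 1e-12
        assert shannon(np.full(n, 1 / n)) == pytest.approx(math.log(n))


class TestCompareAlpha:
    def test_identical_groups_give_p_one(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["a"] * 3 + ["b"] * 3
        assert compare_alpha(values, groups) == pytest.approx(1.0)

    def test_fully_separated_3v3_exact_p(self):
        # 2 / C(6,3) = 0.1 under the exact two-sided rank-sum null
        values = [1, 2, 3, 10, 11, 12]
        groups = ["a"] * 3 + ["b"] * 3
        assert compare_alpha(values, groups) == pytest.approx(0.1)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=12)
        groups = ["a"] * 5 + ["b"] * 7
        p1 = compare_alpha(values, groups)
        p2 = compare_alpha(np.exp(values), groups)
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_alpha([1.0, 2.0], ["a", "a"])


class TestBetaDistance:
    def test_identical_samples_all_metrics_zero(self):
        table = make_table(np.tile([0.2, 0.3, 0.5], (2, 1)), ["a", "b"])
        for metric in ("bray_curtis", "binary_jaccard", "euclidean"):
            assert beta_distance(table, metric).data[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_saturate(self):
        table = make_table([[1, 1, 0, 0], [0, 0, 1, 1]], ["a", "b"])
        assert beta_distance(table, "bray_curtis").data[0, 1] == pytest.approx(1.0)
        assert beta_distance(table, "binary_jaccard").data[0, 1] == pytest.approx(1.0)

    def test_hand_worked_example(self):
        table = make_table([[0.5, 0.5, 0.0], [0.5, 0.0, 0.5]], ["a", "b"])
        assert beta_distance(table, "bray_curtis").data[0, 1] == pytest.approx(0.5)
        assert beta_distance(table, "binary_jaccard").data[0, 1] == pytest.approx(2 / 3)
        assert beta_distance(table, "euclidean").data[0, 1] == pytest.approx(
            math.sqrt(0.5)
        )

    def test_unknown_metric_rejected(self, two_group_table):
        with pytest.raises(ValueError, match="unknown metric"):
            beta_distance(two_group_table, "unifrac")

    def test_matches_skbio_beta_diversity(self, two_group_table):
        from skbio.diversity import beta_diversity

        X = two_group_table.values.to_numpy()
        got = beta_distance(two_group_table, "bray_curtis").data
        want = beta_diversity("braycurtis", X).data
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_bounds_symmetry_zero_diagonal(self, two_group_table):
        for metric in ("bray_curtis", "binary_jaccard"):
            d = beta_distance(two_group_table, metric).data
            assert ((d >= 0) & (d <= 1)).all()
            np.testing.assert_allclose(d, d.T)
            np.testing.assert_allclose(np.diag(d), 0)


class TestPCoA:
    def test_euclidean_configuration_recovered(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(7, 2))
        D = squareform(pdist(pts))
        dm = DistanceMatrix([f"s{i}" for i in range(7)], D, "euclidean")
        coords, eigvals = pcoa(dm, k=2)
        D2 = squareform(pdist(coords.to_numpy()))
        np.testing.assert_allclose(D2, D, atol=1e-8)
        assert np.all(np.diff(eigvals) <= 1e-9)

    def test_collinear_points_have_one_positive_eigenvalue(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        D = squareform(pdist(pts))
        dm = DistanceMatrix(["a", "b", "c"], D, "euclidean")
        coords, eigvals = pcoa(dm, k=2)
        assert (eigvals > 1e-10).sum() == 1
        assert coords.shape[1] == 1  # axes only for positive eigenvalues

    def test_eigenvalues_match_skbio(self, two_group_table):
        dm = beta_distance(two_group_table, "bray_curtis")
        _, eigvals = pcoa(dm, k=3)
        sk = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.data, list(dm.ids)), method="eigh",
            number_of_dimensions=len(dm.ids),
        )
        # skbio clamps negative eigenvalues to zero; compare the positive part
        mine = eigvals[eigvals > 1e-10]
        theirs = np.sort(np.asarray(sk.eigvals))[::-1][: len(mine)]
        np.testing.assert_allclose(mine, theirs, atol=1e-8)


class TestPermanova:
    def test_two_tight_clusters_reach_minimum_p(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.01, (6, 3)), rng.normal(5, 0.01, (6, 3))])
        dm = DistanceMatrix(
            [f"s{i}" for i in range(12)], squareform(pdist(X)), "euclidean"
        )
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=list(dm.ids))
        _, p = permanova(dm, groups, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_pseudo_F_matches_skbio(self, two_group_table):
        dm = beta_distance(two_group_table, "bray_curtis")
        F, _ = permanova(dm, two_group_table.groups, n_perm=9, seed=1)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.data, list(dm.ids)),
            two_group_table.groups.to_numpy(),
            permutations=9,
        )
        assert F == pytest.approx(sk["test statistic"])

    def test_p_invariant_to_relabeling_and_order(self, two_group_table):
        dm = beta_distance(two_group_table, "bray_curtis")
        g = two_group_table.groups
        _, p1 = permanova(dm, g, n_perm=99, seed=4)
        _, p2 = permanova(dm, g.map({"MIBC": "g1", "NMIBC": "g2"}), n_perm=99, seed=4)
        assert p1 == p2
        order = list(dm.ids)[::-1]
        dm_r = DistanceMatrix(
            order, dm.to_frame().loc[order, order].to_numpy(), dm.metric
        )
        _, p3 = permanova(dm_r, g, n_perm=99, seed=4)
        assert p1 == p3

    def test_monte_carlo_p_matches_full_enumeration_small_n(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(6, 3))
        X[3:] += 1.0
        dm = DistanceMatrix(
            [f"s{i}" for i in range(6)], squareform(pdist(X)), "euclidean"
        )
        labels = np.array([0, 0, 0, 1, 1, 1])
        from twobrad.ecology import _permanova_stat

        D2 = dm.data**2
        f_obs = _permanova_stat(D2, labels, np.array([0, 1]))
        perms = [
            _permanova_stat(D2, np.array(perm), np.array([0, 1]))
            for perm in set(itertools.permutations(labels))
        ]
        exact = np.mean([f >= f_obs for f in perms])
        groups = pd.Series(labels, index=list(dm.ids)).map({0: "a", 1: "b"})
        n_perm = 2000
        _, p_mc = permanova(dm, groups, n_perm=n_perm, seed=3)
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p_mc - exact) <= 3 * se + 1 / n_perm

    def test_empty_group_rejected(self, two_group_table):
        dm = beta_distance(two_group_table, "euclidean")
        with pytest.raises(ValueError):
            permanova(dm, two_group_table.groups.iloc[:10], n_perm=9, seed=0)
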