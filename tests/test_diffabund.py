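"""Rank aggregation, per-taxon Kruskal-Wallis, LDA effect size, LEfSe screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal, rankdata, norm

from conftest import make_table
from twobrad.diffabund import (
    aggregate_to_rank,
    kruskal_wallis_per_taxon,
    lda_effect_size,
    lefse,
)


def taxonomy_for(species, genera=None, phyla=None):
    n = len(species)
    return pd.DataFrame(
        {
            "genus": genera or [f"g{i // 2}" for i in range(n)],
            "phylum": phyla or [f"p{i // 4}" for i in range(n)],
        },
        index=pd.Index(species, name="species_id"),
    )


class TestAggregate:
    def test_genus_sums_species(self):
        species = [f"sp{i}" for i in range(4)]
        table = make_table(
            [[0.3, 0.2, 0.4, 0.1], [0.1, 0.1, 0.4, 0.4]], ["a", "b"],
            taxa=species, taxonomy=taxonomy_for(species),
        )
        genus = aggregate_to_rank(table, "genus")
        assert genus.values.loc["s00", "g0"] == pytest.approx(0.5)
        assert genus.values.loc["s01", "g1"] == pytest.approx(0.8)

    def test_mass_conserved_at_every_rank(self, two_group_table):
        species = two_group_table.taxa
        table = make_table(
            two_group_table.values.to_numpy(),
            two_group_table.groups.tolist(),
            taxa=species, taxonomy=taxonomy_for(species),
        )
        for rank in ("phylum", "genus", "species"):
            sums = aggregate_to_rank(table, rank).values.sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_species_rank_is_identity(self, two_group_table):
        assert aggregate_to_rank(two_group_table, "species") is two_group_table

    def test_missing_taxonomy_entry_is_error(self):
        species = ["sp0", "sp1"]
        table = make_table([[0.5, 0.5]], ["a"], taxa=species,
                           taxonomy=taxonomy_for(["sp0"]))
        with pytest.raises(ValueError, match="sp1"):
            aggregate_to_rank(table, "genus")


class TestKruskalWallis:
    def test_constant_taxon_H_zero_p_one(self):
        table = make_table(
            [[0.5, 0.5], [0.5, 0.5], [0.5, 0.5], [0.5, 0.5]],
            ["a", "a", "b", "b"],
        )
        res = kruskal_wallis_per_taxon(table)
        assert (res["H"] == 0).all() and (res["p"] == 1).all()

    def test_enriched_group_is_larger_mean(self):
        table = make_table(
            [[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]],
            ["a", "a", "b", "b"],
        )
        res = kruskal_wallis_per_taxon(table).set_index("taxon")
        assert res.loc["taxon00", "enriched_in"] == "a"
        assert res.loc["taxon01", "enriched_in"] == "b"

    def test_two_groups_equal_rank_sum_chi_square(self):
        """For two tie-free groups, H equals z^2 of the rank-sum normal
        approximation, so the chi-square p matches it exactly."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=22)
        groups = ["a"] * 15 + ["b"] * 7
        table = make_table(
            np.column_stack([x - x.min() + 0.01, np.ones(22)]), groups
        )
        p_kw = kruskal_wallis_per_taxon(table).set_index("taxon").loc["taxon00", "p"]
        # independent oracle: rank-sum z without continuity correction
        vals = table.values["taxon00"].to_numpy()
        ranks = rankdata(vals)
        n1, n2 = 15, 7
        W = ranks[:15].sum()
        z = (W - n1 * (n1 + n2 + 1) / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert p_kw == pytest.approx(2 * norm.sf(abs(z)), rel=1e-9)

    def test_chi_square_p_close_to_exact_permutation_p_small_n(self):
        """In the rejection region the chi-square approximation tracks the
        exact permutation p closely even at n=7 (it is much coarser for H
        near the centre of the null, where no decision rides on it)."""
        vals = np.array([1.0, 2.0, 3.0, 9.0, 4.0, 11.0, 12.0])
        labels = np.array(["a"] * 4 + ["b"] * 3)
        table = make_table(
            np.column_stack([vals - vals.min() + 0.1, np.ones(7)]),
            labels.tolist(),
        )
        p_chi = kruskal_wallis_per_taxon(table).set_index("taxon").loc["taxon00", "p"]
        h_obs = kruskal(vals[labels == "a"], vals[labels == "b"]).statistic
        hs = []
        for combo in itertools.combinations(range(7), 4):
            mask = np.zeros(7, dtype=bool)
            mask[list(combo)] = True
            hs.append(kruskal(vals[mask], vals[~mask]).statistic)
        p_exact = np.mean([h >= h_obs - 1e-12 for h in hs])
        assert abs(p_chi - p_exact) < 0.05

    def test_H_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.random(10) + 0.1
        groups = ["a"] * 5 + ["b"] * 5
        t1 = make_table(np.column_stack([x, np.ones(10)]), groups)
        t2 = make_table(np.column_stack([x**3, np.ones(10)]), groups)
        h1 = kruskal_wallis_per_taxon(t1).set_index("taxon").loc["taxon00", "H"]
        h2 = kruskal_wallis_per_taxon(t2).set_index("taxon").loc["taxon00", "H"]
        assert h1 == pytest.approx(h2)


class TestLDAEffectSize:
    def test_identical_feature_scores_zero(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.full(12, 0.5), rng.dirichlet([1, 1], 12) * 0.5])
        table = make_table(X, ["a"] * 6 + ["b"] * 6)
        res = lda_effect_size(table, seed=1).set_index("taxon")
        assert res.loc["taxon00", "lda_score"] <= 1e-9

    def test_planted_large_effect_scores_at_least_four(self):
        # ~1e5 per-million in one group, 0 in the other
        rng = np.random.default_rng(0)
        noise = rng.dirichlet(np.ones(5), 12) * 0.9
        planted = np.r_[np.full(6, 0.1), np.zeros(6)]
        X = np.column_stack([planted, noise])
        table = make_table(X, ["a"] * 6 + ["b"] * 6)
        res = lda_effect_size(table, seed=1).set_index("taxon")
        assert res.loc["taxon00", "lda_score"] >= 4.0
        assert res.loc["taxon00", "enriched_in"] == "a"

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.dirichlet(np.ones(6), 14)
        table = make_table(X, ["a"] * 8 + ["b"] * 6)
        res1 = lda_effect_size(table, seed=9)
        shuffled = table.values.sample(frac=1, random_state=0)
        table2 = make_table(
            shuffled.to_numpy(), table.groups.loc[shuffled.index].tolist()
        )
        table2.values.index = shuffled.index
        table2.groups.index = shuffled.index
        res2 = lda_effect_size(table2, seed=9)
        pd.testing.assert_frame_equal(
            res1.sort_values("taxon", ignore_index=True),
            res2.sort_values("taxon", ignore_index=True),
        )

    def test_label_swap_flips_enrichment_keeps_magnitude(self):
        rng = np.random.default_rng(3)
        X = rng.dirichlet(np.ones(4), 16)
        X[:8, 0] *= 6
        table = make_table(X, ["a"] * 8 + ["b"] * 8)
        res1 = lda_effect_size(table, seed=5).set_index("taxon")
        swapped = make_table(
            table.values.to_numpy(),
            table.groups.map({"a": "b", "b": "a"}).tolist(),
        )
        res2 = lda_effect_size(swapped, seed=5).set_index("taxon")
        assert (res1["enriched_in"] != res2["enriched_in"]).all()
        # magnitudes agree up to bootstrap noise
        np.testing.assert_allclose(
            res1["lda_score"], res2["lda_score"], atol=0.35
        )

    def test_too_few_samples_per_class_rejected(self):
        table = make_table([[0.4, 0.6], [0.3, 0.7], [0.2, 0.8]], ["a", "b", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            lda_effect_size(table, seed=0)


class TestLefse:
    def _planted_table(self, seed, n_taxa=15, fold=8.0):
        """High-baseline taxon 0 planted ``fold``-fold higher in group a."""
        rng = np.random.default_rng(seed)
        base = rng.lognormal(0, 0.4, size=(22, n_taxa))
        base[:, 0] *= 10  # high-abundance baseline
        base[:15, 0] *= fold
        return make_table(base, ["a"] * 15 + ["b"] * 7)

    def test_planted_enrichment_detected_with_correct_group(self):
        table = self._planted_table(seed=0)
        report = lefse(table, seed=1)
        assert "taxon00" in report["taxon"].tolist()
        row = report.set_index("taxon").loc["taxon00"]
        assert row["enriched_in"] == "a"

    def test_infinite_cutoff_empty_report(self):
        table = self._planted_table(seed=0)
        assert lefse(table, lda_cutoff=np.inf, seed=1).empty

    def test_report_is_strict_superset_filter(self):
        table = self._planted_table(seed=2)
        report = lefse(table, alpha=0.05, lda_cutoff=2.0, seed=3)
        assert (report["p"] < 0.05).all()
        assert (report["lda_score"] >= 2.0).all()

    def test_group_swap_same_taxa_flipped_labels(self):
        table = self._planted_table(seed=4)
        swapped = make_table(
            table.values.to_numpy(),
            table.groups.map({"a": "b", "b": "a"}).tolist(),
        )
        r1 = lefse(table, seed=6)
        r2 = lefse(swapped, seed=6)
        assert set(r1["taxon"]) == set(r2["taxon"])
        merged = r1.merge(r2, on="taxon", suffixes=("_1", "_2"))
        assert (merged["enriched_in_1"] != merged["enriched_in_2"]).all()

    def test_runs_across_ranks_with_taxonomy(self):
        table = self._planted_table(seed=5, n_taxa=8)
        species = table.taxa
        table = make_table(
            table.values.to_numpy(), table.groups.tolist(), taxa=species,
            taxonomy=taxonomy_for(species),
        )
        report = lefse(table, lda_cutoff=2.0, seed=7)
        assert set(report["rank"]) <= {"phylum", "genus", "species"}
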