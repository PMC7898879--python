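import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from habprof import (
    CountMatrix,
    Dendrogram,
    SynthConfig,
    entanglement,
    filter_and_scope,
    gen_abundance_matrix,
    gen_nested_matrix,
    habitat_mean_distance,
    nodf,
    occupancy,
    pool_and_rarefy,
    sample_bray_curtis,
    top_features,
    ward_cluster,
)
from conftest import nodf_bruteforce


class TestFilterAndScope:
    def make_cm(self, bact_cols):
        counts = pd.DataFrame(
            bact_cols, index=["s1", "s2"],
        )
        fm = pd.DataFrame({"kingdom": "bacteria", "rank": "genus"},
                          index=counts.columns)
        return CountMatrix(counts, feature_meta=fm)

    def test_rows_sum_to_one_after_renormalization(self):
        cm = self.make_cm({"a": [10, 20], "b": [30, 40]})
        rel = filter_and_scope(cm, "bacteria", min_mean_fraction=0.0)
        assert np.allclose(rel.sum(axis=1), 1.0)

    def test_mean_fraction_boundary_strict(self):
        # rows total 1e6, so taxon d sits at exactly mean fraction 1e-5
        # (kept) while taxon c averages 9e-6 (dropped)
        n = 10**6
        cm = self.make_cm({
            "a": [n - 28, n - 10], "c": [18, 0], "d": [10, 10],
        })
        rel = filter_and_scope(cm, "bacteria", min_mean_fraction=1e-5)
        cols = set(rel.columns)
        assert "c" not in cols and "d" in cols

    def test_unknown_kingdom_rejected(self):
        cm = self.make_cm({"a": [1, 2]})
        with pytest.raises(ValueError):
            filter_and_scope(cm, "fungi")


class TestHabitatMeanDistance:
    def test_identical_samples_give_single_distance(self):
        rel = pd.DataFrame(
            [[0.5, 0.5], [0.5, 0.5], [0.9, 0.1], [0.9, 0.1]],
            index=["a1", "a2", "b1", "b2"],
        )
        dist = sample_bray_curtis(rel, sqrt=False)
        hdm = habitat_mean_distance(
            dist, pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        )
        assert hdm.distances.loc["A", "B"] == pytest.approx(
            dist.loc["a1", "b1"]
        )
        assert hdm.distances.loc["A", "A"] == 0.0

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(2)
        rel = pd.DataFrame(
            rng.dirichlet(np.ones(8), size=6),
            index=[f"s{i}" for i in range(6)],
        )
        habitat_of = pd.Series(
            ["A", "A", "B", "B", "C", "C"], index=rel.index
        )
        dist = sample_bray_curtis(rel)
        hdm = habitat_mean_distance(dist, habitat_of)
        for a, b in itertools.combinations("ABC", 2):
            sa = habitat_of.index[habitat_of == a]
            sb = habitat_of.index[habitat_of == b]
            brute = np.mean([dist.loc[x, y] for x in sa for y in sb])
            assert hdm.distances.loc[a, b] == pytest.approx(brute)
            assert hdm.n_pairs.loc[a, b] == 4
        assert np.allclose(hdm.distances.values, hdm.distances.values.T)


FIX4 = pd.DataFrame(
    [[0, 2, 6, 10], [2, 0, 5, 9], [6, 5, 0, 4], [10, 9, 4, 0]],
    index=list("abcd"), columns=list("abcd"), dtype=float,
)


class TestWardCluster:
    def test_two_leaves_merge_at_pair_distance(self):
        d = pd.DataFrame([[0, 3.0], [3.0, 0]], index=["x", "y"], columns=["x", "y"])
        den = ward_cluster(d)
        assert den.merges == [(0, 1, 3.0)]

    def test_ward_d_matches_hclust_reference(self):
        # reference heights computed with R hclust(method="ward.D")
        den = ward_cluster(FIX4, method="ward_d")
        assert [m[:2] for m in den.merges] == [(0, 1), (2, 3), (4, 5)]
        assert [m[2] for m in den.merges] == pytest.approx([2.0, 4.0, 12.0])

    def test_ward_d2_matches_hclust_reference(self):
        # reference heights computed with R hclust(method="ward.D2")
        den = ward_cluster(FIX4, method="ward_d2")
        assert [m[2] for m in den.merges] == pytest.approx(
            [2.0, 4.0, 10.53565375], abs=1e-6
        )

    def test_ward_d2_heights_match_scipy(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(7)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        df = pd.DataFrame(d, index=list("abcdefgh"), columns=list("abcdefgh"))
        ours = sorted(m[2] for m in ward_cluster(df, "ward_d2").merges)
        scipys = sorted(linkage(squareform(d), "ward")[:, 2])
        assert ours == pytest.approx(scipys)

    def test_separated_blocks_split_first(self):
        labels = ["a1", "a2", "b1", "b2"]
        d = pd.DataFrame(
            [[0, 0.1, 0.9, 0.8], [0.1, 0, 0.85, 0.9],
             [0.9, 0.85, 0, 0.1], [0.8, 0.9, 0.1, 0]],
            index=labels, columns=labels,
        )
        cut = ward_cluster(d).cut(2)
        assert cut["a1"] == cut["a2"] != cut["b1"] == cut["b2"]

    def test_recovers_generated_habitat_groups(self):
        cfg = SynthConfig(
            n_habitats=6, n_habitat_groups=3, samples_per_habitat=6,
            habitat_effect=2.5, bf_ratio_per_habitat=50.0,
            depth_range=(10_000, 10_000), seed=13,
        )
        cm, truth = gen_abundance_matrix(cfg)
        rel = filter_and_scope(cm, "bacteria")
        hdm = habitat_mean_distance(sample_bray_curtis(rel), cm.habitat_of())
        cut = ward_cluster(hdm).cut(3)
        # partition identity: same group <=> same cluster
        for a, b in itertools.combinations(truth.group_of.index, 2):
            same_truth = truth.group_of[a] == truth.group_of[b]
            assert (cut[a] == cut[b]) == same_truth


class TestEntanglement:
    def test_identical_dendrograms_zero(self):
        den = ward_cluster(FIX4)
        assert entanglement(den, den) == 0.0

    def test_reversed_leaf_order_is_one(self):
        # two caterpillar trees whose canonical leaf orders are exact
        # reverses of each other
        d1 = Dendrogram(list("abcd"), [(0, 1, 1.0), (4, 2, 2.0), (5, 3, 3.0)])
        d2 = Dendrogram(list("cdab"), [(0, 1, 1.0), (4, 2, 2.0), (5, 3, 3.0)])
        o1, o2 = d1.leaf_order(), d2.leaf_order()
        assert o1 == o2[::-1]
        assert entanglement(d1, d2) == pytest.approx(1.0)

    def test_matches_direct_formula_on_permutation(self):
        labels = list("abcdef")
        d1 = Dendrogram(labels, [(0, 1, 1), (2, 3, 1), (4, 5, 1),
                                 (6, 7, 2), (8, 9, 3)])
        shuffled = ["c", "e", "a", "f", "b", "d"]
        d2 = Dendrogram(shuffled, [(0, 1, 1), (2, 3, 1), (4, 5, 1),
                                   (6, 7, 2), (8, 9, 3)])
        o1, o2 = d1.leaf_order(), d2.leaf_order()
        r1 = {lab: i for i, lab in enumerate(o1)}
        r2 = {lab: i for i, lab in enumerate(o2)}
        n = len(labels)
        expected = sum(abs(r1[l] - r2[l]) ** 1.5 for l in labels) / sum(
            abs(i - (n - 1 - i)) ** 1.5 for i in range(n)
        )
        assert entanglement(d1, d2) == pytest.approx(expected)

    def test_different_leaf_sets_rejected(self):
        d1 = Dendrogram(["a", "b"], [(0, 1, 1.0)])
        d2 = Dendrogram(["a", "c"], [(0, 1, 1.0)])
        with pytest.raises(ValueError):
            entanglement(d1, d2)


class TestPoolAndRarefy:
    def make_cm(self):
        counts = pd.DataFrame(
            {"g1": [50, 30, 10, 5], "g2": [10, 20, 40, 45]},
            index=["a1", "a2", "b1", "b2"],
        )
        meta = pd.DataFrame({"habitat": ["A", "A", "B", "B"]}, index=counts.index)
        return CountMatrix(counts, sample_meta=meta)

    def test_rows_sum_to_depth(self):
        pooled = pool_and_rarefy(self.make_cm(), depth=60, seed=0)
        assert (pooled.sum(axis=1) == 60).all()

    def test_full_depth_row_unchanged(self):
        pooled = pool_and_rarefy(self.make_cm(), depth=100, seed=0)
        assert pooled.loc["B", "g1"] == 15 and pooled.loc["B", "g2"] == 85

    def test_excessive_depth_rejected(self):
        with pytest.raises(ValueError):
            pool_and_rarefy(self.make_cm(), depth=200)

    def test_hypergeometric_expectation(self):
        cm = self.make_cm()
        draws = np.array(
            [pool_and_rarefy(cm, depth=30, seed=s).loc["A", "g1"]
             for s in range(200)]
        )
        # pooled habitat A: g1=80 of 110; E = 30*80/110, hypergeometric SE
        n, k, total = 30, 80, 110
        expect = n * k / total
        var = n * (k / total) * (1 - k / total) * (total - n) / (total - 1)
        assert abs(draws.mean() - expect) <= 3 * np.sqrt(var / 200)


class TestNodf:
    def test_hand_computed_three_rows(self):
        m = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 0]])
        assert nodf(m).nodf_total == pytest.approx(100 / 3)

    def test_matches_vegan_reference(self):
        # reference values computed with vegan::nestednodf in R
        m = np.array(
            [[0, 0, 1, 0, 0, 0], [0, 0, 0, 0, 1, 1], [1, 1, 0, 1, 0, 0],
             [0, 0, 1, 1, 0, 1], [0, 0, 1, 0, 1, 0]]
        )
        res = nodf(m)
        assert res.nodf_total == pytest.approx(26.0)
        assert res.nodf_rows == pytest.approx(30.0)
        assert res.nodf_cols == pytest.approx(23.33333, abs=1e-5)

    def test_perfect_and_equal_fill_for_all_sizes(self):
        for n in (2, 3, 5, 9):
            assert nodf(gen_nested_matrix(n, n, "perfect")).nodf_total == 100.0
            assert nodf(gen_nested_matrix(n, n, "equal_fill")).nodf_total == 0.0

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_row_and_column_permutation(self, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((6, 7)) < 0.5).astype(int)
        perm = m[rng.permutation(6)][:, rng.permutation(7)]
        assert nodf(perm).nodf_total == pytest.approx(nodf(m).nodf_total)

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            m = (rng.random((5, 6)) < rng.uniform(0.2, 0.8)).astype(int)
            assert nodf(m).nodf_total == pytest.approx(nodf_bruteforce(m))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            nodf(np.array([[0, 2], [1, 0]]))


class TestTopFeatures:
    def test_deterministic_with_ties(self):
        counts = pd.DataFrame(
            {"b": [5, 5], "a": [5, 5], "c": [20, 0], "d": [1, 1]},
        )
        assert top_features(counts, 3) == ["c", "a", "b"]

    def test_occupancy_binary(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [2, 0]})
        occ = occupancy(counts)
        assert occ.values.tolist() == [[0, 1], [1, 0]]
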