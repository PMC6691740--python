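import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otukit.diversity import (
    DistanceMatrix,
    alpha_table,
    beta_partition_pair,
    bray_curtis,
    chao1,
    goods_coverage,
    shannon,
    venn_counts,
    weighted_unifrac,
)
from otukit.normalize import AbundanceTable, to_relative
from otukit.synthetic import generate_tree
from otukit.tables_io import CountTable, PhyloTree, ValidationError

import skbio


class TestShannon:
    def test_single_taxon_zero(self):
        assert shannon([7]) == 0.0

    def test_uniform_maximum(self):
        assert shannon([3, 3, 3, 3]) == pytest.approx(np.log(4), abs=1e-12)

    def test_hand_value(self):
        assert shannon([2, 1, 1]) == pytest.approx(1.0397207708399179, abs=1e-9)

    def test_all_zero_errors(self):
        with pytest.raises(ValidationError):
            shannon([0, 0])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(0, 50), min_size=1, max_size=30))
    def test_bounded_by_log_richness(self, counts):
        if sum(counts) == 0:
            counts[0] = 1
        richness = sum(c > 0 for c in counts)
        assert shannon(counts) <= np.log(richness) + 1e-12


class TestChao1:
    def test_no_singletons(self):
        assert chao1([3, 5, 2]) == 3.0

    def test_classic_hand_value(self):
        # S_obs=5, F1=2, F2=1 -> 5 + 4/2 = 7
        assert chao1([1, 1, 2, 3, 4]) == pytest.approx(7.0)

    def test_bias_corrected_hand_value(self):
        # 5 + 2*1/(2*2) = 5.5
        assert chao1([1, 1, 2, 3, 4], bias_corrected=True) == pytest.approx(5.5)

    def test_f2_zero_fallback(self):
        # S_obs=3, F1=2, F2=0 -> 3 + 2*1/2 = 4
        assert chao1([1, 1, 5]) == pytest.approx(4.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(0, 20), min_size=1, max_size=40))
    def test_bias_corrected_at_least_observed(self, counts):
        if sum(counts) == 0:
            counts[0] = 1
        s_obs = sum(c > 0 for c in counts)
        assert chao1(counts, bias_corrected=True) >= s_obs


class TestGoodsCoverage:
    def test_no_singletons(self):
        assert goods_coverage([2, 3, 2]) == 1.0

    def test_hand_value(self):
        counts = [1, 1] + [98]
        assert goods_coverage(counts) == pytest.approx(0.98)

    def test_all_singletons_zero(self):
        assert goods_coverage([1] * 10) == 0.0


class TestAlphaTable:
    def test_columns_and_invariants(self, default_dataset):
        df = alpha_table(default_dataset[0])
        assert list(df.columns) == ["observed_otus", "chao1", "shannon", "goods_coverage"]
        assert (df["chao1"] >= df["observed_otus"] - 1e-9).all()
        assert df["goods_coverage"].between(0, 1).all()
        assert (df["shannon"] >= 0).all()


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        t = CountTable(["a", "b"], ["x", "y"], np.array([[2, 3], [2, 3]]))
        assert bray_curtis(t).matrix[0, 1] == pytest.approx(0.0)

    def test_disjoint_support_one(self):
        t = CountTable(["a", "b"], ["x", "y"], np.array([[2, 0], [0, 3]]))
        assert bray_curtis(t).matrix[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        t = CountTable(["a", "b"], ["x", "y", "z"], np.array([[1, 1, 0], [0, 1, 1]]))
        assert bray_curtis(t).matrix[0, 1] == pytest.approx(0.5)

    def test_symmetry_zero_diag(self, default_dataset):
        dm = bray_curtis(to_relative(default_dataset[0]))
        assert np.allclose(dm.matrix, dm.matrix.T, atol=1e-12)
        assert np.allclose(np.diag(dm.matrix), 0.0, atol=1e-12)
        assert dm.matrix.max() <= 1.0 + 1e-12


def star_tree(taxa, lengths=None):
    children = [
        skbio.TreeNode(name=t, length=1.0 if lengths is None else lengths[i])
        for i, t in enumerate(taxa)
    ]
    return PhyloTree(skbio.TreeNode(children=children))


class TestWeightedUnifrac:
    def test_identical_samples_zero(self):
        tree = star_tree(["x", "y"])
        t = AbundanceTable(["a", "b"], ["x", "y"], np.array([[1.0, 1.0], [2.0, 2.0]]),
                           "relative")
        dm = weighted_unifrac(t, tree, normalized=False)
        assert dm.matrix[0, 1] == pytest.approx(0.0)

    def test_star_tree_raw_is_l1(self):
        tree = star_tree(["x", "y"])
        t = AbundanceTable(["a", "b"], ["x", "y"], np.array([[1.0, 0.0], [0.0, 1.0]]),
                           "relative")
        assert weighted_unifrac(t, tree, normalized=False).matrix[0, 1] == pytest.approx(2.0)

    def test_star_tree_l1_random(self):
        rng = np.random.default_rng(4)
        taxa = [f"t{i}" for i in range(8)]
        tree = star_tree(taxa)
        vals = rng.dirichlet(np.ones(8), size=6)
        t = AbundanceTable([f"s{i}" for i in range(6)], taxa, vals, "relative")
        dm = weighted_unifrac(t, tree, normalized=False)
        for i, j in itertools.combinations(range(6), 2):
            assert dm.matrix[i, j] == pytest.approx(np.abs(vals[i] - vals[j]).sum(),
                                                    abs=1e-12)

    def test_normalized_bounded_random_pairs(self):
        rng = np.random.default_rng(9)
        taxa = [f"t{i}" for i in range(20)]
        tree = generate_tree(taxa, seed=2)
        vals = rng.dirichlet(np.ones(20), size=100)
        t = AbundanceTable([f"s{i}" for i in range(100)], taxa, vals, "relative")
        dm = weighted_unifrac(t, tree, normalized=True)
        assert dm.matrix.min() >= -1e-12
        assert dm.matrix.max() <= 1.0 + 1e-12

    def test_missing_taxon_errors(self):
        tree = star_tree(["x"])
        t = AbundanceTable(["a", "b"], ["x", "y"], np.ones((2, 2)), "relative")
        with pytest.raises(ValidationError, match="y"):
            weighted_unifrac(t, tree)

    def test_matches_skbio(self):
        # independent implementation check on a random tree
        rng = np.random.default_rng(12)
        taxa = [f"t{i}" for i in range(12)]
        tree = generate_tree(taxa, seed=7)
        counts = rng.integers(1, 60, size=(5, 12))
        t = AbundanceTable([f"s{i}" for i in range(5)], taxa, counts.astype(float),
                           "relative")
        mine = weighted_unifrac(t, tree, normalized=False)
        from skbio.diversity import beta_diversity

        theirs = beta_diversity("weighted_unifrac", counts, ids=t.sample_ids,
                                taxa=taxa, tree=tree.root)
        assert np.allclose(mine.matrix, theirs.data, atol=1e-9)


class TestBetaPartition:
    def test_nested_pair_no_turnover(self):
        part = beta_partition_pair([1, 1, 1, 0], [1, 1, 1, 1])
        assert part.beta_sim == pytest.approx(0.0)
        assert part.beta_sne == pytest.approx(part.beta_sor)

    def test_full_replacement_no_nestedness(self):
        part = beta_partition_pair([1, 1, 0, 0], [0, 0, 1, 1])
        assert part.beta_sne == pytest.approx(0.0)
        assert part.beta_sor == pytest.approx(1.0)

    def test_hand_values(self):
        # a=2, b=1, c=3
        x = [1, 1, 1, 0, 0, 0]
        y = [1, 1, 0, 1, 1, 1]
        part = beta_partition_pair(x, y)
        assert part.beta_sor == pytest.approx(0.5)
        assert part.beta_sim == pytest.approx(1 / 3)
        assert part.beta_sne == pytest.approx(1 / 6)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=40))
    def test_additivity_property(self, pairs):
        x = [int(a) for a, _ in pairs]
        y = [int(b) for _, b in pairs]
        if sum(x) == 0 or sum(y) == 0:
            x, y = x + [1], y + [1]
        part = beta_partition_pair(x, y)
        assert part.beta_sor == pytest.approx(part.beta_sim + part.beta_sne, abs=1e-12)
        assert part.beta_sne >= -1e-12

    def test_empty_community_errors(self):
        with pytest.raises(ValidationError):
            beta_partition_pair([0, 0], [1, 0])


class TestVennCounts:
    def test_everywhere_in_full_intersection(self):
        t = CountTable(["a", "b", "c"], ["x"], np.array([[1], [2], [3]]))
        counts = venn_counts(t, {"a": "g1", "b": "g2", "c": "g3"})
        assert counts[frozenset({"g1", "g2", "g3"})] == 1

    def test_partition_identity(self, default_dataset):
        table, _, meta, _, _ = default_dataset
        labels = dict(zip(table.sample_ids, meta.niches(table.sample_ids)))
        counts = venn_counts(table, labels)
        detected = int((table.counts.sum(axis=0) > 0).sum())
        assert sum(counts.values()) == detected

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 3, size=(6, 10))
        counts[:, 0] += 1
        t = CountTable([f"s{i}" for i in range(6)], [f"o{j}" for j in range(10)], counts)
        groups = ["A", "A", "B", "B", "C", "C"]
        result = venn_counts(t, groups)
        labels = np.array(groups)
        for j, otu in enumerate(t.taxon_ids):
            present_in = frozenset(
                g for g in "ABC" if (counts[labels == g, j] > 0).any()
            )
            if present_in:
                # the OTU must be counted exactly in its own subset
                assert result[present_in] >= 1


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        m = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], m)
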