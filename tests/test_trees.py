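"""Bipartition algebra, newick round-trips, RF, consensus, collapse/conflict."""

import itertools

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from galliphylo import trees as T
from galliphylo.trees import (
    Bipartition,
    TreeSample,
    collapse_by_support,
    conflict_report,
    enumerate_topologies,
    majority_rule_consensus,
    parse_newick,
    random_topology,
    resolution,
    rf_distance,
    sample_metrics,
    tree_from_bipartitions,
    write_newick,
)


class TestBipartition:
    def test_canonical_orientation_is_side_without_smallest_taxon(self):
        taxa = {"A", "B", "C", "D"}
        b1 = Bipartition.of({"A", "B"}, taxa)
        b2 = Bipartition.of({"C", "D"}, taxa)
        assert b1 == b2
        assert "A" not in b1.clade

    def test_compatibility(self):
        taxa = set("ABCDE")
        ab = Bipartition.of({"A", "B"}, taxa)
        de = Bipartition.of({"D", "E"}, taxa)
        ac = Bipartition.of({"A", "C"}, taxa)
        assert ab.compatible_with(de)
        assert not ab.compatible_with(ac)
        assert ac.compatible_with(ac)


class TestNewick:
    def test_quartet_has_single_expected_bipartition(self):
        t = parse_newick("((A,B),(C,D));")
        assert t.bipartitions() == {Bipartition.of({"A", "B"}, set("ABCD"))}

    def test_three_leaf_star(self):
        t = parse_newick("(A,B,C);")
        assert t.bipartitions() == frozenset()

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="(?i)duplicate"):
            parse_newick("((A,B),(A,C));")

    def test_rooted_input_is_unrooted(self):
        rooted = parse_newick("((A,B),((C,D),E));")
        unrooted = parse_newick("((A,B),(C,D),E);")
        assert rooted.bipartitions() == unrooted.bipartitions()

    def test_supports_and_lengths_roundtrip(self):
        text = "((A:1,B:2)90:0.5,C:1,(D:1,E:1)0.97:0.25);"
        t = parse_newick(text)
        t2 = parse_newick(write_newick(t))
        e1 = {b: (nd.support, nd.length) for b, nd in t.bipartition_edges().items()}
        e2 = {b: (nd.support, nd.length) for b, nd in t2.bipartition_edges().items()}
        assert e1 == e2

    @pytest.mark.parametrize("seed", range(10))
    def test_roundtrip_preserves_topology_random_20_leaf(self, seed):
        rng = np.random.default_rng(seed)
        t = random_topology([f"t{i:02d}" for i in range(20)], rng)
        again = parse_newick(write_newick(t))
        assert again.bipartitions() == t.bipartitions()


class TestBipartitionSets:
    def test_caterpillar_five_leaves(self):
        t = parse_newick("((A,B),C,(D,E));")
        assert len(t.bipartitions()) == 2

    def test_star_any_n(self):
        t = parse_newick("(" + ",".join(f"x{i}" for i in range(9)) + ");")
        assert t.bipartitions() == frozenset()

    @pytest.mark.parametrize("n", [5, 8, 12, 20])
    def test_random_binary_tree_has_n_minus_3(self, n):
        rng = np.random.default_rng(n)
        t = random_topology([f"t{i:02d}" for i in range(n)], rng)
        assert len(t.bipartitions()) == n - 3


def _brute_rf(t1, t2):
    """Independent symmetric-difference count via explicit frozenset pairs."""
    def splits(t):
        out = set()
        for b in t.bipartitions():
            out.add(frozenset({b.clade, b.taxa - b.clade}))
        return out

    return len(splits(t1) ^ splits(t2))


class TestRF:
    def test_identity(self, caterpillar8):
        assert rf_distance(caterpillar8, caterpillar8) == 0

    def test_three_conflicting_branches_give_rf_six(self):
        t1 = parse_newick("(A,B,(C,(D,(E,(F,(G,H))))));")
        t2 = parse_newick("(A,B,(C,(E,(G,(D,(F,H))))));")
        b1, b2 = t1.bipartitions(), t2.bipartitions()
        assert len(b1 - b2) == 3 and len(b2 - b1) == 3
        assert rf_distance(t1, t2) == 6

    def test_exhaustive_five_leaf_pairs_match_oracles(self):
        tops = list(enumerate_topologies("ABCDE"))
        assert len(tops) == 15
        dtaxa = dendropy.TaxonNamespace()
        dtops = [
            dendropy.Tree.get(data=write_newick(t), schema="newick",
                              taxon_namespace=dtaxa)
            for t in tops
        ]
        for dt in dtops:
            dt.encode_bipartitions()
        for i, j in itertools.product(range(15), repeat=2):
            rf = rf_distance(tops[i], tops[j])
            assert rf == _brute_rf(tops[i], tops[j])
            assert rf == dendropy.calculate.treecompare.symmetric_difference(
                dtops[i], dtops[j]
            )
            assert rf in (0, 2, 4)

    def test_metric_properties_on_five_leaf_topologies(self):
        tops = list(enumerate_topologies("ABCDE"))
        d = np.array([[rf_distance(a, b) for b in tops] for a in tops])
        assert (d >= 0).all()
        assert (d == d.T).all()
        assert (np.diag(d) == 0).all()
        assert all(d[i, j] > 0 for i in range(15) for j in range(15) if i != j)
        for i, j, k in itertools.product(range(15), repeat=3):
            assert d[i, k] <= d[i, j] + d[j, k]

    def test_rf_to_star_equals_internal_edge_count(self, caterpillar8):
        star = parse_newick("(" + ",".join("ABCDEFGH") + ");")
        assert rf_distance(caterpillar8, star) == len(caterpillar8.bipartitions())

    def test_leaf_set_mismatch_names_missing_taxa(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,B),(C,E));")
        with pytest.raises(ValueError, match="E"):
            rf_distance(t1, t2)

    def test_multifurcating_trees_supported(self):
        t1 = parse_newick("((A,B),C,D,E);")
        t2 = parse_newick("((A,B),(C,D),E);")
        assert rf_distance(t1, t2) == 1


class TestConsensus:
    def test_identical_sample_returns_tree_with_full_support(self):
        t = parse_newick("((A,B),C,(D,E));")
        cons = majority_rule_consensus(TreeSample([t.copy() for _ in range(7)]))
        assert cons.bipartitions() == t.bipartitions()
        assert all(
            nd.support == 100.0 for nd in cons.bipartition_edges().values()
        )

    def test_two_to_one_majority_keeps_edge_at_667(self):
        t1 = parse_newick("((A,B),C,(D,E));")
        t2 = parse_newick("((A,C),B,(D,E));")
        cons = majority_rule_consensus(TreeSample([t1.copy(), t1.copy(), t2]))
        sup = {b: nd.support for b, nd in cons.bipartition_edges().items()}
        ab = Bipartition.of({"A", "B"}, set("ABCDE"))
        de = Bipartition.of({"D", "E"}, set("ABCDE"))
        assert sup[ab] == pytest.approx(200 / 3)
        assert sup[de] == 100.0
        assert set(sup) == {ab, de}

    def test_high_threshold_on_split_sample_gives_star_at_conflict(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        cons = majority_rule_consensus(
            TreeSample([t1, t2]), threshold=0.99
        )
        assert cons.bipartitions() == frozenset()

    def test_majority_tree_fully_contained_at_half_threshold(self):
        rng = np.random.default_rng(5)
        t = random_topology(list("ABCDEFG"), rng)
        other = random_topology(list("ABCDEFG"), rng)
        sample = TreeSample([t.copy(), t.copy(), t.copy(), other])
        cons = majority_rule_consensus(sample, threshold=0.5)
        assert t.bipartitions() <= cons.bipartitions()

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            TreeSample([])


class TestResolutionAndMetrics:
    def test_binary_tree_is_fully_resolved(self, caterpillar8):
        assert resolution(caterpillar8) == 1.0

    def test_star_tree_resolution_zero(self):
        assert resolution(parse_newick("(A,B,C,D,E);")) == 0.0

    def test_small_trees_rejected(self):
        with pytest.raises(ValueError):
            resolution(parse_newick("(A,B,C);"))

    def test_46_leaf_tree_with_one_collapsed_edge(self):
        rng = np.random.default_rng(46)
        t = random_topology([f"t{i:02d}" for i in range(46)], rng)
        collapsed = tree_from_bipartitions(
            sorted(t.taxa), list(t.bipartitions())[:-1]
        )
        assert resolution(collapsed) == pytest.approx(42 / 43)

    def test_identical_sample_metrics(self):
        t = parse_newick("((A,B),(C,D),E);")
        m = sample_metrics(TreeSample([t.copy() for _ in range(100)]))
        assert m["percent_unique"] == pytest.approx(1.0)
        assert m["mean_resolution"] == 1.0

    def test_all_distinct_sample(self):
        tops = list(enumerate_topologies("ABCDE"))[:10]
        m = sample_metrics(TreeSample(tops))
        assert m["percent_unique"] == 100.0

    def test_mixed_resolution_sample(self):
        labels = [f"t{i}" for i in range(10)]
        rng = np.random.default_rng(0)
        binary = random_topology(labels, rng)
        poly = tree_from_bipartitions(labels, list(binary.bipartitions())[:-1])
        sample = TreeSample(
            [binary.copy() for _ in range(50)] + [poly.copy() for _ in range(50)]
        )
        m = sample_metrics(sample)
        assert m["mean_resolution"] == pytest.approx((50 * 1.0 + 50 * 6 / 7) / 100)
        assert m["resolution_range"] == (pytest.approx(6 / 7), 1.0)


class TestCollapse:
    def test_all_supports_above_threshold_unchanged(self, caterpillar8):
        out = collapse_by_support(caterpillar8, bootstrap_min=70)
        assert out.bipartitions() == caterpillar8.bipartitions()

    def test_all_supports_below_threshold_gives_star(self, caterpillar8):
        out = collapse_by_support(caterpillar8, bootstrap_min=99.5)
        assert out.bipartitions() == frozenset()

    def test_support_exactly_at_threshold_is_retained(self, caterpillar8):
        out = collapse_by_support(caterpillar8, bootstrap_min=97)
        sup = [nd.support for nd in out.bipartition_edges().values()]
        assert sorted(sup) == [97, 98, 99]

    def test_posterior_scale_supports(self):
        t = parse_newick("((A,B)0.96,C,(D,E)0.90);")
        out = collapse_by_support(t, posterior_min=0.95)
        assert len(out.bipartitions()) == 1

    def test_missing_support_policy(self):
        t = parse_newick("((A,B),C,(D,E)80);")
        with pytest.raises(ValueError):
            collapse_by_support(t)
        kept = collapse_by_support(t, on_missing="keep")
        assert len(kept.bipartitions()) == 2

    def test_collapse_never_increases_resolution(self, caterpillar8):
        res = [
            resolution(collapse_by_support(caterpillar8, bootstrap_min=thr))
            for thr in (0, 96, 97, 98, 99, 100)
        ]
        assert res == sorted(res, reverse=True)
        assert all(r <= resolution(caterpillar8) for r in res)


class TestConflictReport:
    def test_identical_trees_no_conflict(self, caterpillar8):
        assert conflict_report(caterpillar8, caterpillar8) == []

    def test_single_strong_conflict_detected(self):
        a = parse_newick("((A,B)95,C,(D,E)99);")
        b = parse_newick("((A,C)90,B,(D,E)99);")
        pairs = conflict_report(a, b, support_min=70)
        assert len(pairs) == 1
        ba, bb = pairs[0]
        assert not ba.compatible_with(bb)

    def test_threshold_above_supports_silences_conflict(self):
        a = parse_newick("((A,B)95,C,(D,E)99);")
        b = parse_newick("((A,C)90,B,(D,E)99);")
        assert conflict_report(a, b, support_min=96) == []


@settings(derandomize=True, deadline=None, max_examples=30)
@given(seed=st.integers(0, 10**6), n=st.integers(4, 14))
def test_property_rf_is_symmetric_and_bounded(seed, n):
    rng = np.random.default_rng(seed)
    labels = [f"t{i:02d}" for i in range(n)]
    a = random_topology(labels, rng)
    b = random_topology(labels, rng)
    d = rf_distance(a, b)
    assert d == rf_distance(b, a)
    assert 0 <= d <= 2 * (n - 3)
    assert (d == 0) == (a.bipartitions() == b.bipartitions())


@settings(derandomize=True, deadline=None, max_examples=30)
@given(seed=st.integers(0, 10**6), n=st.integers(4, 12))
def test_property_bipartition_orientation_is_canonical(seed, n):
    rng = np.random.default_rng(seed)
    taxa = {f"t{i:02d}" for i in range(n)}
    side = set(
        rng.choice(sorted(taxa), size=int(rng.integers(1, n)), replace=False)
    )
    assert Bipartition.of(side, taxa) == Bipartition.of(taxa - side, taxa)


class TestTreeFromBipartitions:
    @pytest.mark.parametrize("seed", range(5))
    def test_rebuild_from_own_bipartitions(self, seed):
        rng = np.random.default_rng(seed)
        t = random_topology([f"t{i}" for i in range(12)], rng)
        rebuilt = tree_from_bipartitions(sorted(t.taxa), t.bipartitions())
        assert rebuilt.bipartitions() == t.bipartitions()

    def test_incompatible_input_rejected(self):
        taxa = sorted("ABCDE")
        ab = Bipartition.of({"A", "B"}, set(taxa))
        ac = Bipartition.of({"A", "C"}, set(taxa))
        with pytest.raises(ValueError, match="incompatible"):
            tree_from_bipartitions(taxa, [ab, ac])
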