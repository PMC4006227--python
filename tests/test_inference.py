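"""Distances, neighbor joining, pruning likelihood, AIC, NNI, bootstrap."""

import itertools
import math

import numpy as np
import pytest

from galliphylo import inference as I
from galliphylo import trees as T
from galliphylo.alignment import concatenate
from galliphylo.inference import (
    DistanceMatrix,
    SaturationError,
    SitePatterns,
    SubstitutionModel,
    aic_select,
    bootstrap_trees,
    log_likelihood,
    neighbor_joining,
    nni_hill_climb,
    pairwise_distance,
)
from galliphylo.simulate import simulate_sequences
from conftest import patristic_matrix


def brute_force_likelihood(tree, aln, model):
    """Sum over all internal-state assignments (oracle for <= 6 taxa)."""
    rates = model.category_rates()
    pi = np.asarray(model.pi)
    nodes = list(tree.root.postorder())
    internals = [nd for nd in nodes if nd.children]
    L = len(next(iter(aln.values())))
    site_liks = np.zeros(L)
    for site in range(L):
        total = 0.0
        for rate in rates:
            pmats = {
                id(nd): model.transition_matrix(nd.length, rate)
                for nd in nodes
                if nd.parent is not None
            }
            s = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                amap = {id(nd): a for nd, a in zip(internals, assign)}
                prob = pi[amap[id(tree.root)]]
                for nd in nodes:
                    if nd.parent is None:
                        continue
                    state = (
                        amap[id(nd)]
                        if nd.children
                        else "ACGT".index(aln[nd.label][site])
                    )
                    prob *= pmats[id(nd)][amap[id(nd.parent)], state]
                s += prob
            total += s / len(rates)
        site_liks[site] = total
    return float(np.log(site_liks).sum())


class TestDistances:
    def test_identical_sequences_are_distance_zero(self):
        for model in ("p", "JC", "K80"):
            assert pairwise_distance("ACGTACGT", "ACGTACGT", model) == 0.0

    def test_jc_closed_form_at_ten_percent(self):
        s1 = "A" * 900 + "C" * 100
        s2 = "A" * 1000
        expected = -0.75 * math.log(1 - 0.4 / 3)
        assert pairwise_distance(s1, s2, "JC") == pytest.approx(expected)
        assert expected == pytest.approx(0.10732, abs=1e-5)

    def test_ambiguous_sites_skipped(self):
        assert pairwise_distance("ACGT", "RCGT", "p") == 0.0
        assert pairwise_distance("ACG-", "TCG?", "p") == pytest.approx(1 / 3)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            pairwise_distance("AAAA", "CCCC", "JC")

    def test_no_comparable_sites_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distance("----", "ACGT", "JC")

    def test_saturation_policy_in_matrix(self):
        aln = concatenate(
            [("L", "nuclear", {"a": "AAAAAA", "b": "AAAAAC", "c": "CCCCCC"})]
        )
        dm = I.distance_matrix(aln, "JC")
        finite = pairwise_distance("AAAAAA", "AAAAAC", "JC")
        assert dm[("a", "c")] == pytest.approx(2 * finite)

    def test_jc_estimator_inverts_simulation(self):
        """Simulate at known distance, estimate it back within 5%."""
        two = T.parse_newick("(x:0.15,y:0.15);", rooted=True)
        aln = simulate_sequences(two, 10000, SubstitutionModel.jc(), seed=8)
        d = pairwise_distance(aln["x"], aln["y"], "JC")
        assert d == pytest.approx(0.3, rel=0.05)

    def test_k80_on_transition_only_divergence(self):
        s1 = "A" * 100
        s2 = "A" * 90 + "G" * 10
        d = pairwise_distance(s1, s2, "K80")
        expected = -0.5 * math.log(1 - 0.2)
        assert d == pytest.approx(expected)


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # distances from ((A:1,B:2):1,(C:3,D:1))
        dm = DistanceMatrix(
            list("ABCD"),
            np.array(
                [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
            ),
        )
        tree = neighbor_joining(dm)
        assert tree.bipartitions() == {T.Bipartition.of({"A", "B"}, set("ABCD"))}
        taxa, d = patristic_matrix(tree)
        assert np.allclose(d, dm.values)

    def test_three_taxa_three_point_formulas(self):
        dm = DistanceMatrix(
            list("ABC"), np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        )
        tree = neighbor_joining(dm)
        lengths = {nd.label: nd.length for nd in tree.root.children}
        assert lengths == {"A": 0.0, "B": 2.0, "C": 3.0}

    @pytest.mark.parametrize("seed", range(20))
    def test_additive_matrices_recover_topology(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        tree = T.random_topology([f"t{i:02d}" for i in range(n)], rng)
        for nd in tree.root.postorder():
            if nd.parent is not None:
                nd.length = float(rng.uniform(0.1, 1.0))
        taxa, d = patristic_matrix(tree)
        est = neighbor_joining(DistanceMatrix(taxa, d))
        assert est.bipartitions() == tree.bipartitions()

    def test_constant_shift_leaves_topology_unchanged(self):
        rng = np.random.default_rng(77)
        n = 8
        vals = rng.uniform(0.2, 1.0, size=(n, n))
        d = (vals + vals.T) / 2
        np.fill_diagonal(d, 0)
        taxa = [f"t{i}" for i in range(n)]
        t1 = neighbor_joining(DistanceMatrix(taxa, d))
        shifted = d + 1.0
        np.fill_diagonal(shifted, 0)
        t2 = neighbor_joining(DistanceMatrix(taxa, shifted))
        assert t1.bipartitions() == t2.bipartitions()

    def test_deterministic_under_ties(self):
        d = np.ones((4, 4)) - np.eye(4)
        taxa = list("ABCD")
        t1 = neighbor_joining(DistanceMatrix(taxa, d.copy()))
        t2 = neighbor_joining(DistanceMatrix(taxa, d.copy()))
        assert t1.newick() == t2.newick()

    def test_nonnegative_branch_lengths(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.01, 0.1, size=(6, 6))
        d = (vals + vals.T) / 2
        np.fill_diagonal(d, 0)
        tree = neighbor_joining(DistanceMatrix([f"t{i}" for i in range(6)], d))
        assert all(
            nd.length >= 0
            for nd in tree.root.postorder()
            if nd.parent is not None
        )


class TestLikelihood:
    def test_two_taxa_single_site_closed_form(self):
        for d in (0.01, 0.1, 1.0):
            tree = T.parse_newick(f"(X:{d},Y:0);", rooted=True)
            lnl = log_likelihood(tree, {"X": "A", "Y": "A"}, SubstitutionModel.jc())
            expected = math.log(0.25 * (0.25 + 0.75 * math.exp(-4 * d / 3)))
            assert lnl == pytest.approx(expected)

    def test_zero_distance_identical_sequences(self):
        tree = T.parse_newick("(X:0,Y:0);", rooted=True)
        aln = {"X": "ACGTACGTAC", "Y": "ACGTACGTAC"}
        lnl = log_likelihood(tree, aln, SubstitutionModel.jc())
        assert lnl == pytest.approx(10 * math.log(0.25))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_pruning_matches_brute_force_five_taxa(self, seed):
        rng = np.random.default_rng(seed)
        tree = T.random_topology(list("ABCDE"), rng)
        for nd in tree.root.postorder():
            if nd.parent is not None:
                nd.length = float(rng.uniform(0.05, 0.5))
        aln = {t: "".join(rng.choice(list("ACGT"), 15)) for t in "ABCDE"}
        model = SubstitutionModel.gtr(
            (1.0, 2.0, 0.7, 1.3, 2.5, 1.0), (0.3, 0.2, 0.2, 0.3), alpha=0.8
        )
        assert log_likelihood(tree, aln, model) == pytest.approx(
            brute_force_likelihood(tree, aln, model)
        )

    def test_invariant_to_site_and_taxon_order(self):
        rng = np.random.default_rng(5)
        tree = T.random_topology(list("ABCDEF"), rng)
        for nd in tree.root.postorder():
            if nd.parent is not None:
                nd.length = 0.2
        cols = rng.choice(list("ACGT"), size=(6, 50))
        aln = {t: "".join(cols[i]) for i, t in enumerate("ABCDEF")}
        perm = rng.permutation(50)
        aln_shuffled = {t: "".join(cols[i, perm]) for i, t in enumerate("ABCDEF")}
        aln_reversed = dict(reversed(list(aln.items())))
        model = SubstitutionModel.k80(3.0, alpha=1.0)
        ref = log_likelihood(tree, aln, model)
        assert log_likelihood(tree, aln_shuffled, model) == pytest.approx(ref)
        assert log_likelihood(tree, aln_reversed, model) == pytest.approx(ref)

    def test_gtr_gamma_limit_reduces_to_jc(self):
        rng = np.random.default_rng(6)
        tree = T.random_topology(list("ABCDE"), rng)
        for nd in tree.root.postorder():
            if nd.parent is not None:
                nd.length = 0.1
        aln = {t: "".join(rng.choice(list("ACGT"), 40)) for t in "ABCDE"}
        jc = log_likelihood(tree, aln, SubstitutionModel.jc())
        gtr_limit = log_likelihood(
            tree,
            aln,
            SubstitutionModel.gtr(
                (1.0,) * 6, (0.25,) * 4, alpha=1e9
            ),
        )
        assert abs(jc - gtr_limit) < 1e-6

    def test_ambiguity_codes_as_partial_likelihoods(self):
        tree = T.parse_newick("(X:0.1,Y:0.1);", rooted=True)
        model = SubstitutionModel.jc()
        # N is compatible with everything: likelihood sums over all states = 1
        lnl_n = log_likelihood(tree, {"X": "N", "Y": "A"}, model)
        assert lnl_n == pytest.approx(math.log(0.25))
        # R = A or G: sum of the two resolved-site likelihoods
        la = math.exp(log_likelihood(tree, {"X": "A", "Y": "A"}, model))
        lg = math.exp(log_likelihood(tree, {"X": "G", "Y": "A"}, model))
        lr = math.exp(log_likelihood(tree, {"X": "R", "Y": "A"}, model))
        assert lr == pytest.approx(la + lg)

    def test_zero_length_alignment_rejected(self):
        with pytest.raises(ValueError):
            SitePatterns.from_alignment({"X": "", "Y": ""})


class TestModelSelection:
    def test_aic_arithmetic_and_tie_break(self):
        rng = np.random.default_rng(12)
        tree = T.random_topology(list("ABCD"), rng)
        for nd in tree.root.postorder():
            if nd.parent is not None:
                nd.length = 0.1
        two = T.parse_newick("(X:0.1,Y:0.1);", rooted=True)
        aln = {t: "".join(rng.choice(list("ACGT"), 100)) for t in "ABCD"}
        best, table = aic_select(aln, tree, candidates=[SubstitutionModel.jc()])
        row = table.iloc[0]
        assert row["AIC"] == pytest.approx(2 * row["k"] - 2 * row["lnL"])
        assert row["k"] == 0

    def test_jc_data_prefers_jc_over_gtr_gamma(self):
        """Parsimony of parameters: on JC-simulated data JC should win AIC
        in most replicates."""
        rng = np.random.default_rng(0)
        wins = 0
        n_reps = 8
        for rep in range(n_reps):
            tree = T.random_topology(list("ABCDE"), np.random.default_rng(rep))
            for nd in tree.root.postorder():
                if nd.parent is not None:
                    nd.length = float(rng.uniform(0.05, 0.3))
            aln = simulate_sequences(tree, 2000, SubstitutionModel.jc(), seed=rep + 1)
            best, table = aic_select(
                aln,
                tree,
                candidates=[
                    SubstitutionModel.jc(),
                    SubstitutionModel.gtr(
                        (1.0, 2.0, 1.0, 1.0, 2.0, 1.0), (0.25,) * 4, alpha=1.0
                    ),
                ],
            )
            aics = dict(zip(table["model"], table["AIC"]))
            wins += aics["JC"] <= aics["GTR+G"]
        assert wins >= int(0.8 * n_reps)


def _score_topology(top, pats, model):
    t = top.copy()
    for nd in t.root.postorder():
        if nd.parent is not None:
            nd.length = 0.1
    return I.optimize_branch_lengths(t, pats, model, rounds=2)


class TestNNI:
    def test_four_taxa_reaches_global_optimum(self):
        rng = np.random.default_rng(21)
        true = T.parse_newick("((A:0.3,B:0.3):0.2,(C:0.3,D:0.3));", rooted=True)
        aln = simulate_sequences(true, 800, SubstitutionModel.jc(), seed=2)
        model = SubstitutionModel.jc()
        pats = SitePatterns.from_alignment(aln)
        start = T.parse_newick("((A:0.1,C:0.1):0.1,B:0.1,D:0.1);")
        result = nni_hill_climb(start, aln, model)
        best = max(
            _score_topology(t, pats, model)
            for t in T.enumerate_topologies("ABCD")
        )
        got = I.optimize_branch_lengths(result.copy(), pats, model, rounds=2)
        # attains the exhaustive optimum (up to branch-length optimizer slack)
        assert got >= best - 0.05

    def test_five_taxa_recovers_exhaustive_optimum(self):
        model = SubstitutionModel.jc()
        hits = 0
        n_reps = 10
        for rep in range(n_reps):
            rng = np.random.default_rng(100 + rep)
            true = T.random_topology(list("ABCDE"), rng)
            for nd in true.root.postorder():
                if nd.parent is not None:
                    nd.length = float(rng.uniform(0.1, 0.4))
            aln = simulate_sequences(true, 600, model, seed=200 + rep)
            pats = SitePatterns.from_alignment(aln)
            start = T.random_topology(list("ABCDE"), np.random.default_rng(999))
            result = nni_hill_climb(start, aln, model)
            scores = [
                _score_topology(t, pats, model)
                for t in T.enumerate_topologies("ABCDE")
            ]
            got = I.optimize_branch_lengths(result.copy(), pats, model, rounds=2)
            hits += got >= max(scores) - 1e-3
        assert hits >= n_reps - 1

    def test_start_at_optimum_is_stable(self):
        true = T.parse_newick("((A:0.3,B:0.3):0.3,(C:0.3,D:0.3));", rooted=True)
        aln = simulate_sequences(true, 1500, SubstitutionModel.jc(), seed=5)
        start = T.parse_newick("((A:0.3,B:0.3):0.3,C:0.3,D:0.3);")
        result = nni_hill_climb(start, aln, SubstitutionModel.jc())
        assert result.bipartitions() == start.bipartitions()

    def test_final_lnl_never_below_start(self):
        rng = np.random.default_rng(31)
        true = T.random_topology(list("ABCDEF"), rng)
        for nd in true.root.postorder():
            if nd.parent is not None:
                nd.length = 0.2
        aln = simulate_sequences(true, 300, SubstitutionModel.jc(), seed=3)
        start = T.random_topology(list("ABCDEF"), rng)
        for nd in start.root.postorder():
            if nd.parent is not None:
                nd.length = 0.05
        model = SubstitutionModel.jc()
        start_lnl = log_likelihood(start, aln, model)
        result = nni_hill_climb(start, aln, model)
        assert log_likelihood(result, aln, model) >= start_lnl - 1e-9


class TestBootstrap:
    @pytest.fixture(scope="class")
    def signal_alignment(self):
        tree = T.parse_newick(
            "(((A:0.2,B:0.2):0.15,(C:0.2,D:0.2):0.15):0.1,"
            "((E:0.2,F:0.2):0.15,(G:0.2,H:0.2):0.15));",
            rooted=True,
        )
        aln = simulate_sequences(tree, 5000, SubstitutionModel.jc(), seed=17)
        return tree, concatenate([("L", "nuclear", aln)])

    def test_deterministic_given_seed(self, signal_alignment):
        _, m = signal_alignment
        t1 = bootstrap_trees(m, B=1, seed=42).trees[0]
        t2 = bootstrap_trees(m, B=1, seed=42).trees[0]
        assert t1.newick() == t2.newick()

    def test_replicate_columns_come_from_original(self, signal_alignment):
        _, m = signal_alignment
        rep = I._resample_columns(m, np.random.default_rng(1))
        original = {m.data[:, j].tobytes() for j in range(m.length)}
        assert all(
            rep.data[:, j].tobytes() in original for j in range(rep.length)
        )
        assert rep.length == m.length

    def test_clean_data_supports_true_splits_strongly(self, signal_alignment):
        tree, m = signal_alignment
        sample = bootstrap_trees(m, B=50, seed=7)
        cons = T.majority_rule_consensus(sample)
        supports = {b: nd.support for b, nd in cons.bipartition_edges().items()}
        for b in tree.unrooted().bipartitions():
            assert supports.get(b, 0.0) >= 95.0

    def test_provenance_recorded(self, signal_alignment):
        _, m = signal_alignment
        sample = bootstrap_trees(m, B=3, seed=5, locus="L")
        assert sample.locus == "L"
        assert sample.seed == 5
        assert sample.replicate_ids == [0, 1, 2]
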