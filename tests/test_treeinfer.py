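"""Distance estimation, NJ, likelihood engine, NNI, bootstrap."""

import numpy as np
import pytest

from traitrad.iocore import Alignment
from traitrad.protmodel import (DistanceMatrix, SubstitutionModel,
                                distance_matrix, ml_distance)
from traitrad.treeinfer import (TreeLikelihood, bootstrap_support,
                                ml_refine, nj_tree)
from traitrad.tree import Tree, path_length
from traitrad._wag import AA_ORDER

MODEL = SubstitutionModel()


def simulate_protein_rows(tree, n_sites, seed):
    rng = np.random.default_rng(seed)
    states = {id(tree.root): rng.choice(20, size=n_sites, p=MODEL.pi)}
    for node in tree.preorder():
        for c in node.children:
            P = MODEL.transition(c.length or 0.0)
            cur = states[id(node)]
            cum = P.cumsum(axis=1)
            u = rng.random(n_sites)
            states[id(c)] = (u[:, None] > cum[cur]).sum(axis=1)
    return {t.label: "".join(AA_ORDER[s] for s in states[id(t)])
            for t in tree.tips()}


class TestModel:
    def test_transition_rows_sum_to_one(self):
        for t in (0.0, 0.1, 2.0, 10.0):
            P = MODEL.transition(t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_time_zero_is_identity(self):
        assert np.allclose(MODEL.transition(0.0), np.eye(20), atol=1e-12)

    def test_chapman_kolmogorov(self):
        P = MODEL.transition(0.7)
        P2 = MODEL.transition(0.3) @ MODEL.transition(0.4)
        assert np.abs(P - P2).max() < 1e-10


class TestMlDistance:
    def test_identical_rows_distance_zero(self):
        assert ml_distance("MKVLIT" * 30, "MKVLIT" * 30, MODEL) == 0.0

    def test_two_taxon_tree_likelihood_matches_distance_objective(self):
        tree = Tree.from_newick("(a:0.15,b:0.15);")
        rows = simulate_protein_rows(tree, 300, seed=5)
        aln = Alignment(["a", "b"], [rows["a"], rows["b"]])
        engine = TreeLikelihood(aln, MODEL)
        d_hat = ml_distance(rows["a"], rows["b"], MODEL)
        # engine likelihood at split t/2 + t/2 equals pair objective at t
        for t in (0.1, d_hat, 0.8):
            tree2 = Tree.from_newick(f"(a:{t / 2},b:{t / 2});")
            ll_engine = engine.loglik(tree2)
            N = np.zeros((20, 20))
            from traitrad.protmodel import (encode_protein_alignment,
                                            _pair_counts)
            codes = encode_protein_alignment(aln)
            N = _pair_counts(codes[0], codes[1])
            P = MODEL.transition(t)
            ll_pair = (N * np.log(MODEL.pi[:, None] * P)).sum()
            assert ll_engine == pytest.approx(ll_pair, abs=1e-6)

    def test_recovery_near_truth(self):
        tree = Tree.from_newick("(a:0.25,b:0.25);")
        hits = 0
        for seed in range(20):
            rows = simulate_protein_rows(tree, 1000, seed=seed)
            d = ml_distance(rows["a"], rows["b"], MODEL)
            hits += 0.4 <= d <= 0.6
        assert hits >= 18

    def test_no_shared_columns_rejected(self):
        from traitrad.iocore import FormatError
        with pytest.raises(FormatError):
            ml_distance("MK--", "--VL", MODEL)


class TestNeighborJoining:
    def test_additive_distances_recover_tree_exactly(self):
        truth = Tree.from_newick(
            "((A:0.2,B:0.3):0.15,(C:0.25,D:0.35):0.1);")
        ids = ["A", "B", "C", "D"]
        D = np.array([[path_length(truth, a, b) if a != b else 0.0
                       for b in ids] for a in ids])
        out = nj_tree(DistanceMatrix(ids, D))
        assert out.same_topology(truth)
        for a in ids:
            for b in ids:
                if a < b:
                    assert path_length(out, a, b) == pytest.approx(
                        path_length(truth, a, b), abs=1e-10)

    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 0.4, 0.6],
                                     [0.4, 0, 0.8],
                                     [0.6, 0.8, 0]]))
        t = nj_tree(D)
        la = t.find_tip("A").length
        lb = t.find_tip("B").length
        lc = t.find_tip("C").length
        assert la == pytest.approx((0.4 + 0.6 - 0.8) / 2)
        assert lb == pytest.approx((0.4 + 0.8 - 0.6) / 2)
        assert lc == pytest.approx((0.6 + 0.8 - 0.4) / 2)

    def test_ultrametric_cherry_splits_evenly(self):
        eps = 0.05
        D = DistanceMatrix(["A", "B", "C", "D"], np.array([
            [0, 2 * eps, 1.0, 1.0],
            [2 * eps, 0, 1.0, 1.0],
            [1.0, 1.0, 0, 2 * eps],
            [1.0, 1.0, 2 * eps, 0]]))
        t = nj_tree(D)
        assert t.find_tip("A").length == pytest.approx(eps)
        assert t.find_tip("B").length == pytest.approx(eps)

    def test_random_binary_trees_recovered(self, rng):
        from conftest import random_rooted_tree
        for _ in range(10):
            truth = random_rooted_tree(rng, 8, max_bl=0.5)
            ids = truth.tip_labels()
            D = np.array([[path_length(truth, a, b) if a != b else 0.0
                           for b in ids] for a in ids])
            assert nj_tree(DistanceMatrix(ids, D)).same_topology(truth)

    def test_too_few_taxa_rejected(self):
        from traitrad.tree import TreeError
        with pytest.raises(TreeError):
            nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))


class TestMlRefine:
    TRUTH = Tree.from_newick(
        "((A:0.12,B:0.12):0.1,(C:0.12,D:0.12):0.1,E:0.2);")

    def _aln(self, seed, n=1500):
        rows = simulate_protein_rows(self.TRUTH, n, seed=seed)
        return Alignment(list(rows), list(rows.values()))

    def test_zero_rounds_only_optimizes_branch_lengths(self):
        aln = self._aln(1)
        start = nj_tree(distance_matrix(aln, MODEL))
        out = ml_refine(start, aln, MODEL, max_nni_rounds=0)
        assert out.same_topology(start)

    def test_likelihood_never_decreases(self):
        aln = self._aln(2)
        start = nj_tree(distance_matrix(aln, MODEL))
        engine = TreeLikelihood(aln, MODEL)
        before = engine.loglik(start)
        out = ml_refine(start, aln, MODEL, max_nni_rounds=3)
        assert engine.loglik(out) >= before - 1e-9

    def test_recovers_generating_topology(self):
        wins = 0
        for seed in range(5):
            aln = self._aln(seed, n=2000)
            start = nj_tree(distance_matrix(aln, MODEL))
            out = ml_refine(start, aln, MODEL, max_nni_rounds=3)
            wins += out.same_topology(self.TRUTH)
        assert wins >= 4

    def test_nni_escapes_a_wrong_start_topology(self):
        aln = self._aln(7, n=2000)
        wrong = Tree.from_newick(
            "((A:0.1,C:0.1):0.1,(B:0.1,D:0.1):0.1,E:0.2);")
        out = ml_refine(wrong, aln, MODEL, max_nni_rounds=5)
        assert out.same_topology(self.TRUTH)


class TestBootstrap:
    def test_perfectly_supported_split_gets_100(self):
        # repeated identical columns carrying one clean split
        rows = {"A": "KK" * 40, "B": "KK" * 40,
                "C": "DD" * 40, "D": "DD" * 40}
        aln = Alignment(list(rows), list(rows.values()))
        t = bootstrap_support(aln, MODEL, n_reps=30, seed=1)
        supports = [n.support for n in t.postorder()
                    if n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_supports_within_range_and_deterministic(self):
        tree = Tree.from_newick(
            "((A:0.2,B:0.2):0.08,(C:0.2,D:0.2):0.08,E:0.3);")
        rows = simulate_protein_rows(tree, 250, seed=9)
        aln = Alignment(list(rows), list(rows.values()))
        t1 = bootstrap_support(aln, MODEL, n_reps=20, seed=4)
        t2 = bootstrap_support(aln, MODEL, n_reps=20, seed=4)
        s1 = sorted(n.support for n in t1.postorder()
                    if n.support is not None)
        s2 = sorted(n.support for n in t2.postorder()
                    if n.support is not None)
        assert s1 == s2
        assert all(0.0 <= s <= 100.0 for s in s1)
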