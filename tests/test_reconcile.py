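"""LCA reconciliation, presence matrices, loss asymmetry."""

import itertools
import math

import numpy as np
import pytest

from traitrad.iocore import FormatError, TipSpeciesMap, TraitTable
from traitrad.reconcile import (count_clade_duplications, lca_reconcile,
                                loss_asymmetry, occurrence_presence_matrix,
                                presence_matrix)
from traitrad.simulate import DupEvent, simulate_gene_family, \
    simulate_species_tree
from traitrad.tree import Tree


def oracle_duplications(gene_tree, species_tree, tip_map):
    """Independent check of the duplication condition per node.

    Maps every gene node to the smallest species clade containing its
    descendant species by scanning all species nodes (no shared code
    with the implementation's depth-walk LCA).
    """
    sp_sets = {}
    for n in species_tree.postorder():
        sp_sets[id(n)] = (n, frozenset(t.label for t in n.leaves()))

    def smallest_containing(species):
        best = None
        for node, tips in sp_sets.values():
            if species <= tips:
                if best is None or len(tips) < len(best[1]):
                    best = (node, tips)
        return best[0]

    gene_species = {}
    for g in gene_tree.postorder():
        if g.is_leaf:
            gene_species[id(g)] = frozenset([tip_map(g.label)])
        else:
            gene_species[id(g)] = frozenset().union(
                *(gene_species[id(c)] for c in g.children))
    dups = set()
    for g in gene_tree.postorder():
        if g.is_leaf:
            continue
        m = smallest_containing(gene_species[id(g)])
        for c in g.children:
            if smallest_containing(gene_species[id(c)]) is m:
                dups.add(id(g))
                break
    return dups


class TestLcaReconcile:
    def test_isomorphic_trees_have_no_duplications(self):
        sp = simulate_species_tree(8, seed=1)
        gt, _ = simulate_gene_family(sp, [])
        recon = lca_reconcile(gt, sp)
        assert recon.n_duplications == 0

    def test_textbook_root_duplication(self):
        sp = Tree.from_newick("(A:1,B:1);")
        gt = Tree.from_newick("((A@1:1,B@1:1):1,(A@2:1,B@2:1):1);")
        recon = lca_reconcile(gt, sp)
        assert recon.n_duplications == 1
        dup = recon.duplication_nodes[0]
        assert dup is gt.root
        assert recon.placements[id(dup)] is sp.root

    def test_unmapped_tip_named_in_error(self):
        sp = Tree.from_newick("(A:1,B:1);")
        gt = Tree.from_newick("(A@1:1,Q@1:1);")
        with pytest.raises(FormatError, match="Q@1"):
            lca_reconcile(gt, sp)

    def test_matches_bruteforce_oracle_on_random_pairs(self, rng):
        from conftest import random_rooted_tree
        tip_map = TipSpeciesMap()
        for _ in range(40):
            n_sp = int(rng.integers(2, 6))
            sp = random_rooted_tree(rng, n_sp,
                                    labels=[f"s{i}" for i in range(n_sp)])
            n_genes = int(rng.integers(2, 9))
            gene_labels = [f"s{rng.integers(n_sp)}@g{i}"
                           for i in range(n_genes)]
            gt = random_rooted_tree(rng, n_genes, labels=gene_labels)
            recon = lca_reconcile(gt, sp, tip_map)
            assert {id(d) for d in recon.duplication_nodes} == \
                oracle_duplications(gt, sp, tip_map)

    def test_lca_map_is_monotone_up_the_tree(self, small_scenario):
        sc = small_scenario
        recon = lca_reconcile(sc.gene_tree, sc.species_tree)
        anc_of = {}
        for n in sc.species_tree.preorder():
            anc_of[id(n)] = ({id(n)} if n.parent is None
                             else anc_of[id(n.parent)] | {id(n)})
        for g in sc.gene_tree.postorder():
            if g.parent is None:
                continue
            child_map = recon.lca_map[id(g)]
            parent_map = recon.lca_map[id(g.parent)]
            assert id(parent_map) in anc_of[id(child_map)]

    def test_simulated_duplications_counted_exactly_without_losses(self):
        sp = simulate_species_tree(10, seed=3)
        clade = sorted(t.label for t in sp.root.children[0].leaves())
        if len(clade) < 2:
            clade = sorted(t.label for t in sp.root.children[1].leaves())
        gt, truth = simulate_gene_family(
            sp, [DupEvent(clade, "anc", ("a", "b"))])
        recon = lca_reconcile(gt, sp)
        assert recon.n_duplications == len(truth.duplication_labels) == 1

    def test_clade_duplication_counts_partition(self, small_scenario):
        sc = small_scenario
        recon = lca_reconcile(sc.gene_tree, sc.species_tree)
        root = sc.gene_tree.root
        total = sum(count_clade_duplications(recon, c)
                    for c in root.children)
        root_is_dup = any(d is root for d in recon.duplication_nodes)
        assert total + root_is_dup == recon.n_duplications


class TestPresenceMatrix:
    def test_membership_and_missing_species(self):
        gt = Tree.from_newick("((A@a:1,B@a:1):1,(A@b:1,B@b:1):1);")
        pm = presence_matrix(gt, {"alpha": ["A@a", "B@a"],
                                  "beta": ["A@b"]},
                             ["A", "B", "C"])
        assert pm.present("A", "alpha") and pm.present("B", "alpha")
        assert pm.present("A", "beta") and not pm.present("B", "beta")
        assert not pm.present("C", "alpha") and not pm.present("C", "beta")

    def test_overlapping_clades_rejected(self):
        gt = Tree.from_newick("(A@a:1,B@a:1);")
        with pytest.raises(FormatError, match="overlap"):
            presence_matrix(gt, {"x": ["A@a"], "y": ["A@a"]}, ["A", "B"])

    def test_reported_doda_occurrence_pattern(self):
        """The published DODA counts: beta in 15/15 anthocyanic
        transcriptomes, alpha in exactly one (Spergularia media)."""
        anth = [f"anth_sp{i}" for i in range(1, 15)] + ["Spergularia_media"]
        occurrences = {"DODA-alpha": ["Spergularia_media"],
                       "DODA-beta": list(anth)}
        traits = TraitTable({s: "anthocyanin" for s in anth})
        pm = occurrence_presence_matrix(occurrences, anth, traits)
        assert pm.column_sum("DODA-beta", "anthocyanin") == 15
        assert pm.column_sum("DODA-alpha", "anthocyanin") == 1


class TestLossAsymmetry:
    @staticmethod
    def hypergeom_two_sided(a, b, c, d):
        """Fisher two-sided p by full hypergeometric enumeration."""
        n1, n2 = a + b, c + d
        k = a + c

        def pmf(x):
            return (math.comb(n1, x) * math.comb(n2, k - x)
                    / math.comb(n1 + n2, k))
        p_obs = pmf(a)
        total = 0.0
        for x in range(max(0, k - n2), min(k, n1) + 1):
            p = pmf(x)
            if p <= p_obs * (1 + 1e-9):
                total += p
        return total

    def test_identical_columns_give_p_one(self):
        gt = Tree.from_newick("((A@a:1,B@a:1):1,(A@b:1,B@b:1):1);")
        traits = TraitTable({"A": "anthocyanin", "B": "anthocyanin"})
        pm = presence_matrix(gt, {"alpha": ["A@a", "B@a"],
                                  "beta": ["A@b", "B@b"]},
                             ["A", "B"], traits=traits)
        res = loss_asymmetry(pm, "alpha", "beta", "anthocyanin")
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration_oracle(self):
        occurrences = {"a": [], "b": [f"s{i}" for i in range(15)]}
        species = [f"s{i}" for i in range(15)]
        traits = TraitTable({s: "anthocyanin" for s in species})
        pm = occurrence_presence_matrix(occurrences, species, traits)
        res = loss_asymmetry(pm, "a", "b", "anthocyanin")
        assert res.table == [[0, 15], [15, 0]]
        assert res.p_value == pytest.approx(
            self.hypergeom_two_sided(0, 15, 15, 0), rel=1e-9)

    def test_paper_reported_doda_table(self):
        """alpha present 1 / absent 14; beta present 15 / absent 0."""
        anth = [f"sp{i}" for i in range(14)] + ["Spergularia_media"]
        occurrences = {"alpha": ["Spergularia_media"], "beta": list(anth)}
        traits = TraitTable({s: "anthocyanin" for s in anth})
        pm = occurrence_presence_matrix(occurrences, anth, traits)
        res = loss_asymmetry(pm, "alpha", "beta", "anthocyanin")
        assert res.table == [[1, 14], [15, 0]]
        assert res.p_value < 1e-5

    def test_absent_trait_state_rejected(self):
        occurrences = {"a": ["s1"], "b": ["s1"]}
        traits = TraitTable({"s1": "betalain"})
        pm = occurrence_presence_matrix(occurrences, ["s1"], traits)
        with pytest.raises(FormatError):
            loss_asymmetry(pm, "a", "b", "anthocyanin")
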