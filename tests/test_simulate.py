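"""Synthetic-data generator: determinism and truth consistency."""

import numpy as np
import pytest

from traitrad.iocore import TipSpeciesMap
from traitrad.simulate import (ClusterSpec, CodonSimParams, DupEvent,
                               LossEvent, ScenarioConfig,
                               generate_scenario, make_cluster_annotation,
                               simulate_codon_alignment,
                               simulate_gene_family, simulate_species_tree,
                               simulate_trait, write_scenario)
from traitrad.tree import Tree, TreeError


class TestSpeciesTree:
    def test_two_species_is_a_cherry(self):
        t = simulate_species_tree(2, seed=1)
        assert t.n_tips == 2 and len(t.root.children) == 2

    def test_counts_and_determinism(self):
        a = simulate_species_tree(50, seed=9)
        b = simulate_species_tree(50, seed=9)
        assert a.n_tips == 50
        assert len(a.internal_nodes()) == 49
        assert a.to_newick() == b.to_newick()

    def test_ultrametric(self):
        t = simulate_species_tree(20, seed=3, height=1.0)
        depths = []
        h = {id(t.root): 0.0}
        for n in t.preorder():
            for c in n.children:
                h[id(c)] = h[id(n)] + c.length
                if c.is_leaf:
                    depths.append(h[id(c)])
        assert max(depths) - min(depths) < 1e-9
        assert abs(max(depths) - 1.0) < 1e-9

    def test_rejects_tiny(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, seed=0)


class TestTrait:
    def test_zero_rate_keeps_root_state_everywhere(self):
        t = simulate_species_tree(12, seed=2)
        traits, nodes = simulate_trait(t, 0.0, seed=2)
        assert set(traits.states.values()) == {"anthocyanin"}

    def test_forced_gain_marks_whole_clade(self):
        t = simulate_species_tree(12, seed=2)
        clade = [x.label for x in t.root.children[0].leaves()]
        if len(clade) < 2:
            clade = [x.label for x in t.root.children[1].leaves()]
        traits, _ = simulate_trait(
            t, 0.0, forced_events={"gain": clade}, seed=2)
        for tip in t.tip_labels():
            expect = "betalain" if tip in clade else "anthocyanin"
            assert traits[tip] == expect

    def test_reversal_must_nest_inside_gain(self):
        t = simulate_species_tree(12, seed=2)
        clade = [x.label for x in t.root.children[0].leaves()]
        outside = [x for x in t.tip_labels() if x not in clade][:1]
        with pytest.raises(TreeError, match="reversal"):
            simulate_trait(t, 0.0, forced_events={
                "gain": clade, "reversals": [outside]}, seed=2)

    def test_high_rate_visits_both_states(self):
        t = simulate_species_tree(200, seed=4)
        traits, _ = simulate_trait(t, 1.0, seed=4)
        states = set(traits.states.values())
        assert states == {"anthocyanin", "betalain"}

    def test_rate_to_infinity_equilibrates_states(self):
        """Tip-state frequencies approach 1/2 each at very high rate."""
        from scipy.stats import chisquare
        counts = np.zeros(2)
        for rep in range(10):
            t = simulate_species_tree(100, seed=100 + rep)
            traits, _ = simulate_trait(t, 50.0, seed=100 + rep)
            vals = list(traits.states.values())
            counts[0] += vals.count("anthocyanin")
            counts[1] += vals.count("betalain")
        p = chisquare(counts).pvalue
        assert p > 1e-4


class TestGeneFamily:
    def test_no_events_gives_species_topology(self):
        sp = simulate_species_tree(10, seed=5)
        gt, truth = simulate_gene_family(sp, [], [])
        mapped = {t: t.split("@")[0] for t in gt.tip_labels()}
        assert sorted(mapped.values()) == sorted(sp.tip_labels())
        relabeled = gt.copy()
        for tip in relabeled.tips():
            tip.label = tip.label.split("@")[0]
        assert relabeled.same_topology(sp)
        assert truth.duplication_labels == []

    def test_root_duplication_doubles_the_tree(self):
        sp = Tree.from_newick("(A:1,B:1);")
        gt, truth = simulate_gene_family(
            sp, [DupEvent(["A", "B"], "anc", ("c1", "c2"))])
        assert sorted(gt.tip_labels()) == ["A@c1", "A@c2", "B@c1", "B@c2"]
        assert len(truth.duplication_labels) == 1
        c1 = gt.mrca(["A@c1", "B@c1"])
        assert {t.label for t in c1.leaves()} == {"A@c1", "B@c1"}

    def test_alpha_loss_reproduces_reversal_absence(self, small_scenario):
        sc = small_scenario
        tsm = TipSpeciesMap()
        alpha_species = {tsm(t) for t in sc.alpha_tips}
        assert not (alpha_species & set(sc.reversal_species))
        for sp in sc.reversal_species:
            assert "beta" in sc.family_truth.presence[sp]

    def test_presence_truth_matches_tips(self, small_scenario):
        sc = small_scenario
        rebuilt: dict = {s: set() for s in sc.species_tree.tip_labels()}
        for t in sc.gene_tree.tip_labels():
            spp, copy = t.split("@", 1)
            rebuilt[spp].add(copy)
        assert rebuilt == sc.family_truth.presence

    def test_emptying_family_rejected(self):
        sp = Tree.from_newick("(A:1,B:1);")
        with pytest.raises(TreeError, match="whole family"):
            simulate_gene_family(sp, [], [LossEvent(["anc"], ["A", "B"])])


class TestCodonSim:
    def test_class_counts_near_binomial_expectation(self):
        tree = Tree.from_newick("(A:0.2,B:0.2);")
        params = CodonSimParams(p0=0.45, p1=0.45, omega2=5.0, n_codons=500)
        _, truth = simulate_codon_alignment(tree, params, seed=11)
        n2 = (truth.site_classes >= 2).sum()
        # p2 = 0.1 of 500 -> ~50; allow 4 sigma
        assert 20 <= n2 <= 80

    def test_diagnostic_overwrite_invariant_per_clade(self):
        tree = Tree.from_newick("((A:0.4,B:0.4):0.2,(C:0.4,D:0.4):0.2);")
        params = CodonSimParams(n_codons=50)
        caln, truth = simulate_codon_alignment(
            tree, params, diagnostic_spec=[(10, "P", "N")],
            clade_a_tips=["A", "B"], clade_b_tips=["C", "D"], seed=1)
        from traitrad.gencode import translate_cds
        aa = {sid: translate_cds(row) for sid, row in
              zip(caln.ids, caln.rows)}
        assert {aa["A"][9], aa["B"][9]} == {"P"}
        assert {aa["C"][9], aa["D"][9]} == {"N"}

    def test_no_stop_codons_emitted(self):
        tree = Tree.from_newick("(A:0.5,B:0.5);")
        caln, _ = simulate_codon_alignment(
            tree, CodonSimParams(n_codons=200), seed=3)
        # CodonAlignment construction would already reject stops
        from traitrad.gencode import STOP_CODONS
        for row in caln.rows:
            for k in range(0, len(row), 3):
                assert row[k:k + 3] not in STOP_CODONS


class TestClusterAnnotation:
    def test_paper_like_cluster_one_intervening(self):
        spec = ClusterSpec(distance=50000, n_intervening=1)
        anns = make_cluster_annotation(spec)
        focal = [a for a in anns if a.gene_id in spec.focal_ids]
        inner = [a for a in anns
                 if a.chromosome == spec.chromosome
                 and a.gene_id not in spec.focal_ids
                 and a.start > min(f.end for f in focal)
                 and a.end < max(f.start for f in focal)]
        assert len(inner) == 1

    def test_zero_intervening_adjacent(self):
        anns = make_cluster_annotation(
            ClusterSpec(distance=5000, n_intervening=0))
        from traitrad.diagnostics import gene_clusters
        rep = gene_clusters(anns, ClusterSpec().focal_ids)
        assert rep.intervening_genes == 0

    def test_impossible_packing_rejected(self):
        with pytest.raises(ValueError, match="pack"):
            make_cluster_annotation(
                ClusterSpec(distance=1000, n_intervening=3))


class TestScenario:
    def test_full_determinism_byte_level(self, tmp_path):
        cfg = ScenarioConfig(seed=8, n_species=12)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_scenario(generate_scenario(cfg), d1)
        write_scenario(generate_scenario(cfg), d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_seed_is_mandatory(self):
        with pytest.raises(TypeError):
            ScenarioConfig()  # noqa: seed is positional

    def test_proportions_validated(self):
        with pytest.raises(ValueError):
            CodonSimParams(p0=0.8, p1=0.4)
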