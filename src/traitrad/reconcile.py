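"""Gene-tree / species-tree reconciliation by LCA mapping.

Each gene-tree node maps to the most recent common ancestor, in the
species tree, of the species of its descendant gene copies.  A node is
a duplication iff it maps to the same species node as at least one of
its children — the parsimony (minimum) duplication count.  Each
duplication is placed on the mapped species node together with its
parent edge, encoding "arose just before the divergence of X".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from scipy.stats import fisher_exact

from .iocore import FormatError, TipSpeciesMap, TraitTable
from .tree import Node, Tree, TreeError


@dataclass
class ReconciliationResult:
    gene_tree: Tree
    species_tree: Tree
    lca_map: dict                 # id(gene node) -> species Node
    duplication_nodes: list       # gene Nodes
    placements: dict              # id(gene node) -> species Node

    @property
    def n_duplications(self) -> int:
        return len(self.duplication_nodes)

    def placement_edge(self, gene_node: Node):
        """(species node, its parent or None): the placement interval."""
        sp = self.placements[id(gene_node)]
        return sp, sp.parent


def _species_label(node: Node, species_tree: Tree) -> str:
    """Human-readable name of a species node (tip label or clade)."""
    if node.is_leaf:
        return node.label
    return "mrca(" + ",".join(sorted(
        t.label for t in node.leaves())[:2]) + ",...)"


def lca_reconcile(gene_tree: Tree, species_tree: Tree,
                  tip_map: Optional[TipSpeciesMap] = None) -> ReconciliationResult:
    """Standard LCA reconciliation of a rooted gene tree.

    Every gene tip must resolve (via ``tip_map``) to a species-tree tip.
    """
    if not gene_tree.rooted or not species_tree.rooted:
        raise TreeError("reconciliation requires rooted trees")
    tip_map = tip_map or TipSpeciesMap()
    sp_tips = {t.label: t for t in species_tree.tips()}

    # species-node depth (root=0) for LCA computation
    depth: dict[int, int] = {}
    for n in species_tree.preorder():
        depth[id(n)] = 0 if n.parent is None else depth[id(n.parent)] + 1

    def sp_lca(a: Node, b: Node) -> Node:
        while a is not b:
            if depth[id(a)] >= depth[id(b)]:
                a = a.parent
            else:
                b = b.parent
        return a

    lca_map: dict[int, Node] = {}
    for g in gene_tree.postorder():
        if g.is_leaf:
            sp = tip_map(g.label)
            if sp not in sp_tips:
                raise FormatError(
                    f"gene tip {g.label!r} maps to unknown species {sp!r}")
            lca_map[id(g)] = sp_tips[sp]
        else:
            m = None
            for c in g.children:
                m = lca_map[id(c)] if m is None else sp_lca(m, lca_map[id(c)])
            lca_map[id(g)] = m

    dups = [g for g in gene_tree.postorder()
            if not g.is_leaf and any(lca_map[id(c)] is lca_map[id(g)]
                                     for c in g.children)]
    placements = {id(g): lca_map[id(g)] for g in dups}
    return ReconciliationResult(gene_tree, species_tree, lca_map, dups,
                                placements)


def count_clade_duplications(recon: ReconciliationResult,
                             clade_root: Node) -> int:
    """Number of duplication nodes within (and including) a gene clade."""
    inside = {id(n) for n in clade_root.postorder()}
    return sum(1 for d in recon.duplication_nodes if id(d) in inside)


@dataclass
class PresenceMatrix:
    """Species x paralog-clade boolean presence, with trait states."""

    table: pd.DataFrame           # bool entries; index=species
    trait_states: dict            # species -> state (may be absent)

    def present(self, species: str, clade: str) -> bool:
        return bool(self.table.loc[species, clade])

    def column_sum(self, clade: str, trait_state: Optional[str] = None) -> int:
        tab = self.table
        if trait_state is not None:
            keep = [s for s in tab.index
                    if self.trait_states.get(s) == trait_state]
            tab = tab.loc[keep]
        return int(tab[clade].sum())


def presence_matrix(gene_tree: Tree, named_clades: dict,
                    species_list: Iterable[str],
                    tip_map: Optional[TipSpeciesMap] = None,
                    traits: Optional[TraitTable] = None) -> PresenceMatrix:
    """Presence/absence of each named paralog clade per species.

    ``named_clades`` maps clade name -> iterable of gene-tip labels
    (the clade's tips).  Clades must be disjoint.  A species appears
    present in a clade iff at least one of its gene copies is a tip of
    that clade; species absent from the gene tree get all-false rows.
    """
    tip_map = tip_map or TipSpeciesMap()
    species_list = list(species_list)
    sets = {name: set(tips) for name, tips in named_clades.items()}
    names = list(sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if sets[a] & sets[b]:
                raise FormatError(f"clades {a!r} and {b!r} overlap")
    tree_tips = set(gene_tree.tip_labels())
    for name, tips in sets.items():
        missing = tips - tree_tips
        if missing:
            raise FormatError(
                f"clade {name!r} tips not in gene tree: {sorted(missing)}")
    data = {}
    for name, tips in sets.items():
        sp_present = {tip_map(t) for t in tips}
        data[name] = [sp in sp_present for sp in species_list]
    table = pd.DataFrame(data, index=species_list)
    states = {}
    if traits is not None:
        states = {sp: traits[sp] for sp in species_list if sp in traits}
    return PresenceMatrix(table, states)


def occurrence_presence_matrix(occurrences: dict, species_list: Iterable[str],
                               traits: Optional[TraitTable] = None) -> PresenceMatrix:
    """Presence matrix from explicit clade -> species occurrence lists."""
    species_list = list(species_list)
    data = {name: [sp in set(spp) for sp in species_list]
            for name, spp in occurrences.items()}
    table = pd.DataFrame(data, index=species_list)
    states = {}
    if traits is not None:
        states = {sp: traits[sp] for sp in species_list if sp in traits}
    return PresenceMatrix(table, states)


@dataclass
class LossAsymmetry:
    """2x2 presence/absence counts for two clades plus Fisher p-value."""

    clade_a: str
    clade_b: str
    trait_state: str
    a_present: int
    a_absent: int
    b_present: int
    b_absent: int
    p_value: float

    @property
    def table(self):
        return [[self.a_present, self.a_absent],
                [self.b_present, self.b_absent]]


def loss_asymmetry(matrix: PresenceMatrix, clade_a: str, clade_b: str,
                   trait_state: str) -> LossAsymmetry:
    """Contrast presence of two clades among species of one trait state.

    The two-sided Fisher exact test is an add-on summary statistic of
    the asymmetry, not part of the reconciliation itself.
    """
    species = [s for s in matrix.table.index
               if matrix.trait_states.get(s) == trait_state]
    if not species:
        raise FormatError(f"no species with trait state {trait_state!r}")
    a_pres = sum(matrix.present(s, clade_a) for s in species)
    b_pres = sum(matrix.present(s, clade_b) for s in species)
    n = len(species)
    table = [[a_pres, n - a_pres], [b_pres, n - b_pres]]
    _, p = fisher_exact(table, alternative="two-sided")
    return LossAsymmetry(clade_a, clade_b, trait_state,
                         a_pres, n - a_pres, b_pres, n - b_pres, float(p))
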