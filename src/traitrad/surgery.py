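"""Tree-editing rules used during iterative gene-tree refinement.

Long internal branches (default > 1.5 substitutions/site) are taken to
join distantly related paralogs or assembly artifacts: the edge is cut
and the component holding the anchor sequence is kept.  Long terminal
branches (default > 1.0) drop the tip.  Both comparisons are strictly
greater-than.  Anchored clade extraction pulls out the ingroup of
interest together with its closest outgroup lineages, and rooting
places the root on the stem of the outgroup set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .tree import Node, Tree, TreeError


@dataclass
class SurgeryConfig:
    max_branch: float = 1.5
    max_tip_branch: float = 1.0
    anchor_id: Optional[str] = None
    outgroup_labels: list = field(default_factory=list)

    def __post_init__(self):
        if self.max_branch <= 0 or self.max_tip_branch <= 0:
            raise ValueError("surgery thresholds must be positive")


def _detach_to_tree(node: Node) -> Tree:
    """Make ``node`` the root of its own tree (lengths preserved)."""
    node.parent = None
    node.length = None
    t = Tree(node, rooted=len(node.children) == 2)
    t.suppress_unifurcations()
    return t


def prune_long_branches(tree: Tree, max_branch: float = 1.5,
                        anchor_id: Optional[str] = None,
                        removed: Optional[list] = None) -> Tree:
    """Cut every edge longer than ``max_branch``; keep the anchor side.

    Applied repeatedly until no offending edge remains.  ``removed``
    (if given) collects the discarded tip labels.
    """
    if anchor_id is None:
        raise TreeError("prune_long_branches requires an anchor tip")
    tree = tree.copy()
    tree.find_tip(anchor_id)  # raises if absent
    while True:
        offender = None
        for n in tree.postorder():
            if n.parent is not None and (n.length or 0.0) > max_branch:
                offender = n
                break
        if offender is None:
            return tree
        below = {t.label for t in offender.leaves()}
        parent = offender.parent
        parent.remove_child(offender)
        if anchor_id in below:
            lost = set(tree.tip_labels()) - below
            if removed is not None:
                removed.extend(sorted(lost))
            tree = _detach_to_tree(offender)
        else:
            if removed is not None:
                removed.extend(sorted(below))
            tree.suppress_unifurcations()
            tree = Tree(tree.root, rooted=len(tree.root.children) == 2)


def prune_long_tips(tree: Tree, max_tip_branch: float = 1.0,
                    removed: Optional[list] = None) -> Tree:
    """Drop tips whose pendant edge is strictly longer than the cap."""
    if tree.n_tips < 3:
        raise TreeError("prune_long_tips needs a tree with >= 3 tips")
    tree = tree.copy()
    victims = [t for t in tree.tips() if (t.length or 0.0) > max_tip_branch]
    if removed is not None:
        removed.extend(sorted(t.label for t in victims))
    if len(victims) >= tree.n_tips - 1:
        raise TreeError("tip pruning would leave fewer than 2 tips")
    for v in victims:
        v.parent.remove_child(v)
    tree.suppress_unifurcations()
    return Tree(tree.root, rooted=len(tree.root.children) == 2)


def extract_anchored_clade(tree: Tree, anchor_id: str,
                           target_tips: Optional[Iterable[str]] = None,
                           n_outgroup_lineages: int = 1) -> Tree:
    """Smallest clade holding the anchor plus targets (or +n sisters).

    With ``target_tips`` the result is the MRCA clade of the anchor and
    all targets.  Without it, the anchor's clade is expanded by
    ``n_outgroup_lineages`` successively more inclusive sister lineages
    (default 1), mirroring "together with the closest outgroups".
    """
    if not tree.rooted:
        raise TreeError("clade extraction requires a rooted tree")
    anchor = tree.find_tip(anchor_id)
    if target_tips is not None:
        node = tree.mrca(set(target_tips) | {anchor_id})
    else:
        node = anchor
        for _ in range(n_outgroup_lineages):
            if node.parent is None:
                break
            node = node.parent
    if node.parent is None:
        return tree.copy()
    sub = Tree(node.copy(), rooted=True)
    sub.root.parent = None
    sub.root.length = None
    sub.rooted = len(sub.root.children) == 2
    return sub


def root_with_outgroup(tree: Tree, outgroup_labels: Iterable[str]) -> Tree:
    """Root on the edge subtending the outgroup clade.

    The root is the midpoint of the edge above the smallest clade that
    contains every outgroup label present in the tree.  If that clade
    spans the whole tree the outgroup is not separable.
    """
    present = [lab for lab in outgroup_labels if lab in tree.tip_labels()]
    if not present:
        raise TreeError("no outgroup tip present in the tree")
    work = tree.copy()
    if len(present) == 1:
        node = work.find_tip(present[0])
    else:
        node = work.mrca(present)
        if node.parent is None:
            # outgroup clade is the whole tree; try the complement side
            ts = work.tipsets()
            comp = set(work.tip_labels()) - set(present)
            cand = [n for n in work.postorder() if n.parent is not None
                    and ts[id(n)] == frozenset(comp)]
            if not cand:
                raise TreeError("outgroup is not separable on this tree")
            node = cand[0]
    if node.parent is None:
        raise TreeError("outgroup is not separable on this tree")
    return work.reroot_on_edge(node, fraction=0.5)
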