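"""Phylogenetic tree container used throughout the pipeline.

A :class:`Tree` is a rooted or unrooted phylogeny stored as linked
:class:`Node` objects.  Branch lengths are in expected substitutions per
site; internal nodes may carry bootstrap support percentages (0-100).
Newick parsing is delegated to :mod:`dendropy`; writing is a small
recursion so that support values round-trip exactly as internal labels.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Iterator, Optional

import dendropy


class TreeError(ValueError):
    """Raised for malformed or inconsistent trees."""


class Node:
    """One vertex of a phylogeny.

    Attributes
    ----------
    label : str or None
        Tip label (unique within the tree) or an optional internal name.
    length : float or None
        Length of the branch subtending this node (substitutions/site).
    support : float or None
        Bootstrap support percentage of the subtending edge (internal
        nodes only).
    """

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(self, label: Optional[str] = None,
                 length: Optional[float] = None,
                 support: Optional[float] = None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    # -- structure -------------------------------------------------
    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack: list[tuple[Node, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    def leaves(self) -> Iterator["Node"]:
        return (n for n in self.postorder() if n.is_leaf)

    def copy(self) -> "Node":
        clone = Node(self.label, self.length, self.support)
        for c in self.children:
            clone.add_child(c.copy())
        return clone

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '(internal)'} len={self.length}>"


class Tree:
    """A phylogeny with unique tip labels.

    Parameters
    ----------
    root : Node
        Root of the linked node structure.  For an unrooted tree the
        root is the conventional trifurcating anchor node.
    rooted : bool
        Whether the root is a true bifurcating root.
    """

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self._check()

    # -- validation ------------------------------------------------
    def _check(self) -> None:
        labels = [n.label for n in self.root.leaves()]
        if any(lab is None or lab == "" for lab in labels):
            raise TreeError("every tip must be labelled")
        dup = {lab for lab in labels if labels.count(lab) > 1}
        if dup:
            raise TreeError(f"duplicate tip labels: {sorted(dup)}")
        for n in self.root.postorder():
            if n.length is not None and n.length < 0:
                raise TreeError(f"negative branch length on {n.label!r}")

    # -- traversal helpers -----------------------------------------
    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def tips(self) -> list[Node]:
        return list(self.root.leaves())

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def find_tip(self, label: str) -> Node:
        for n in self.root.leaves():
            if n.label == label:
                return n
        raise TreeError(f"tip {label!r} not found in tree")

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), rooted=self.rooted)

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the given tip labels."""
        labels = set(labels)
        if not labels:
            raise TreeError("mrca of an empty label set")
        missing = labels - set(self.tip_labels())
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")
        # bottom-up: smallest node whose tip set covers `labels`
        below: dict[int, set] = {}
        for n in self.postorder():
            s = {n.label} if n.is_leaf else set().union(
                *(below[id(c)] for c in n.children))
            below[id(n)] = s
            if labels <= s:
                return n
        raise AssertionError("unreachable: root covers all tips")

    def tipsets(self) -> dict[int, frozenset]:
        """Map id(node) -> frozenset of descendant tip labels."""
        out: dict[int, frozenset] = {}
        for n in self.postorder():
            if n.is_leaf:
                out[id(n)] = frozenset([n.label])
            else:
                out[id(n)] = frozenset().union(
                    *(out[id(c)] for c in n.children))
        return out

    # -- topology comparison ---------------------------------------
    def bipartitions(self) -> set[frozenset]:
        """Non-trivial unrooted bipartitions, canonicalised.

        Each internal edge splits the tips in two; the side *not*
        containing the lexicographically smallest tip is returned, so
        the representation is rooting-invariant.
        """
        all_tips = frozenset(self.tip_labels())
        ref = min(all_tips)
        out: set[frozenset] = set()
        ts = self.tipsets()
        for n in self.postorder():
            if n is self.root or n.is_leaf:
                continue
            side = ts[id(n)]
            if ref in side:
                side = all_tips - side
            if 1 < len(side) < len(all_tips) - 1:
                out.add(side)
        return out

    def same_topology(self, other: "Tree") -> bool:
        """Unrooted-topology equality over a shared tip set."""
        if set(self.tip_labels()) != set(other.tip_labels()):
            return False
        return self.bipartitions() == other.bipartitions()

    # -- editing helpers -------------------------------------------
    def suppress_unifurcations(self) -> None:
        """Remove degree-2 internal nodes, summing branch lengths."""
        changed = True
        while changed:
            changed = False
            for n in list(self.root.postorder()):
                if n.is_leaf or len(n.children) != 1:
                    continue
                child = n.children[0]
                if n.parent is None:
                    # root with one child: make the child the new root
                    child.parent = None
                    child.length = None
                    self.root = child
                else:
                    extra = n.length or 0.0
                    if child.length is not None:
                        child.length += extra
                    parent = n.parent
                    idx = parent.children.index(n)
                    parent.children[idx] = child
                    child.parent = parent
                changed = True
                break

    def unroot(self) -> "Tree":
        """Collapse a bifurcating root into a trifurcation."""
        t = self.copy()
        r = t.root
        if len(r.children) == 2:
            a, b = r.children
            keep, fold = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:
                t.rooted = False
                return t
            total = (a.length or 0.0) + (b.length or 0.0)
            r.children = list(keep.children)
            for c in r.children:
                c.parent = r
            fold.length = total
            fold.parent = r
            r.children.append(fold)
            r.support = None
        t.rooted = False
        return t

    def reroot_on_edge(self, child: Node, fraction: float = 0.5) -> "Tree":
        """Return a new tree rooted on the edge above ``child``.

        ``child`` must belong to *this* tree.  The edge is split at
        ``fraction`` of its length measured from the child end.
        """
        if child.parent is None:
            raise TreeError("cannot root on the root's (absent) edge")
        length = child.length if child.length is not None else 0.0
        new_root = Node()
        below_len = length * fraction
        above_len = length - below_len

        old_parent = child.parent
        old_parent.remove_child(child)
        new_root.add_child(child)
        child.length = below_len

        # walk from old_parent up to the old root, reversing edges
        node = old_parent
        carry_len = above_len
        carry_sup = child.support
        attach = new_root
        while node is not None:
            nxt = node.parent
            nxt_len = node.length
            nxt_sup = node.support
            if nxt is not None:
                nxt.remove_child(node)
            node.length = carry_len
            node.support = carry_sup
            attach.add_child(node)
            attach = node
            carry_len = nxt_len
            carry_sup = nxt_sup
            node = nxt
        out = Tree(new_root, rooted=True)
        out.suppress_unifurcations()
        return out

    # -- newick I/O ------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse a newick string (branch lengths, internal support)."""
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True)
        except Exception as exc:
            raise TreeError(f"newick parse error: {exc}") from exc

        def convert(dnode) -> Node:
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon else dnode.label
                n = Node(label=label, length=dnode.edge.length)
            else:
                n = Node(length=dnode.edge.length)
                raw = dnode.label
                if raw is not None:
                    try:
                        n.support = float(raw)
                    except ValueError:
                        n.label = raw
                for c in dnode.child_nodes():
                    n.add_child(convert(c))
            return n

        root = convert(dtree.seed_node)
        rooted = len(root.children) == 2
        return cls(root, rooted=rooted)

    @classmethod
    def read(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        def fmt_len(x: float) -> str:
            return f"{x:.10g}"

        def fmt(n: Node) -> str:
            if n.is_leaf:
                s = _quote_label(n.label)
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if n.support is not None:
                    s += fmt_len(n.support)
                elif n.label:
                    s += _quote_label(n.label)
            if n.length is not None:
                s += ":" + fmt_len(n.length)
            return s

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree n_tips={self.n_tips} rooted={self.rooted}>"


def _quote_label(label: str) -> str:
    if any(c in label for c in "(),:;[] \t'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def path_length(tree: Tree, a: str, b: str) -> float:
    """Patristic distance between two tips (sum of branch lengths)."""
    na, nb = tree.find_tip(a), tree.find_tip(b)

    def ancestors(n: Node) -> list[Node]:
        out = []
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    anc_a = ancestors(na)
    anc_b = ancestors(nb)
    set_a = {id(x) for x in anc_a}
    lca = next(x for x in anc_b if id(x) in set_a)
    d = 0.0
    for n in anc_a:
        if n is lca:
            break
        d += n.length or 0.0
    for n in anc_b:
        if n is lca:
            break
        d += n.length or 0.0
    return d
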