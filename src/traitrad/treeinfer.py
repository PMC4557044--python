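"""Gene-tree estimation from protein alignments.

The engine is deliberately desk-scale: ML pairwise distances feed
neighbor-joining, and the NJ tree is refined by NNI hill-climbing with
per-edge branch-length optimization under the same likelihood (WAG by
default).  Bootstrap support resamples columns and rebuilds
distance/NJ trees, scoring bipartitions on the reference topology.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .iocore import Alignment, FormatError
from .protmodel import (DistanceMatrix, SubstitutionModel, T_MAX,
                        encode_protein_alignment, ml_distance_from_counts)
from .tree import Node, Tree, TreeError

_BL_MIN = 1e-9
_BL_MAX = T_MAX


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(D: DistanceMatrix) -> Tree:
    """Neighbor-joining tree (unrooted; trifurcating anchor node).

    Negative branch-length estimates are clamped to zero with the
    deficit moved to the adjacent branch; Q-criterion ties are broken
    by lexicographic order of the joined clusters' smallest tip labels.
    """
    n = len(D.ids)
    if n < 3:
        raise TreeError("neighbor joining requires at least 3 taxa")
    nodes = [Node(label=i, length=None) for i in D.ids]
    reps = list(D.ids)           # tie-break representative per cluster
    d = D.values.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                key = tuple(sorted((reps[active[ai]], reps[active[aj]])))
                if best is None or q < best[0] - 1e-12 or \
                        (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, ai, aj)
        _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        if lj < 0:
            li, lj = dij, 0.0
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances of the new cluster to the rest
        new_idx = len(nodes)
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dk = max(0.0, (d[i, k] + d[j, k] - dij) / 2.0)
            d[new_idx, k] = d[k, new_idx] = dk
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # final three limbs: closed-form lengths around the central node
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    li = max(0.0, (dij + dik - djk) / 2.0)
    lj = max(0.0, (dij + djk - dik) / 2.0)
    lk = max(0.0, (dik + djk - dij) / 2.0)
    center = Node()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = ln
        center.add_child(nodes[idx])
    return Tree(center, rooted=False)


# ---------------------------------------------------------------------------
# pruning likelihood engine
# ---------------------------------------------------------------------------

class TreeLikelihood:
    """Felsenstein pruning for a protein alignment under a fixed model.

    Site patterns are compressed once; the engine can then score any
    tree over the alignment's sequence set and optimize its branch
    lengths in place.
    """

    def __init__(self, aln: Alignment, model: Optional[SubstitutionModel] = None):
        self.model = model or SubstitutionModel()
        self.aln = aln
        codes = encode_protein_alignment(aln)
        patterns, weights = np.unique(codes, axis=1, return_counts=True)
        self.patterns = patterns          # (n_rows, n_pat)
        self.weights = weights.astype(float)
        self.row_index = {sid: r for r, sid in enumerate(aln.ids)}
        n_states = self.model.n_states
        eye = np.eye(n_states)
        self._tip_partial = {}
        for sid, r in self.row_index.items():
            codes_r = patterns[r]
            part = np.ones((patterns.shape[1], n_states))
            det = codes_r >= 0
            part[det] = eye[codes_r[det]]
            self._tip_partial[sid] = part

    # -- core passes -----------------------------------------------
    def _check_tree(self, tree: Tree) -> None:
        if set(tree.tip_labels()) != set(self.row_index):
            raise FormatError("tree tips do not match alignment rows")

    def _up_pass(self, tree: Tree, rate: float = 1.0):
        """Post-order partials and log-scalers keyed by node id."""
        up, scale = {}, {}
        for node in tree.postorder():
            if node.is_leaf:
                up[id(node)] = self._tip_partial[node.label]
                scale[id(node)] = np.zeros(self.patterns.shape[1])
            else:
                L = None
                sc = np.zeros(self.patterns.shape[1])
                for c in node.children:
                    P = self.model.transition(_bl(c), rate)
                    contrib = up[id(c)] @ P.T
                    L = contrib if L is None else L * contrib
                    sc += scale[id(c)]
                smax = L.max(axis=1)
                smax[smax == 0] = 1.0
                L = L / smax[:, None]
                up[id(node)] = L
                scale[id(node)] = sc + np.log(smax)
        return up, scale

    def loglik(self, tree: Tree) -> float:
        self._check_tree(tree)
        rates, rweights = self.model.rate_categories()
        pi = self.model.pi
        if len(rates) == 1:
            up, scale = self._up_pass(tree, rates[0])
            root = tree.root
            lik = up[id(root)] @ pi
            return float((self.weights * (np.log(lik)
                                          + scale[id(root)])).sum())
        # Gamma mixture: combine categories under a shared scaler
        parts = []
        for rate in rates:
            upc, scc = self._up_pass(tree, rate)
            parts.append((upc[id(tree.root)] @ pi, scc[id(tree.root)]))
        ref = np.max([s for _, s in parts], axis=0)
        mix = np.zeros(self.patterns.shape[1])
        for (lik, sc), w in zip(parts, rweights):
            mix += w * lik * np.exp(sc - ref)
        return float((self.weights * (np.log(mix) + ref)).sum())

    # -- branch-length optimization --------------------------------
    def _messages(self, tree: Tree, rate: float = 1.0):
        """Up partials plus 'outside' messages for every non-root node."""
        up, upsc = self._up_pass(tree, rate)
        pi = self.model.pi
        out, outsc = {}, {}
        npat = self.patterns.shape[1]
        for node in tree.preorder():
            for c in node.children:
                if node.parent is None:
                    base = np.tile(pi, (npat, 1))
                    bsc = np.zeros(npat)
                else:
                    base = out[id(node)].copy()
                    bsc = outsc[id(node)].copy()
                    P = self.model.transition(_bl(node), rate)
                    base = base @ P
                for s in node.children:
                    if s is c:
                        continue
                    Ps = self.model.transition(_bl(s), rate)
                    base = base * (up[id(s)] @ Ps.T)
                    bsc = bsc + upsc[id(s)]
                smax = base.max(axis=1)
                smax[smax == 0] = 1.0
                out[id(c)] = base / smax[:, None]
                outsc[id(c)] = bsc + np.log(smax)
        return up, upsc, out, outsc

    def optimize_branch_lengths(self, tree: Tree, rounds: int = 2) -> float:
        """Per-edge 1-D optimization; returns the final log-likelihood.

        Messages are refreshed once per round; if a round ever fails to
        improve the joint likelihood the previous lengths are restored,
        so the returned likelihood never decreases across calls.
        """
        self._check_tree(tree)
        rates, rweights = self.model.rate_categories()
        if len(rates) != 1:
            raise NotImplementedError(
                "branch optimization implemented for the 1-rate case")
        best = self.loglik(tree)
        for _ in range(rounds):
            saved = {id(n): n.length for n in tree.postorder()}
            up, upsc, out, outsc = self._messages(tree)
            for node in tree.postorder():
                if node.parent is None:
                    continue
                U = up[id(node)]
                O = out[id(node)]
                wsum = self.weights
                const = upsc[id(node)] + outsc[id(node)]

                def neg(t):
                    P = self.model.transition(t)
                    lik = ((U @ P.T) * O).sum(axis=1)
                    return -float((wsum * (np.log(lik) + const)).sum())

                res = minimize_scalar(neg, bounds=(_BL_MIN, _BL_MAX),
                                      method="bounded",
                                      options={"xatol": 1e-7})
                node.length = float(res.x)
            new = self.loglik(tree)
            if new < best - 1e-9:
                for n in tree.postorder():
                    n.length = saved[id(n)]
                break
            if new < best + 1e-7:
                best = max(best, new)
                break
            best = new
        return best


def _bl(node: Node) -> float:
    return max(node.length if node.length is not None else _BL_MIN, _BL_MIN)


# ---------------------------------------------------------------------------
# NNI refinement
# ---------------------------------------------------------------------------

def _internal_edges(tree: Tree) -> list[Node]:
    """Child endpoints of internal edges (child itself internal)."""
    return [n for n in tree.postorder()
            if not n.is_leaf and n.parent is not None]


def _swap_subtrees(a: Node, b: Node) -> None:
    pa, pb = a.parent, b.parent
    ia, ib = pa.children.index(a), pb.children.index(b)
    pa.children[ia], pb.children[ib] = b, a
    a.parent, b.parent = pb, pa


def ml_refine(tree: Tree, aln: Alignment,
              model: Optional[SubstitutionModel] = None,
              max_nni_rounds: int = 5) -> Tree:
    """NNI hill-climbing with branch-length optimization.

    The returned tree's likelihood is never below the input tree's
    (branch lengths are optimized even with ``max_nni_rounds=0``).
    """
    model = model or SubstitutionModel()
    engine = TreeLikelihood(aln, model)
    tree = tree.copy()
    best = engine.optimize_branch_lengths(tree, rounds=2)
    for _ in range(max_nni_rounds):
        improved = False
        for child in list(_internal_edges(tree)):
            parent = child.parent
            if parent is None or len(child.children) != 2:
                continue
            others = [s for s in parent.children if s is not child]
            if not others:
                continue
            s = others[0]
            a, b = child.children
            for cand in (a, b):
                _swap_subtrees(cand, s)
                ll = engine.loglik(tree)
                if ll > best + 1e-6:
                    best = ll
                    improved = True
                    break
                _swap_subtrees(s, cand)  # revert
        if not improved:
            break
        best = max(best, engine.optimize_branch_lengths(tree, rounds=1))
    return tree


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(aln: Alignment,
                      model: Optional[SubstitutionModel] = None,
                      n_reps: int = 100, seed: int = 0,
                      reference: Optional[Tree] = None) -> Tree:
    """Column-resampling bootstrap; supports annotated on the reference.

    Replicate trees are distance/NJ reconstructions.  The reference
    tree defaults to the NJ tree of the full alignment.  Support is the
    percentage of replicates containing each internal bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    model = model or SubstitutionModel()
    rng = np.random.default_rng(seed)
    codes = encode_protein_alignment(aln)
    n = aln.n_rows
    ncol = aln.n_columns

    # per-pair joint codes per column (-1 where indeterminate)
    pair_codes = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            pc = np.where((a >= 0) & (b >= 0), a * 20 + b, -1)
            pair_codes[(i, j)] = pc

    def dm_from_cols(col_idx) -> DistanceMatrix:
        D = np.zeros((n, n))
        for (i, j), pc in pair_codes.items():
            sel = pc[col_idx]
            sel = sel[sel >= 0]
            N = np.bincount(sel, minlength=400).reshape(20, 20).astype(float)
            D[i, j] = D[j, i] = ml_distance_from_counts(N, model)
        return DistanceMatrix(list(aln.ids), D)

    if reference is None:
        reference = nj_tree(dm_from_cols(np.arange(ncol)))
    reference = reference.copy()

    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        rep_tree = nj_tree(dm_from_cols(idx))
        for bp in rep_tree.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1

    all_tips = frozenset(reference.tip_labels())
    ref_min = min(all_tips)
    ts = reference.tipsets()
    for node in reference.postorder():
        if node.is_leaf or node.parent is None:
            continue
        side = ts[id(node)]
        if ref_min in side:
            side = all_tips - side
        if not (1 < len(side) < len(all_tips) - 1):
            continue
        node.support = 100.0 * counts.get(side, 0) / n_reps
    return reference
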