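"""Ancestral state reconstruction of a binary trait under Mk1.

The Mk1 model is a two-state continuous-time Markov chain with a single
symmetric rate r, so P(same, t) = (1 + e^{-2rt})/2 and
P(different, t) = (1 - e^{-2rt})/2.  The root prior is the stationary
distribution (1/2, 1/2).  Tips coded "missing" contribute the partial
likelihood (1, 1).  Per-node marginal posteriors come from combining
inside (subtree) and outside (rest-of-tree) messages, which for a
reversible model equals the re-rooting construction node by node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .iocore import TraitTable
from .tree import Node, Tree, TreeError

STATES = ("anthocyanin", "betalain")

RATE_LO, RATE_HI = 1e-8, 1e3


def mk1_transition(rate: float, t: float) -> np.ndarray:
    """2x2 Mk1 transition matrix for elapsed time t."""
    if rate < 0 or t < 0:
        raise ValueError("rate and time must be non-negative")
    e = math.exp(-2.0 * rate * t)
    same = (1.0 + e) / 2.0
    diff = (1.0 - e) / 2.0
    return np.array([[same, diff], [diff, same]])


def _tip_partial(state: str) -> np.ndarray:
    if state == "missing":
        return np.ones(2)
    return np.array([1.0, 0.0]) if state == STATES[0] else np.array([0.0, 1.0])


def _check_tips(tree: Tree, traits: TraitTable) -> None:
    missing = [lab for lab in tree.tip_labels() if lab not in traits]
    if missing:
        raise TreeError(f"tips absent from trait table: {sorted(missing)}")


def _up_messages(tree: Tree, traits: TraitTable, rate: float):
    """Post-order partial likelihoods (log-scaled) keyed by node id."""
    up, logscale = {}, {}
    for node in tree.postorder():
        if node.is_leaf:
            up[id(node)] = _tip_partial(traits[node.label])
            logscale[id(node)] = 0.0
        else:
            L = np.ones(2)
            sc = 0.0
            for c in node.children:
                P = mk1_transition(rate, c.length or 0.0)
                L = L * (P @ up[id(c)])
                sc += logscale[id(c)]
            m = L.max()
            if m > 0:
                L = L / m
                sc += math.log(m)
            up[id(node)] = L
            logscale[id(node)] = sc
    return up, logscale


def mk1_loglik(tree: Tree, traits: TraitTable, rate: float) -> float:
    """Felsenstein pruning log-likelihood with root prior (1/2, 1/2)."""
    _check_tips(tree, traits)
    up, logscale = _up_messages(tree, traits, rate)
    root = tree.root
    lik = 0.5 * up[id(root)].sum()
    if lik <= 0:
        return -math.inf
    return math.log(lik) + logscale[id(root)]


@dataclass
class Mk1Fit:
    """Fitted Mk1 model: rate, log-likelihood, node posteriors."""

    rate: float
    logL: float
    node_posteriors: dict = field(default_factory=dict)
    at_boundary: bool = False

    @property
    def neg_logL(self) -> float:
        """-log L, the sign convention many ASR programs print."""
        return -self.logL


def fit_mk1(tree: Tree, traits: TraitTable,
            compute_posteriors: bool = True) -> Mk1Fit:
    """Maximize the Mk1 likelihood over the single symmetric rate.

    Optimization is Brent-style on log(rate) over [1e-8, 1e3]; a
    solution pinned at either bound is flagged ``at_boundary`` (this is
    the expected outcome when all scored tips share one state).
    """
    _check_tips(tree, traits)
    observed = {traits[lab] for lab in tree.tip_labels()} - {"missing"}
    if not observed:
        raise TreeError("no tips with a scored state")

    def neg(log_rate: float) -> float:
        return -mk1_loglik(tree, traits, math.exp(log_rate))

    res = minimize_scalar(neg, bounds=(math.log(RATE_LO), math.log(RATE_HI)),
                          method="bounded", options={"xatol": 1e-8})
    rate = math.exp(float(res.x))
    # prefer the exact boundary when the optimum runs into it
    lo_val = neg(math.log(RATE_LO))
    if lo_val <= res.fun + 1e-12:
        rate = RATE_LO
    boundary = rate <= RATE_LO * math.e or rate >= RATE_HI / math.e
    fit = Mk1Fit(rate=rate, logL=mk1_loglik(tree, traits, rate),
                 at_boundary=boundary)
    if compute_posteriors:
        fit.node_posteriors = marginal_asr(tree, traits, rate)
    return fit


def marginal_asr(tree: Tree, traits: TraitTable, rate: float) -> dict:
    """Marginal state posteriors for every internal node.

    Returns a dict keyed by id(node) -> {"node": node, "posterior":
    (p_anthocyanin, p_betalain)}.  Each posterior is the Bayes rule
    over full-tree likelihoods with that node's state fixed, computed
    via inside/outside messages (equivalent to re-rooting at the node).
    """
    _check_tips(tree, traits)
    up, upsc = _up_messages(tree, traits, rate)
    out: dict[int, np.ndarray] = {}
    root = tree.root
    out[id(root)] = np.array([0.5, 0.5])
    for node in tree.preorder():
        for c in node.children:
            base = out[id(node)].copy()
            for s in node.children:
                if s is c:
                    continue
                Ps = mk1_transition(rate, s.length or 0.0)
                base = base * (Ps @ up[id(s)])
            Pc = mk1_transition(rate, c.length or 0.0)
            vec = base @ Pc          # states at c
            m = vec.max()
            out[id(c)] = vec / m if m > 0 else vec
    posteriors = {}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        joint = up[id(node)] * out[id(node)]
        total = joint.sum()
        posteriors[id(node)] = {
            "node": node,
            "posterior": tuple(joint / total) if total > 0 else (0.5, 0.5),
        }
    return posteriors
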