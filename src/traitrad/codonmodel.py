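"""Codon substitution machinery (GY94-style) for selection inference.

States are the 61 sense codons of the standard code.  Instantaneous
rates are zero for multi-nucleotide changes and otherwise proportional
to the target codon frequency, multiplied by kappa for transitions and
by omega for nonsynonymous changes.  Every generator is normalised to
one expected substitution per codon site per unit time at its own
stationary distribution, so branch lengths are expected substitutions
per codon under every site class; exponentials use the symmetric form
available for any reversible model.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from .gencode import (CODON_INDEX, N_SENSE, NONSYNONYMOUS, SENSE_CODONS,
                      SINGLE_CHANGE, TRANSITION)
from .iocore import CodonAlignment, FormatError
from .tree import Node, Tree


def equal_codon_frequencies() -> np.ndarray:
    return np.full(N_SENSE, 1.0 / N_SENSE)


def f3x4_frequencies(caln: CodonAlignment) -> np.ndarray:
    """CodeML-style F3x4: positional nucleotide frequencies.

    Codon frequency is the product of the per-position nucleotide
    frequencies observed in the alignment, renormalised over the 61
    sense codons.  Ambiguous and gap codons are skipped.
    """
    counts = np.zeros((3, 4))
    nuc_idx = {c: i for i, c in enumerate("ACGT")}
    for row in caln.rows:
        for k in range(0, len(row), 3):
            codon = row[k:k + 3]
            if "-" in codon or "N" in codon:
                continue
            for pos, ch in enumerate(codon):
                counts[pos, nuc_idx[ch]] += 1
    if counts.sum() == 0:
        raise FormatError("no determinate codons for F3x4 frequencies")
    # guard empty categories so no sense codon gets probability zero
    counts += 0.5
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.empty(N_SENSE)
    for i, codon in enumerate(SENSE_CODONS):
        freqs[i] = (pos_freq[0, nuc_idx[codon[0]]]
                    * pos_freq[1, nuc_idx[codon[1]]]
                    * pos_freq[2, nuc_idx[codon[2]]])
    return freqs / freqs.sum()


def codon_rate_matrix(kappa: float, omega: float,
                      codon_freqs: np.ndarray) -> np.ndarray:
    """Normalised 61x61 GY94 generator (rows sum to zero).

    Time-reversible by construction: pi_i q_ij = pi_j q_ji.
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be positive and omega non-negative")
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (N_SENSE,) or abs(pi.sum() - 1) > 1e-8 or np.any(pi < 0):
        raise ValueError("codon_freqs must be 61 non-negative values "
                         "summing to 1")
    R = np.where(SINGLE_CHANGE, 1.0, 0.0)
    R = R * np.where(TRANSITION, kappa, 1.0)
    R = R * np.where(NONSYNONYMOUS, omega, 1.0)
    Q = R * pi[None, :]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    if mu <= 0:
        raise ValueError("degenerate codon generator")
    return Q / mu


def gy94_rate(kappa: float, omega: float, codon_freqs: np.ndarray) -> float:
    """Expected substitutions/codon/unit time of the *unscaled* GY94
    generator (rates pi_j, x kappa for transitions, x omega for
    nonsynonymous changes) at its stationary distribution.

    Site-class mixtures are normalised by the proportion-weighted
    average of these rates, so that one unit of branch length is one
    expected substitution per codon averaged over classes — classes
    with higher omega then genuinely evolve faster, as in the standard
    formulation.
    """
    pi = np.asarray(codon_freqs, dtype=float)
    R = np.where(SINGLE_CHANGE, 1.0, 0.0)
    R = R * np.where(TRANSITION, kappa, 1.0)
    R = R * np.where(NONSYNONYMOUS, omega, 1.0)
    Q = R * pi[None, :]
    return float((pi[:, None] * Q).sum())


class _CodonEigen:
    """Cached symmetric eigendecomposition of one normalised generator.

    ``mu`` is the rate of the corresponding unscaled generator, used
    to undo the per-matrix normalisation inside mixture models.
    """

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        self.mu = gy94_rate(kappa, omega, pi)
        Q = codon_rate_matrix(kappa, omega, pi)
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        B = (B + B.T) / 2.0
        evals, evecs = np.linalg.eigh(B)
        self.evals = evals
        self.U = evecs / sqrt_pi[:, None]
        self.V = evecs.T * sqrt_pi[None, :]

    def transition(self, t: float) -> np.ndarray:
        P = (self.U * np.exp(self.evals * t)) @ self.V
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def encode_codon_alignment(caln: CodonAlignment) -> np.ndarray:
    """(n_rows, n_codons) sense-codon indices; -1 for gap/ambiguous."""
    out = np.full((caln.n_rows, caln.n_codons), -1, dtype=np.int16)
    for r, row in enumerate(caln.rows):
        for k in range(caln.n_codons):
            codon = row[3 * k: 3 * k + 3]
            out[r, k] = CODON_INDEX.get(codon, -1)
    return out


class CodonLikelihood:
    """Pruning engine for codon site-class likelihoods on one tree.

    Site patterns are compressed once.  ``class_site_loglik`` returns
    per-site log-likelihoods for a single site class, where foreground
    edges (given as child-node ids) may use a different omega than the
    background — the ingredient shared by M0/M1a/M2a and branch-site
    model A.
    """

    def __init__(self, tree: Tree, caln: CodonAlignment,
                 codon_freqs: Optional[np.ndarray] = None):
        if set(tree.tip_labels()) != set(caln.ids):
            raise FormatError("tree tips do not match alignment rows")
        self.tree = tree
        self.caln = caln
        self.pi = (np.asarray(codon_freqs, dtype=float)
                   if codon_freqs is not None else f3x4_frequencies(caln))
        codes = encode_codon_alignment(caln)
        patterns, inverse, weights = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True)
        self.patterns = patterns
        self.pattern_of_site = inverse.ravel()
        self.weights = weights.astype(float)
        self.n_sites = caln.n_codons
        eye = np.eye(N_SENSE)
        self._tip_partial = {}
        for r, sid in enumerate(caln.ids):
            codes_r = patterns[r]
            part = np.ones((patterns.shape[1], N_SENSE))
            det = codes_r >= 0
            part[det] = eye[codes_r[det]]
            self._tip_partial[sid] = part
        self._eigen_cache: dict = {}

    # -- transition matrices ---------------------------------------
    def _eigen(self, kappa: float, omega: float) -> _CodonEigen:
        key = (round(float(kappa), 12), round(float(omega), 12))
        eig = self._eigen_cache.get(key)
        if eig is None:
            if len(self._eigen_cache) > 256:
                self._eigen_cache.clear()
            eig = _CodonEigen(kappa, omega, self.pi)
            self._eigen_cache[key] = eig
        return eig

    # -- per-class pruning -----------------------------------------
    def mixture_scale(self, kappa: float, proportions, bg_omegas) -> float:
        """Proportion-weighted unscaled rate over background classes."""
        return float(sum(p * gy94_rate(kappa, w, self.pi)
                         for p, w in zip(proportions, bg_omegas)))

    def class_site_loglik(self, kappa: float, omega_bg: float,
                          omega_fg: Optional[float] = None,
                          fg_ids: frozenset = frozenset(),
                          scale: Optional[float] = None) -> np.ndarray:
        """Per-pattern log-likelihood under one site class.

        Edges whose child-node id is in ``fg_ids`` evolve with
        ``omega_fg``; all others with ``omega_bg``.  ``scale`` is the
        mixture normalisation rate (one expected substitution per
        codon per unit branch length averaged over classes); ``None``
        normalises this class alone.
        """
        if omega_fg is None:
            omega_fg = omega_bg
        up: dict[int, np.ndarray] = {}
        logsc: dict[int, np.ndarray] = {}
        npat = self.patterns.shape[1]
        for node in self.tree.postorder():
            if node.is_leaf:
                L = self._tip_partial[node.label]
                sc = np.zeros(npat)
            else:
                L = None
                sc = np.zeros(npat)
                for c in node.children:
                    omega = omega_fg if id(c) in fg_ids else omega_bg
                    t = max(c.length if c.length is not None else 0.0, 0.0)
                    eig = self._eigen(kappa, omega)
                    if scale is not None:
                        t = t * eig.mu / scale
                    P = eig.transition(t)
                    contrib = up[id(c)] @ P.T
                    L = contrib if L is None else L * contrib
                    sc += logsc[id(c)]
                smax = L.max(axis=1)
                smax[smax == 0] = 1.0
                L = L / smax[:, None]
                sc = sc + np.log(smax)
            up[id(node)] = L
            logsc[id(node)] = sc
        root = self.tree.root
        lik = up[id(root)] @ self.pi
        with np.errstate(divide="ignore"):
            return np.log(lik) + logsc[id(root)]

    def mixture_loglik(self, proportions: Iterable[float],
                       class_logliks: Iterable[np.ndarray]) -> float:
        """Total log-likelihood of a site-class mixture."""
        props = np.asarray(list(proportions), dtype=float)
        if np.any(props < -1e-12) or abs(props.sum() - 1) > 1e-8:
            raise ValueError("class proportions must be a distribution")
        stack = np.stack(list(class_logliks))          # (n_class, n_pat)
        ref = stack.max(axis=0)
        mix = (props[:, None] * np.exp(stack - ref)).sum(axis=0)
        return float((self.weights * (np.log(mix) + ref)).sum())

    def foreground_ids(self, clade_tips: Iterable[str]) -> frozenset:
        """Child-node ids of all branches within a clade (incl. stem).

        The clade is the MRCA subtree of ``clade_tips``; "all branches
        within" includes the clade's stem edge and every internal and
        terminal edge inside it.
        """
        mrca = self.tree.mrca(clade_tips)
        return frozenset(id(n) for n in mrca.postorder())
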