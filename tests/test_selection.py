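"""Codon models against an independent enumeration + series-expm oracle."""

import itertools
import math

import numpy as np
import pytest
from Bio.Data import CodonTable

from traitrad.codonmodel import (CodonLikelihood, codon_rate_matrix,
                                 equal_codon_frequencies, gy94_rate)
from traitrad.gencode import SENSE_CODONS
from traitrad.iocore import CodonAlignment
from traitrad.selection import (branch_site_loglik, eb_site_posteriors,
                                fit_codon_model, lrt, site_model_loglik)
from traitrad.tree import Tree

PI = equal_codon_frequencies()


# ---------------------------------------------------------------------------
# independent oracle: own genetic code tables, own Q, series expm,
# likelihood by explicit summation over ancestral states
# ---------------------------------------------------------------------------

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_OC = [c for c in sorted("".join(t) for t in
                         itertools.product("ACGT", repeat=3))
       if c not in _TABLE.stop_codons]
_OIDX = {c: i for i, c in enumerate(_OC)}


def oracle_q(kappa, omega):
    n = len(_OC)
    Q = np.zeros((n, n))
    purines = {"A", "G"}
    for i, ci in enumerate(_OC):
        for j, cj in enumerate(_OC):
            if i == j:
                continue
            diffs = [(x, y) for x, y in zip(ci, cj) if x != y]
            if len(diffs) != 1:
                continue
            rate = 1.0 / n
            x, y = diffs[0]
            if (x in purines) == (y in purines):
                rate *= kappa
            if _TABLE.forward_table[ci] != _TABLE.forward_table[cj]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def oracle_rate(kappa, omega):
    Q = oracle_q(kappa, omega)
    return -np.diag(Q).mean()  # equal frequencies


def series_expm(M, terms=60):
    out = np.eye(M.shape[0])
    term = np.eye(M.shape[0])
    # scaling and squaring with a plain Taylor series
    s = max(0, int(np.ceil(np.log2(max(1e-9, np.abs(M).sum(axis=1).max())))) + 3)
    A = M / (2 ** s)
    acc = np.eye(M.shape[0])
    term = np.eye(M.shape[0])
    for k in range(1, terms):
        term = term @ A / k
        acc = acc + term
    for _ in range(s):
        acc = acc @ acc
    return acc


def oracle_loglik(tree_newick, rows, classes, scale_omegas=None):
    """classes: list of (prop, omega_by_edge_label dict or scalar)."""
    tree = Tree.from_newick(tree_newick)
    props = [p for p, _ in classes]
    if scale_omegas is None:
        scale_omegas = [w if np.isscalar(w) else w["bg"]
                        for _, w in classes]
    rho = sum(p * oracle_rate(2.0, w)
              for p, w in zip(props, scale_omegas))
    ids = list(rows)
    n_sites = len(rows[ids[0]]) // 3
    total = 0.0
    internals = [n for n in tree.postorder() if not n.is_leaf]
    for site in range(n_sites):
        obs = {sid: _OIDX[rows[sid][3 * site:3 * site + 3]]
               for sid in ids}
        site_lik = 0.0
        for prop, w in zip(props, [w for _, w in classes]):
            # per-edge transition matrices under this class
            P = {}
            for node in tree.postorder():
                if node.parent is None:
                    continue
                omega = w if np.isscalar(w) else \
                    w.get(node_key(node), w["bg"])
                Q = oracle_q(2.0, omega)
                P[id(node)] = series_expm(Q * (node.length / rho))
            lik = 0.0
            for assign in itertools.product(range(len(_OC)),
                                            repeat=len(internals)):
                state = {id(n): s for n, s in zip(internals, assign)}
                prob = 1.0 / len(_OC)  # root prior = equal frequencies
                for node in tree.postorder():
                    if node.parent is None:
                        continue
                    ps = state[id(node.parent)]
                    target = (obs[node.label] if node.is_leaf
                              else state[id(node)])
                    prob *= P[id(node)][ps, target]
                    if prob == 0.0:
                        break
                lik += prob
            site_lik += prop * lik
        total += math.log(site_lik)
    return total


def node_key(node):
    if node.is_leaf:
        return node.label
    return "+".join(sorted(t.label for t in node.leaves()))


# ---------------------------------------------------------------------------
# rate matrix properties
# ---------------------------------------------------------------------------

class TestRateMatrix:
    def test_multi_nucleotide_changes_forbidden(self):
        Q = codon_rate_matrix(2.0, 0.5, PI)
        for i, ci in enumerate(SENSE_CODONS):
            for j, cj in enumerate(SENSE_CODONS):
                ndiff = sum(a != b for a, b in zip(ci, cj))
                if ndiff >= 2:
                    assert Q[i, j] == 0.0

    def test_rows_sum_to_zero_and_unit_rate(self):
        Q = codon_rate_matrix(3.0, 0.3, PI)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert -(PI * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_detailed_balance(self):
        rng = np.random.default_rng(1)
        raw = rng.random(61)
        pi = raw / raw.sum()
        Q = codon_rate_matrix(2.5, 0.7, pi)
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_neutral_equal_frequencies_uniform_offdiagonals(self):
        Q = codon_rate_matrix(1.0, 1.0, PI)
        off = Q[(Q > 0)]
        assert np.allclose(off, off[0])

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            codon_rate_matrix(0.0, 1.0, PI)
        with pytest.raises(ValueError):
            codon_rate_matrix(2.0, 1.0, PI[:-1])


# ---------------------------------------------------------------------------
# likelihood engine vs oracle
# ---------------------------------------------------------------------------

TOY2 = "(A:0.2,B:0.4);"
TOY3 = "((A:0.25,B:0.35):0.15,C:0.3);"
ROWS2 = {"A": "ATGAAACCC", "B": "ATGAAGCCA"}
ROWS3 = {"A": "ATGAAACCCTTA".replace("TTA", "TTG"),
         "B": "ATGAAGCCATTG",
         "C": "ATAAAGCCTCTG"}


class TestSiteModelLoglik:
    def test_degenerate_star_tree_single_codon(self):
        t = Tree.from_newick("(A:0,B:0,C:0);")
        caln = CodonAlignment(["A", "B", "C"], ["ATG", "ATG", "ATG"])
        ll = site_model_loglik(t, caln, "M0",
                               {"kappa": 2.0, "omega": 1.0},
                               codon_freqs=PI)
        # zero-length star: the site likelihood is just pi(ATG)
        assert ll == pytest.approx(math.log(1.0 / 61), abs=1e-9)

    def test_m0_matches_oracle_two_taxa(self):
        caln = CodonAlignment(["A", "B"], [ROWS2["A"], ROWS2["B"]])
        t = Tree.from_newick(TOY2)
        ll = site_model_loglik(t, caln, "M0",
                               {"kappa": 2.0, "omega": 0.5},
                               codon_freqs=PI)
        want = oracle_loglik(TOY2, ROWS2, [(1.0, 0.5)])
        assert ll == pytest.approx(want, abs=1e-8)

    def test_m1a_matches_oracle_three_taxa(self):
        caln = CodonAlignment(list(ROWS3), list(ROWS3.values()))
        t = Tree.from_newick(TOY3)
        ll = site_model_loglik(t, caln, "M1a",
                               {"kappa": 2.0, "omega0": 0.2, "p0": 0.7},
                               codon_freqs=PI)
        want = oracle_loglik(TOY3, ROWS3, [(0.7, 0.2), (0.3, 1.0)])
        assert ll == pytest.approx(want, abs=1e-8)

    def test_m2a_matches_oracle_three_taxa(self):
        caln = CodonAlignment(list(ROWS3), list(ROWS3.values()))
        t = Tree.from_newick(TOY3)
        params = {"kappa": 2.0, "omega0": 0.2, "p0": 0.5, "p1": 0.3,
                  "omega2": 4.0}
        ll = site_model_loglik(t, caln, "M2a", params, codon_freqs=PI)
        want = oracle_loglik(TOY3, ROWS3,
                             [(0.5, 0.2), (0.3, 1.0), (0.2, 4.0)])
        assert ll == pytest.approx(want, abs=1e-8)

    def test_m2a_with_empty_positive_class_reduces_to_m1a(self):
        caln = CodonAlignment(list(ROWS3), list(ROWS3.values()))
        t = Tree.from_newick(TOY3)
        m2 = site_model_loglik(t, caln, "M2a",
                               {"kappa": 2.0, "omega0": 0.2, "p0": 0.7,
                                "p1": 0.3 - 1e-12, "omega2": 5.0},
                               codon_freqs=PI)
        m1 = site_model_loglik(t, caln, "M1a",
                               {"kappa": 2.0, "omega0": 0.2, "p0": 0.7},
                               codon_freqs=PI)
        assert m2 == pytest.approx(m1, abs=1e-6)

    def test_unclean_alignment_rejected(self):
        t = Tree.from_newick(TOY2)
        caln = CodonAlignment(["A", "B"], ["ATG---", "ATGAAA"])
        from traitrad.iocore import FormatError
        with pytest.raises(FormatError, match="clean"):
            site_model_loglik(t, caln, "M0",
                              {"kappa": 2.0, "omega": 1.0})


class TestBranchSiteLoglik:
    def test_matches_oracle_with_one_foreground_edge(self):
        caln = CodonAlignment(list(ROWS3), list(ROWS3.values()))
        t = Tree.from_newick(TOY3)
        params = {"kappa": 2.0, "omega0": 0.2, "p0": 0.45, "p1": 0.45,
                  "omega2": 6.0}
        ll = branch_site_loglik(t, caln, ["A"], params, codon_freqs=PI)
        p0, p1 = 0.45, 0.45
        p2 = 0.1
        classes = [
            (p0, 0.2),
            (p1, 1.0),
            (p2 * p0 / 0.9, {"bg": 0.2, "A": 6.0}),
            (p2 * p1 / 0.9, {"bg": 1.0, "A": 6.0}),
        ]
        want = oracle_loglik(TOY3, ROWS3, classes,
                             scale_omegas=[0.2, 1.0, 0.2, 1.0])
        assert ll == pytest.approx(want, abs=1e-8)

    def test_omega2_one_equals_null(self):
        caln = CodonAlignment(list(ROWS3), list(ROWS3.values()))
        t = Tree.from_newick(TOY3)
        params = {"kappa": 2.0, "omega0": 0.3, "p0": 0.5, "p1": 0.3,
                  "omega2": 1.0}
        alt = branch_site_loglik(t, caln, ["A", "B"], params,
                                 codon_freqs=PI)
        null = branch_site_loglik(t, caln, ["A", "B"], params, null=True,
                                  codon_freqs=PI)
        assert alt == pytest.approx(null, abs=1e-12)

    def test_empty_foreground_rejected(self):
        caln = CodonAlignment(list(ROWS3), list(ROWS3.values()))
        t = Tree.from_newick(TOY3)
        with pytest.raises(ValueError):
            branch_site_loglik(t, caln, [], {"kappa": 2.0})

    def test_site_model_invariant_to_rerooting(self):
        caln = CodonAlignment(list(ROWS3), list(ROWS3.values()))
        t = Tree.from_newick(TOY3)
        params = {"kappa": 2.0, "omega0": 0.2, "p0": 0.7}
        base = site_model_loglik(t, caln, "M1a", params, codon_freqs=PI)
        t2 = t.copy()
        target = t2.find_tip("C")
        rerooted = t2.reroot_on_edge(target, 0.4)
        moved = site_model_loglik(rerooted, caln, "M1a", params,
                                  codon_freqs=PI)
        assert moved == pytest.approx(base, abs=1e-10)


class TestLRT:
    def _fit(self, model, logL):
        from traitrad.selection import CodonFit
        return CodonFit(model=model, params={}, logL=logL, converged=True,
                        n_starts=1)

    def test_equal_likelihoods_give_p_one(self):
        res = lrt(self._fit("M1a", -100.0), self._fit("M2a", -100.0))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi2_quantile(self):
        res = lrt(self._fit("M1a", -100.0),
                  self._fit("M2a", -100.0 + 5.991 / 2))
        assert res.df == 2
        assert res.p_value == pytest.approx(0.05, abs=1e-3)

    def test_mixture_null_halves_tail(self):
        stat = 2.706  # chi2_1 upper 10% point
        res = lrt(self._fit("modelA_null", -50.0),
                  self._fit("modelA", -50.0 + stat / 2), mixture=True)
        assert res.p_value == pytest.approx(0.05, abs=1e-3)

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ValueError):
            lrt(self._fit("M2a", -10.0), self._fit("M1a", -9.0))


class TestFitAndPosteriors:
    def test_alternative_never_below_null_with_warm_start(self):
        from traitrad.simulate import CodonSimParams, \
            simulate_codon_alignment
        t = Tree.from_newick(TOY3)
        caln, _ = simulate_codon_alignment(
            t, CodonSimParams(omega2=1.0, p0=0.6, p1=0.4 - 1e-9,
                              n_codons=60), seed=3)
        null = fit_codon_model(t, caln, "M1a", n_starts=1, seed=0,
                               codon_freqs="equal")
        alt_start = {"kappa": null.params["kappa"],
                     "omega0": null.params["omega0"],
                     "p0": null.params["p0"] * 0.98,
                     "p1": (1 - null.params["p0"]) * 0.98,
                     "omega2": 1.2}
        alt = fit_codon_model(t, caln, "M2a", n_starts=1, seed=0,
                              codon_freqs="equal",
                              start_params=alt_start)
        assert alt.logL >= null.logL - 1e-4

    def test_posteriors_sum_to_one_and_invariant_site_not_flagged(self):
        from traitrad.simulate import CodonSimParams, \
            simulate_codon_alignment
        t = Tree.from_newick(TOY3)
        caln, _ = simulate_codon_alignment(
            t, CodonSimParams(n_codons=40), foreground_clade=["A"],
            seed=9)
        # force the first codon column to be invariant
        rows = [caln.rows[0][:3] + r[3:] for r in caln.rows]
        caln = CodonAlignment(caln.ids, rows)
        fit = fit_codon_model(t, caln, "modelA", foreground_tips=["A"],
                              n_starts=1, seed=0, codon_freqs="equal")
        for method in ("NEB", "BEB"):
            post = eb_site_posteriors(fit, t, caln, method=method)
            assert np.allclose(post.posterior.sum(axis=1), 1.0,
                               atol=1e-9)
            assert post.selected_prob[0] < 0.95

    def test_nesting_chain_numerically(self):
        from traitrad.simulate import CodonSimParams, \
            simulate_codon_alignment
        t = Tree.from_newick(TOY3)
        caln, _ = simulate_codon_alignment(
            t, CodonSimParams(n_codons=80), seed=4)
        m1 = fit_codon_model(t, caln, "M1a", n_starts=1, seed=0,
                             codon_freqs="equal")
        m2_start = {"kappa": m1.params["kappa"],
                    "omega0": m1.params["omega0"],
                    "p0": m1.params["p0"] * 0.98,
                    "p1": (1 - m1.params["p0"]) * 0.98, "omega2": 1.5}
        m2 = fit_codon_model(t, caln, "M2a", n_starts=1, seed=0,
                             codon_freqs="equal", start_params=m2_start)
        a_start = dict(m2_start)
        mA = fit_codon_model(t, caln, "modelA", foreground_tips=["A"],
                             n_starts=1, seed=0, codon_freqs="equal",
                             start_params=a_start)
        assert m2.logL >= m1.logL - 1e-4
        assert mA.logL >= m1.logL - 1e-4
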