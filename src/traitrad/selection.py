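"""Positive-selection inference with codon site and branch-site models.

Implements M0 (one ratio), M1a (nearly neutral), M2a (positive
selection) and branch-site model A with an a priori foreground branch
set, likelihood-ratio tests between nested pairs, and empirical-Bayes
site posteriors (naive plug-in NEB and the grid-averaged BEB scheme).

Model A's four site classes are (0) omega0 everywhere, (1) omega1=1
everywhere, (2a) omega0 background / omega2 foreground and (2b) 1
background / omega2 foreground, with proportions (p0, p1, p2a, p2b)
where p2a = p2 p0/(p0+p1) and p2b = p2 p1/(p0+p1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .codonmodel import (CodonLikelihood, equal_codon_frequencies,
                         f3x4_frequencies)
from .iocore import CodonAlignment, FormatError
from .tree import Tree

SITE_MODELS = ("M0", "M1a", "M2a")
BRANCH_SITE_MODELS = ("modelA", "modelA_null")

_NESTED_PAIRS = {("M1a", "M2a"): 2, ("M0", "M2a"): 3,
                 ("modelA_null", "modelA"): 1, ("M1a", "modelA"): 2}

KAPPA_BOUNDS = (0.1, 20.0)
OMEGA0_BOUNDS = (1e-4, 1.0)
OMEGA2_BOUNDS = (1.0, 50.0)
OMEGA_M0_BOUNDS = (1e-4, 20.0)
PROP_BOUNDS = (1e-4, 1.0 - 1e-4)


def _require_clean(engine: CodonLikelihood) -> None:
    if np.any(engine.patterns < 0):
        raise FormatError(
            "codon alignment contains gap or ambiguous codons; apply "
            "clean_codon_columns first")


def _class_table(model: str, params: dict) -> list[tuple[float, float, float]]:
    """(proportion, omega_background, omega_foreground) per class."""
    k = params
    if model == "M0":
        return [(1.0, k["omega"], k["omega"])]
    if model == "M1a":
        p0 = k["p0"]
        return [(p0, k["omega0"], k["omega0"]), (1 - p0, 1.0, 1.0)]
    if model == "M2a":
        p0, p1 = k["p0"], k["p1"]
        p2 = 1.0 - p0 - p1
        return [(p0, k["omega0"], k["omega0"]), (p1, 1.0, 1.0),
                (p2, k["omega2"], k["omega2"])]
    if model in BRANCH_SITE_MODELS:
        p0, p1 = k["p0"], k["p1"]
        p2 = 1.0 - p0 - p1
        w2 = 1.0 if model == "modelA_null" else k["omega2"]
        tot = p0 + p1
        p2a = p2 * p0 / tot
        p2b = p2 * p1 / tot
        return [(p0, k["omega0"], k["omega0"]), (p1, 1.0, 1.0),
                (p2a, k["omega0"], w2), (p2b, 1.0, w2)]
    raise ValueError(f"unknown model {model!r}")


def _mixture_scale(engine: CodonLikelihood, kappa: float, table) -> float:
    """Mixture normalisation: proportion-weighted background rates."""
    return engine.mixture_scale(kappa, [p for p, _, _ in table],
                                [w_bg for _, w_bg, _ in table])


def _class_logliks(engine: CodonLikelihood, kappa: float,
                   table, fg_ids: frozenset,
                   scale: Optional[float] = None) -> list[np.ndarray]:
    if scale is None:
        scale = _mixture_scale(engine, kappa, table)
    return [engine.class_site_loglik(kappa, w_bg, w_fg, fg_ids, scale=scale)
            for _p, w_bg, w_fg in table]


def site_model_loglik(tree: Tree, caln: CodonAlignment, model: str,
                      params: dict,
                      codon_freqs: Optional[np.ndarray] = None,
                      engine: Optional[CodonLikelihood] = None) -> float:
    """Log-likelihood of M0 / M1a / M2a on a clean codon alignment."""
    if model not in SITE_MODELS:
        raise ValueError(f"not a site model: {model!r}")
    engine = engine or CodonLikelihood(tree, caln, codon_freqs)
    _require_clean(engine)
    table = _class_table(model, params)
    lls = _class_logliks(engine, params["kappa"], table, frozenset())
    return engine.mixture_loglik([p for p, _, _ in table], lls)


def branch_site_loglik(tree: Tree, caln: CodonAlignment,
                       foreground_tips: Iterable[str], params: dict,
                       null: bool = False,
                       codon_freqs: Optional[np.ndarray] = None,
                       engine: Optional[CodonLikelihood] = None) -> float:
    """Log-likelihood of branch-site model A (or its omega2=1 null).

    ``foreground_tips`` name the clade whose internal and terminal
    branches (including the stem) form the foreground.
    """
    foreground_tips = list(foreground_tips)
    if not foreground_tips:
        raise ValueError("foreground clade must be non-empty")
    engine = engine or CodonLikelihood(tree, caln, codon_freqs)
    _require_clean(engine)
    fg_ids = engine.foreground_ids(foreground_tips)
    model = "modelA_null" if null else "modelA"
    table = _class_table(model, params)
    lls = _class_logliks(engine, params["kappa"], table, fg_ids)
    return engine.mixture_loglik([p for p, _, _ in table], lls)


@dataclass
class CodonFit:
    """A fitted codon model with optimizer diagnostics."""

    model: str
    params: dict
    logL: float
    converged: bool
    n_starts: int
    start_logLs: list = field(default_factory=list)
    foreground_tips: Optional[list] = None
    codon_freqs: Optional[np.ndarray] = None


def _pack(model: str, params: dict) -> tuple[np.ndarray, list]:
    if model == "M0":
        x = [params["kappa"], params["omega"]]
        b = [KAPPA_BOUNDS, OMEGA_M0_BOUNDS]
    elif model == "M1a":
        x = [params["kappa"], params["omega0"], params["p0"]]
        b = [KAPPA_BOUNDS, OMEGA0_BOUNDS, PROP_BOUNDS]
    else:
        p0, p1 = params["p0"], params["p1"]
        c = p0 + p1
        f = p0 / c
        x = [params["kappa"], params["omega0"], c, f]
        b = [KAPPA_BOUNDS, OMEGA0_BOUNDS, PROP_BOUNDS, PROP_BOUNDS]
        if model in ("M2a", "modelA"):
            x.append(params["omega2"])
            b.append(OMEGA2_BOUNDS)
    return np.array(x, dtype=float), b


def _unpack(model: str, x: np.ndarray) -> dict:
    if model == "M0":
        return {"kappa": x[0], "omega": x[1]}
    if model == "M1a":
        return {"kappa": x[0], "omega0": x[1], "p0": x[2]}
    out = {"kappa": x[0], "omega0": x[1],
           "p0": x[2] * x[3], "p1": x[2] * (1 - x[3])}
    if model in ("M2a", "modelA"):
        out["omega2"] = x[4]
    return out


_DEFAULT_START = {
    "M0": {"kappa": 2.0, "omega": 0.4},
    "M1a": {"kappa": 2.0, "omega0": 0.3, "p0": 0.7},
    "M2a": {"kappa": 2.0, "omega0": 0.3, "p0": 0.6, "p1": 0.3,
            "omega2": 3.0},
    "modelA": {"kappa": 2.0, "omega0": 0.3, "p0": 0.6, "p1": 0.3,
               "omega2": 3.0},
    "modelA_null": {"kappa": 2.0, "omega0": 0.3, "p0": 0.6, "p1": 0.3},
}


def fit_codon_model(tree: Tree, caln: CodonAlignment, model: str,
                    foreground_tips: Optional[Iterable[str]] = None,
                    n_starts: int = 3, seed: int = 0,
                    codon_freqs="f3x4",
                    start_params: Optional[dict] = None,
                    tol: float = 1e-7) -> CodonFit:
    """Bounded multi-start quasi-Newton fit of one codon model.

    Proportions are parametrised as (p0+p1, p0/(p0+p1)) so the
    simplex constraint is a box; the best of ``n_starts`` L-BFGS-B
    runs is returned with every start's likelihood logged.
    """
    if model in BRANCH_SITE_MODELS:
        if not foreground_tips:
            raise ValueError(f"{model} requires a foreground clade")
        foreground_tips = list(foreground_tips)
    elif model not in SITE_MODELS:
        raise ValueError(f"unknown model {model!r}")

    if isinstance(codon_freqs, str):
        if codon_freqs == "f3x4":
            freqs = f3x4_frequencies(caln)
        elif codon_freqs == "equal":
            freqs = equal_codon_frequencies()
        else:
            raise ValueError(f"unknown frequency scheme {codon_freqs!r}")
    else:
        freqs = np.asarray(codon_freqs, dtype=float)

    engine = CodonLikelihood(tree, caln, freqs)
    _require_clean(engine)
    fg_ids = (engine.foreground_ids(foreground_tips)
              if model in BRANCH_SITE_MODELS else frozenset())

    def neg(x: np.ndarray) -> float:
        params = _unpack(model, x)
        table = _class_table(model, params)
        lls = _class_logliks(engine, params["kappa"], table, fg_ids)
        return -engine.mixture_loglik([p for p, _, _ in table], lls)

    rng = np.random.default_rng(seed)
    x0, bounds = _pack(model, start_params or _DEFAULT_START[model])
    starts = [x0]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for _ in range(n_starts - 1):
        starts.append(lo + rng.random(len(bounds)) * (hi - lo))

    best = None
    start_lls = []
    any_converged = False
    for s in starts:
        res = minimize(neg, s, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": tol})
        start_lls.append(-float(res.fun))
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged and not np.isfinite(best.fun):
        raise RuntimeError(
            f"codon model {model} failed to converge in {n_starts} starts: "
            f"{best.message}")
    params = _unpack(model, best.x)
    return CodonFit(model=model, params=params, logL=-float(best.fun),
                    converged=any_converged, n_starts=n_starts,
                    start_logLs=start_lls,
                    foreground_tips=(list(foreground_tips)
                                     if foreground_tips else None),
                    codon_freqs=freqs)


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float
    null_model: str
    alt_model: str
    mixture_null: bool = False


def lrt(null: CodonFit, alt: CodonFit, df: Optional[int] = None,
        mixture: bool = False) -> LRTResult:
    """Likelihood-ratio test of nested codon models.

    ``mixture`` uses the 50:50 chi2_0 / chi2_1 null recommended for
    model A against its omega2=1 null; otherwise the chi-square upper
    tail with ``df`` degrees of freedom.
    """
    pair = (null.model, alt.model)
    if pair not in _NESTED_PAIRS:
        raise ValueError(f"models {pair} are not a supported nested pair")
    if df is None:
        df = _NESTED_PAIRS[pair]
    if alt.logL < null.logL - 1e-4:
        raise ValueError(
            "alternative likelihood is below the null beyond tolerance; "
            "refit with more starts")
    stat = max(0.0, 2.0 * (alt.logL - null.logL))
    if mixture:
        p = 0.5 * chi2.sf(stat, 1) + (0.5 if stat <= 0 else 0.0)
    else:
        p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(stat, df, min(1.0, float(p)), null.model, alt.model,
                     mixture_null=mixture)


# ---------------------------------------------------------------------------
# empirical Bayes site posteriors
# ---------------------------------------------------------------------------

@dataclass
class SitePosterior:
    """Per-site posterior over site classes.

    ``posterior`` is (n_sites, n_classes); the positively selected
    probability is the summed posterior of the omega2 classes (class 2
    for M2a; classes 2a+2b for model A).
    """

    model: str
    method: str
    class_names: list
    posterior: np.ndarray
    selected_prob: np.ndarray

    def selected_sites(self, threshold: float = 0.95) -> list[int]:
        """1-based codon positions with selected-class posterior > threshold."""
        return [i + 1 for i, p in enumerate(self.selected_prob)
                if p > threshold]


def _neb_posterior(engine: CodonLikelihood, model: str, params: dict,
                   fg_ids: frozenset) -> np.ndarray:
    table = _class_table(model, params)
    lls = np.stack(_class_logliks(engine, params["kappa"], table, fg_ids))
    props = np.array([p for p, _, _ in table])
    ref = lls.max(axis=0)
    joint = props[:, None] * np.exp(lls - ref)
    post = joint / joint.sum(axis=0, keepdims=True)
    return post.T  # (n_pat, n_class)


def _beb_posterior(engine: CodonLikelihood, model: str, params: dict,
                   fg_ids: frozenset, d: int = 10) -> np.ndarray:
    """Grid-averaged posterior over (p0, p1, omega0, omega2).

    A uniform prior is placed on a d-point grid per dimension (the
    proportions via the (p0+p1, p0/(p0+p1)) square, omega0 on (0,1),
    omega2 on (1, 11)); other parameters stay at their MLEs.  Grid
    points are weighted by the full-data likelihood.
    """
    kappa = params["kappa"]
    # branch lengths stay calibrated at the MLE's mixture scale
    scale = _mixture_scale(engine, kappa, _class_table(model, params))
    mids = (np.arange(d) + 0.5) / d
    w0_grid = mids                      # omega0 in (0,1)
    w2_grid = 1.0 + 10.0 * mids         # omega2 in (1,11)
    c_grid, f_grid = mids, mids

    # cache per-class site logliks for every needed omega value
    ll_w0 = {w0: engine.class_site_loglik(kappa, w0, w0, frozenset(),
                                          scale=scale)
             for w0 in w0_grid}
    ll_neutral = engine.class_site_loglik(kappa, 1.0, 1.0, frozenset(),
                                          scale=scale)
    if model == "M2a":
        ll_w2 = {w2: engine.class_site_loglik(kappa, w2, w2, frozenset(),
                                              scale=scale)
                 for w2 in w2_grid}
        ll_2a = None
    else:  # modelA
        ll_w2 = {w2: engine.class_site_loglik(kappa, 1.0, w2, fg_ids,
                                              scale=scale)
                 for w2 in w2_grid}
        ll_2a = {(w0, w2): engine.class_site_loglik(kappa, w0, w2, fg_ids,
                                                    scale=scale)
                 for w0 in w0_grid for w2 in w2_grid}

    # proportion grid as (n_cf, n_class)
    cf = [(c, f) for c in c_grid for f in f_grid]
    if model == "M2a":
        props = np.array([[c * f, c * (1 - f), 1 - c] for c, f in cf])
        n_class = 3
    else:
        props = np.array(
            [[c * f, c * (1 - f), (1 - c) * f, (1 - c) * (1 - f)]
             for c, f in cf])
        n_class = 4

    npat = engine.patterns.shape[1]
    weights = engine.weights
    num = np.zeros((npat, n_class))
    den = np.zeros(npat)
    log_evidence = []
    mixes = []
    for w0 in w0_grid:
        for w2 in w2_grid:
            if model == "M2a":
                lls = np.stack([ll_w0[w0], ll_neutral, ll_w2[w2]])
            else:
                lls = np.stack([ll_w0[w0], ll_neutral,
                                ll_2a[(w0, w2)], ll_w2[w2]])
            ref = lls.max(axis=0)
            L = np.exp(lls - ref)                     # (n_class, npat)
            mix = props @ L                           # (n_cf, npat)
            logZ = (weights * (np.log(mix) + ref)).sum(axis=1)
            log_evidence.append(logZ)
            mixes.append((L, mix))
    log_evidence = np.concatenate(log_evidence)       # (d*d*n_cf,)
    grid_post = np.exp(log_evidence - log_evidence.max())
    grid_post /= grid_post.sum()
    gp = grid_post.reshape(len(w0_grid) * len(w2_grid), len(cf))
    for block, (L, mix) in enumerate(mixes):
        g = gp[block]                                 # (n_cf,)
        # class posterior per site for each cf point, weighted by g
        joint = props[:, :, None] * L[None, :, :]     # (n_cf, n_class, npat)
        post = joint / mix[:, None, :]
        num += np.einsum("g,gcp->pc", g, post)
    total = num.sum(axis=1, keepdims=True)
    return num / total


def eb_site_posteriors(fit: CodonFit, tree: Tree, caln: CodonAlignment,
                       method: str = "BEB") -> SitePosterior:
    """NEB or grid-BEB site-class posteriors for M2a or model A."""
    if fit.model not in ("M2a", "modelA"):
        raise ValueError("site posteriors require an M2a or modelA fit")
    if method not in ("NEB", "BEB"):
        raise ValueError(f"unknown empirical-Bayes method {method!r}")
    engine = CodonLikelihood(tree, caln, fit.codon_freqs)
    _require_clean(engine)
    fg_ids = (engine.foreground_ids(fit.foreground_tips)
              if fit.model == "modelA" else frozenset())
    if method == "NEB":
        post_pat = _neb_posterior(engine, fit.model, fit.params, fg_ids)
    else:
        post_pat = _beb_posterior(engine, fit.model, fit.params, fg_ids)
    post = post_pat[engine.pattern_of_site]
    if fit.model == "M2a":
        names = ["omega0", "neutral", "positive"]
        sel = post[:, 2]
    else:
        names = ["0", "1", "2a", "2b"]
        sel = post[:, 2] + post[:, 3]
    return SitePosterior(fit.model, method, names, post, sel)
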