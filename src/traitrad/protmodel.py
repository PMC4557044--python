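"""Empirical amino-acid substitution models and ML pairwise distances.

The default model is WAG.  The rate matrix is assembled from published
exchangeabilities and stationary frequencies, normalised to one
expected substitution per site per unit time, and exponentiated through
the symmetric form  pi^{1/2} Q pi^{-1/2}  (valid for any reversible
model).  Distances are maximum-likelihood under the model, capped at
``t_max`` to guard against saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from ._wag import AA_ORDER, WAG_FREQS, wag_exchangeabilities
from .iocore import Alignment, FormatError

AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: maximum ML distance (substitutions/site); larger estimates saturate
T_MAX = 10.0


def discrete_gamma_rates(alpha: float, n_cat: int) -> np.ndarray:
    """Mean rates of ``n_cat`` equal-probability Gamma(alpha, alpha) bins."""
    quantiles = gamma_dist.ppf(
        (np.arange(n_cat) + 0.5) / n_cat, alpha, scale=1.0 / alpha)
    return quantiles / quantiles.mean()


class ReversibleMatrix:
    """Eigendecomposition of a reversible generator for fast exp(Qt)."""

    def __init__(self, S: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalise: 1 expected substitution per unit time at stationarity
        mu = -(pi * np.diag(Q)).sum()
        Q = Q / mu
        self.pi = pi
        self.Q = Q
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        B = (B + B.T) / 2.0  # symmetrise numerical noise
        evals, evecs = np.linalg.eigh(B)
        self._evals = evals
        self._U = evecs / sqrt_pi[:, None]            # pi^{-1/2} U
        self._V = evecs.T * sqrt_pi[None, :]          # U' pi^{1/2}

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ValueError("negative time")
        P = (self._U * np.exp(self._evals * t)) @ self._V
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


@dataclass
class SubstitutionModel:
    """Named empirical amino-acid model, optionally with Gamma rates.

    Parameters
    ----------
    name : str
        Only ``"WAG"`` is built in.
    alpha : float, optional
        Gamma shape; ``None`` disables among-site rate heterogeneity.
    n_categories : int
        Number of discrete Gamma categories when ``alpha`` is set.
    """

    name: str = "WAG"
    alpha: Optional[float] = None
    n_categories: int = 4
    _matrix: ReversibleMatrix = field(init=False, repr=False)

    def __post_init__(self):
        if self.name.upper() != "WAG":
            raise ValueError(f"unknown substitution model {self.name!r}")
        self._matrix = ReversibleMatrix(wag_exchangeabilities(), WAG_FREQS)

    @property
    def pi(self) -> np.ndarray:
        return self._matrix.pi

    @property
    def n_states(self) -> int:
        return 20

    def rate_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the discrete-Gamma mixture (or a point)."""
        if self.alpha is None:
            return np.array([1.0]), np.array([1.0])
        rates = discrete_gamma_rates(self.alpha, self.n_categories)
        weights = np.full(self.n_categories, 1.0 / self.n_categories)
        return rates, weights

    def transition(self, t: float, rate: float = 1.0) -> np.ndarray:
        return self._matrix.transition(t * rate)


def encode_protein_alignment(aln: Alignment) -> np.ndarray:
    """Row-major integer codes: residue index 0..19, or -1 for gap/X."""
    codes = np.full((aln.n_rows, aln.n_columns), -1, dtype=np.int16)
    for r, row in enumerate(aln.rows):
        for c, ch in enumerate(row):
            codes[r, c] = AA_INDEX.get(ch, -1)
    return codes


@dataclass
class DistanceMatrix:
    """Symmetric ML distance matrix over sequence ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite and non-negative")

    def __getitem__(self, pair) -> float:
        a, b = pair
        return self.values[self.ids.index(a), self.ids.index(b)]


def _pair_counts(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """20x20 joint counts over columns where both rows are determinate."""
    mask = (codes_a >= 0) & (codes_b >= 0)
    a = codes_a[mask].astype(np.int64)
    b = codes_b[mask].astype(np.int64)
    return np.bincount(a * 20 + b, minlength=400).reshape(20, 20).astype(float)


def ml_distance_from_counts(N: np.ndarray, model: SubstitutionModel) -> float:
    """ML distance given a 20x20 joint count matrix."""
    if N.sum() == 0:
        raise FormatError("no shared determinate columns between rows")
    pi = model.pi
    off = N.sum() - np.trace(N)
    if off == 0:
        return 0.0

    def neg_loglik(t: float) -> float:
        P = model.transition(t)
        M = pi[:, None] * P
        with np.errstate(divide="ignore"):
            logM = np.log(M)
        return -(N * logM)[N > 0].sum()

    res = minimize_scalar(neg_loglik, bounds=(1e-9, T_MAX), method="bounded",
                          options={"xatol": 1e-8})
    t_hat = float(res.x)
    # accept boundary solutions (saturation cap)
    if neg_loglik(1e-9) <= res.fun:
        t_hat = 0.0
    return min(t_hat, T_MAX)


def ml_distance(row_a: str, row_b: str, model: SubstitutionModel) -> float:
    """ML distance between two aligned protein rows (gaps skipped)."""
    if len(row_a) != len(row_b):
        raise FormatError("aligned rows differ in length")
    aln = Alignment(["a", "b"], [row_a, row_b], kind="protein")
    codes = encode_protein_alignment(aln)
    return ml_distance_from_counts(_pair_counts(codes[0], codes[1]), model)


def distance_matrix(aln: Alignment,
                    model: Optional[SubstitutionModel] = None) -> DistanceMatrix:
    """All pairwise ML distances of an alignment."""
    model = model or SubstitutionModel()
    codes = encode_protein_alignment(aln)
    n = aln.n_rows
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = ml_distance_from_counts(
                _pair_counts(codes[i], codes[j]), model)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(aln.ids), D)
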