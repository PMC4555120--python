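"""Empirical amino-acid substitution models with +I / +Gamma rate
heterogeneity.

A model is a symmetric exchangeability matrix S and equilibrium frequencies
pi; the instantaneous rate matrix is Q_ij = S_ij * pi_j (i != j) with the
diagonal filled so rows sum to zero, scaled so the expected substitution
rate at equilibrium is 1 (branch lengths are then expected substitutions
per site).  Rate heterogeneity across sites uses the discrete-gamma
approximation (equal-probability categories represented by their means)
plus an optional proportion of invariant sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.stats import gamma as _gamma_dist

from ._matrices import (
    AA_ORDER,
    JTT_EXCHANGEABILITIES,
    JTT_FREQUENCIES,
    WAG_EXCHANGEABILITIES,
    WAG_FREQUENCIES,
)

N_STATES = 20
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


def _square_from_lower(flat) -> np.ndarray:
    """Rebuild the symmetric 20x20 matrix from its column-major lower triangle."""
    m = np.zeros((N_STATES, N_STATES))
    it = iter(flat)
    for j in range(N_STATES - 1):
        for i in range(j + 1, N_STATES):
            m[i, j] = m[j, i] = next(it)
    return m


_MATRICES = {
    "WAG": (WAG_EXCHANGEABILITIES, WAG_FREQUENCIES),
    "JTT": (JTT_EXCHANGEABILITIES, JTT_FREQUENCIES),
}


def discretize_gamma(alpha: float, n_cat: int) -> np.ndarray:
    """Discrete-gamma category rates: equal-probability bins represented by
    their conditional means, normalized to mean exactly 1.

    The gamma density has shape ``alpha`` and mean 1 (scale ``1/alpha``).
    Rates are strictly increasing in the category index.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if n_cat < 1:
        raise ValueError("n_cat must be >= 1")
    if n_cat == 1:
        return np.ones(1)
    scale = 1.0 / alpha
    edges = _gamma_dist.ppf(np.linspace(0, 1, n_cat + 1), a=alpha, scale=scale)
    # conditional mean over [q_i, q_{i+1}] via the shape alpha+1 CDF identity
    upper_cdf = _gamma_dist.cdf(edges, a=alpha + 1, scale=scale)
    rates = n_cat * np.diff(upper_cdf)  # each bin has probability 1/n_cat
    rates = rates / rates.mean()
    return rates


@dataclass(frozen=True)
class SubstitutionModel:
    """An amino-acid replacement model, optionally with +I and +Gamma."""

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float | None = None
    p_inv: float | None = None
    n_cat: int = 4

    def __post_init__(self):
        s = np.asarray(self.exchangeabilities, dtype=float)
        f = np.asarray(self.frequencies, dtype=float)
        if s.shape != (N_STATES, N_STATES) or not np.allclose(s, s.T):
            raise ValueError("exchangeabilities must be a symmetric 20x20 matrix")
        if np.any(s < 0) or np.any(f <= 0):
            raise ValueError("exchangeabilities/frequencies must be non-negative")
        f = f / f.sum()
        object.__setattr__(self, "exchangeabilities", s)
        object.__setattr__(self, "frequencies", f)
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.p_inv is not None and not 0 <= self.p_inv < 1:
            raise ValueError("p_inv must be in [0, 1)")

    # -- derived quantities -------------------------------------------------

    @cached_property
    def rate_matrix(self) -> np.ndarray:
        """Q scaled so the expected rate at equilibrium is 1."""
        q = self.exchangeabilities * self.frequencies[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(self.frequencies, np.diag(q))
        return q / mu

    @cached_property
    def _eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition of Q via its symmetrized form.

        Returns (eigenvalues, A, B) with P(t) = A @ diag(exp(lam t)) @ B.
        """
        pi = self.frequencies
        d = np.sqrt(pi)
        sym = (self.rate_matrix * d[:, None]) / d[None, :]
        lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
        a = u / d[:, None]
        b = u.T * d[None, :]
        return lam, a, b

    @property
    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.ones(1)
        return discretize_gamma(self.alpha, self.n_cat)

    @property
    def category_weights(self) -> np.ndarray:
        r = self.category_rates
        return np.full(len(r), 1.0 / len(r))

    @property
    def proportion_invariant(self) -> float:
        return 0.0 if self.p_inv is None else self.p_inv

    def transition_matrices(self, lengths) -> np.ndarray:
        """P(t) for an array of branch lengths; shape (len(lengths), 20, 20)."""
        lam, a, b = self._eigen
        t = np.atleast_1d(np.asarray(lengths, dtype=float))
        if np.any(t < 0):
            raise ValueError("negative branch length")
        ev = np.exp(np.outer(t, lam))
        p = np.einsum("ik,ek,kj->eij", a, ev, b)
        np.clip(p, 0.0, None, out=p)
        # renormalize rows (clipping can leave rows slightly off 1)
        p /= p.sum(axis=2, keepdims=True)
        p[t == 0.0] = np.eye(N_STATES)  # exact identity at zero length
        return p

    def transition_matrix(self, length: float) -> np.ndarray:
        return self.transition_matrices([length])[0]

    # -- constructors -------------------------------------------------------

    def with_rates(self, alpha=None, p_inv=None, n_cat=None) -> "SubstitutionModel":
        return SubstitutionModel(
            self.name,
            self.exchangeabilities,
            self.frequencies,
            alpha=self.alpha if alpha is None else alpha,
            p_inv=self.p_inv if p_inv is None else p_inv,
            n_cat=self.n_cat if n_cat is None else n_cat,
        )


def get_model(
    name: str,
    alpha: float | None = None,
    p_inv: float | None = None,
    n_cat: int = 4,
) -> SubstitutionModel:
    """Look up an embedded matrix by name; accepts "WAG", "WAG+G", "WAG+I+G".

    The +I / +G suffixes switch the corresponding components on with default
    parameters (alpha=1.0, p_inv=0.0) unless explicit values are given.
    """
    parts = name.upper().split("+")
    base = parts[0]
    if base not in _MATRICES:
        raise KeyError(f"unknown substitution matrix {base!r}")
    use_g = "G" in parts[1:]
    use_i = "I" in parts[1:]
    exch, freqs = _MATRICES[base]
    if use_g and alpha is None:
        alpha = 1.0
    if use_i and p_inv is None:
        p_inv = 0.0
    return SubstitutionModel(
        base,
        _square_from_lower(exch),
        np.asarray(freqs),
        alpha=alpha,
        p_inv=p_inv,
        n_cat=n_cat,
    )
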