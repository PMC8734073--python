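"""Stationary, reversible substitution models with discrete-gamma rate variation.

A model is defined by a symmetric exchangeability matrix ``S`` and stationary
frequencies ``pi``; the instantaneous rate matrix is ``Q[i, j] = S[i, j] * pi[j]``
with rows normalised so the expected substitution rate at stationarity is one —
branch lengths are then expected substitutions per site.  Across-site rate
variation uses the standard four-category discrete gamma (equal-probability
categories represented by their means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.linalg import eigh

from .lg_data import LG_EXCHANGEABILITIES, LG_FREQUENCIES, LG_RESIDUE_ORDER

AMINO_ACIDS = LG_RESIDUE_ORDER

DEFAULT_N_CATEGORIES = 4


def discrete_gamma_rates(alpha: float, n_categories: int = DEFAULT_N_CATEGORIES) -> np.ndarray:
    """Mean rates of ``n`` equal-probability categories of Gamma(alpha, 1/alpha).

    The mean of the k-th quantile slice has the closed form
    ``n * (I(alpha+1, a*b_{k+1}) - I(alpha+1, a*b_k))`` where ``I`` is the
    regularised lower incomplete gamma function and ``b_k`` the category
    boundaries.  ``alpha = None`` or ``inf`` means rate homogeneity.
    """
    if alpha is None or np.isinf(alpha):
        return np.ones(n_categories)
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    from scipy.stats import gamma as gamma_dist

    probs = np.arange(1, n_categories) / n_categories
    bounds = gamma_dist.ppf(probs, alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    upper = gammainc(alpha + 1.0, alpha * bounds[1:])
    lower = gammainc(alpha + 1.0, alpha * bounds[:-1])
    rates = n_categories * (upper - lower)
    # guard: means must average to 1 by construction
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """Reversible k-state substitution model with discrete-gamma rates.

    Parameters
    ----------
    exchangeabilities : symmetric (k, k) matrix, zero diagonal.
    frequencies : stationary distribution on the k states.
    alpha : gamma shape for across-site rate variation; ``None`` disables it.
    n_categories : number of discrete gamma categories (4 by convention).
    states : the state alphabet, one character per state.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float | None = None
    n_categories: int = DEFAULT_N_CATEGORIES
    states: str = AMINO_ACIDS
    name: str = "custom"
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        k = len(self.states)
        if S.shape != (k, k):
            raise ValueError(f"exchangeability matrix must be ({k},{k}), got {S.shape}")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if pi.shape != (k,) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("frequencies must be a length-k simplex vector")
        self.exchangeabilities = S
        self.frequencies = pi / pi.sum()
        self._eig = None

    @property
    def n_states(self) -> int:
        return len(self.states)

    def rate_matrix(self) -> np.ndarray:
        """Normalised rate matrix Q; rows sum to zero, mean rate one."""
        pi = self.frequencies
        Q = self.exchangeabilities * pi[np.newaxis, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_categories)

    def _eigendecomposition(self):
        """Symmetrised eigendecomposition of Q for fast matrix exponentials."""
        if self._eig is None:
            pi = self.frequencies
            sq = np.sqrt(pi)
            Q = self.rate_matrix()
            B = (sq[:, None] * Q) / sq[None, :]
            w, U = eigh((B + B.T) / 2.0)
            self._eig = (w, U, sq)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows are conditional distributions."""
        if t < 0:
            raise ValueError(f"negative evolutionary distance: {t}")
        w, U, sq = self._eigendecomposition()
        E = U @ np.diag(np.exp(w * t)) @ U.T
        P = (E / sq[:, None]) * sq[None, :]
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    def with_alpha(self, alpha: float | None) -> "SubstitutionModel":
        return SubstitutionModel(
            self.exchangeabilities, self.frequencies, alpha=alpha,
            n_categories=self.n_categories, states=self.states, name=self.name,
        )


def lg_model(alpha: float | None = None) -> SubstitutionModel:
    """The LG empirical amino-acid model with its published frequencies."""
    return SubstitutionModel(
        LG_EXCHANGEABILITIES, LG_FREQUENCIES, alpha=alpha, name="LG",
    )


def poisson_model(n_states: int = 20, states: str | None = None,
                  alpha: float | None = None) -> SubstitutionModel:
    """Equal-rates, equal-frequencies model (the Poisson/JC special case)."""
    S = np.ones((n_states, n_states)) - np.eye(n_states)
    pi = np.full(n_states, 1.0 / n_states)
    return SubstitutionModel(
        S, pi, alpha=alpha, states=states or AMINO_ACIDS[:n_states], name="Poisson",
    )


def kstate_model(frequencies: np.ndarray, states: str,
                 alpha: float | None = None) -> SubstitutionModel:
    """Equal-exchangeability model with empirical frequencies, for recoded data."""
    k = len(states)
    S = np.ones((k, k)) - np.eye(k)
    return SubstitutionModel(S, np.asarray(frequencies), alpha=alpha,
                             states=states, name=f"F{k}")
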