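"""Nucleotide substitution models for likelihood computations.

The model family axis (JC69, K80, F81, HKY85, GTR) spans the complexity range
relevant for closely related plant nuclear loci; among-site rate
heterogeneity is handled by a discrete gamma with equal-probability
categories represented by their category means.  All models are
time-reversible, so the rate matrix is diagonalized once per parameter set
via the pi^(1/2) similarity transform and transition matrices P(t) are cheap
per branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

BASES = "ACGT"

FAMILIES = ("JC69", "K80", "F81", "HKY85", "GTR")

#: free parameters per family (exchangeabilities + frequencies)
_FREE_PARAMS = {"JC69": 0, "K80": 1, "F81": 3, "HKY85": 4, "GTR": 8}


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible nucleotide model, optionally with discrete-gamma rates.

    Parameters
    ----------
    family:
        One of JC69, K80, F81, HKY85, GTR.
    freqs:
        Equilibrium base frequencies in A, C, G, T order.  Forced to 1/4
        for JC69/K80.
    kappa:
        Transition/transversion rate ratio (K80, HKY85).
    exchangeabilities:
        Six GTR exchangeabilities in AC, AG, AT, CG, CT, GT order
        (GT acts as the reference rate).
    gamma_categories:
        Number of discrete gamma rate categories; 0 disables rate
        heterogeneity.
    alpha:
        Gamma shape for among-site rate variation (required when
        ``gamma_categories > 0``).
    """

    family: str = "HKY85"
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    kappa: float = 2.0
    exchangeabilities: Optional[tuple[float, ...]] = None
    gamma_categories: int = 0
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or np.any(f <= 0):
            raise ValueError("freqs must be four positive numbers")
        if abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("freqs must sum to 1")
        if self.family in ("JC69", "K80") and np.any(np.abs(f - 0.25) > 1e-12):
            object.__setattr__(self, "freqs", (0.25, 0.25, 0.25, 0.25))
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.family == "GTR":
            ex = self.exchangeabilities
            if ex is None or len(ex) != 6 or any(r <= 0 for r in ex):
                raise ValueError("GTR requires six positive exchangeabilities")
        if self.gamma_categories:
            if self.gamma_categories < 2:
                raise ValueError("gamma_categories must be 0 or >= 2")
            if self.alpha is None or self.alpha <= 0:
                raise ValueError("alpha must be positive when gamma rates are on")

    # -- derived quantities -------------------------------------------------

    @property
    def n_free_parameters(self) -> int:
        """Free model parameters counted for AIC (excludes branch lengths)."""
        k = _FREE_PARAMS[self.family]
        if self.gamma_categories:
            k += 1
        return k

    def with_(self, **kw) -> "SubstitutionModel":
        return replace(self, **kw)

    def rate_matrix(self) -> np.ndarray:
        """Instantaneous rate matrix Q, scaled to one expected substitution
        per unit branch length at equilibrium."""
        pi = np.asarray(self.freqs, dtype=float)
        if self.family in ("JC69", "F81"):
            s = np.ones(6)
        elif self.family in ("K80", "HKY85"):
            # transitions: A<->G (index 1) and C<->T (index 4)
            s = np.array([1.0, self.kappa, 1.0, 1.0, self.kappa, 1.0])
        else:
            s = np.asarray(self.exchangeabilities, dtype=float)
        Q = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), rate in zip(pairs, s):
            Q[i, j] = rate * pi[j]
            Q[j, i] = rate * pi[i]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.sum(pi * np.diag(Q))
        return Q / mu

    def category_rates(self) -> np.ndarray:
        """Relative rates of the discrete gamma categories (mean 1)."""
        if not self.gamma_categories:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.gamma_categories)


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean-of-category discretization of a mean-1 gamma into ``k``
    equal-probability categories.

    Category i covers the quantile band (i/k, (i+1)/k); its representative
    rate is the conditional mean of the band, computed from the regularized
    incomplete gamma function, so the discretized rates always average to 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    bounds = _gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    x = np.concatenate([[0.0], bounds * alpha, [np.inf]])
    cum = gammainc(alpha + 1.0, x)
    rates = k * np.diff(cum)
    return rates / rates.mean()


class ModelMatrices:
    """Pre-diagonalized model: cheap transition matrices per branch.

    For a reversible Q, B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric;
    with B = U L U', P(t) = diag(1/sqrt(pi)) U exp(L t) U' diag(sqrt(pi)).
    """

    def __init__(self, model: SubstitutionModel):
        self.model = model
        self.pi = np.asarray(model.freqs, dtype=float)
        Q = model.rate_matrix()
        sq = np.sqrt(self.pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)  # symmetrize against roundoff
        lam, U = np.linalg.eigh(B)
        self.lam = lam
        self._left = U / sq[:, None]          # diag(1/sqrt(pi)) U
        self._right = (U * sq[:, None]).T     # U' diag(sqrt(pi))
        self.rates = model.category_rates()   # (ncat,)
        self.ncat = len(self.rates)

    def transition(self, t: float) -> np.ndarray:
        """P(t) per rate category, shape (ncat, 4, 4)."""
        e = np.exp(np.outer(self.rates * t, self.lam))  # (ncat, 4)
        P = np.einsum("ij,cj,jk->cik", self._left, e, self._right)
        np.clip(P, 0.0, None, out=P)
        return P


def empirical_frequencies(seqs: list[str]) -> tuple[float, float, float, float]:
    """Base frequencies counted over unambiguous characters, with a small
    floor so no frequency is exactly zero."""
    counts = np.zeros(4)
    for s in seqs:
        for i, b in enumerate(BASES):
            counts[i] += s.upper().count(b)
    counts = np.maximum(counts, 1.0)
    f = counts / counts.sum()
    return tuple(f)
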