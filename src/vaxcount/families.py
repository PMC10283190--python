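"""Count distributions for vaccine-uptake modelling.

Four families are supported: Poisson, negative binomial (NB), and their
zero-inflated versions (ZIP, ZINB).  All four share a single mean
parameter ``mu``; the NB families add a dispersion parameter ``k`` with

    Var(Y) = mu + mu**2 / k,

so ``k -> inf`` recovers the Poisson, and the zero-inflated families add
a structural-zero probability ``pi`` in [0, 1):

    P(Y = 0) = pi + (1 - pi) * P_base(0),
    P(Y = y) = (1 - pi) * P_base(y),   y >= 1.

Everything is computed through log-gamma functions, never factorials, so
log-probabilities stay finite over the whole parameter range used here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp


class Family(str, enum.Enum):
    """The four count families."""

    POISSON = "poisson"
    NB = "nb"
    ZIP = "zip"
    ZINB = "zinb"

    @property
    def has_dispersion(self) -> bool:
        return self in (Family.NB, Family.ZINB)

    @property
    def has_zero_inflation(self) -> bool:
        return self in (Family.ZIP, Family.ZINB)


@dataclass(frozen=True)
class FamilyParams:
    """Distribution parameters for one count family.

    Parameters
    ----------
    family : Family
        Which of the four families.
    mu : float
        Mean of the count component (> 0).
    k : float, optional
        NB dispersion; required for nb/zinb, forbidden otherwise.
        Variance of the count component is ``mu + mu**2 / k``.
    pi : float, optional
        Structural-zero probability in [0, 1); required for zip/zinb,
        forbidden otherwise.  ``pi = 1`` (a degenerate all-zero model)
        is rejected.
    """

    family: Family
    mu: float
    k: float | None = None
    pi: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        fam = self.family
        if not np.all(np.asarray(self.mu) > 0):
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if fam.has_dispersion:
            if self.k is None:
                raise ValueError(f"family {fam.value!r} requires dispersion k")
            if not np.all(np.asarray(self.k) > 0):
                raise ValueError(f"k must be > 0, got {self.k}")
        elif self.k is not None:
            raise ValueError(f"family {fam.value!r} does not take dispersion k")
        if fam.has_zero_inflation:
            if self.pi is None:
                raise ValueError(f"family {fam.value!r} requires zero-inflation pi")
            p = np.asarray(self.pi)
            if not np.all((p >= 0) & (p < 1)):
                raise ValueError(f"pi must lie in [0, 1), got {self.pi}")
        elif self.pi is not None:
            raise ValueError(f"family {fam.value!r} does not take zero-inflation pi")


def _log_pmf_poisson(y, mu):
    return y * np.log(mu) - mu - gammaln(y + 1)


def _log_pmf_nb(y, mu, k):
    # Gamma(k+y)/(Gamma(k) y!) * (k/(k+mu))^k * (mu/(k+mu))^y
    k = np.asarray(k, dtype=float)
    # log Gamma(k+y) - log Gamma(k): direct difference of gammaln values
    # loses ~k*eps absolute precision for huge k; switch to the asymptotic
    # sum_{i<y} log(1+i/k) expansion where that noise would dominate
    ratio_big = (y * np.log(k) + y * (y - 1) / (2 * k)
                 - y * (y - 1) * (2 * y - 1) / (12 * k**2))
    ratio = np.where(k > 1e6, ratio_big, gammaln(k + y) - gammaln(k))
    log_mu_frac = np.log(mu) - np.log(k + mu)
    return ratio - gammaln(y + 1) - k * np.log1p(mu / k) + y * log_mu_frac


def _with_log(p):
    """log(p) tolerating p == 0 (gives -inf, silently)."""
    with np.errstate(divide="ignore"):
        return np.log(p)


def _zero_inflate(y, base_logpmf, pi):
    """Mix a point mass at zero (weight pi) into base log-pmf values."""
    log_pi = _with_log(np.broadcast_to(np.asarray(pi, dtype=float), np.shape(base_logpmf)))
    log_1mpi = np.log1p(-np.asarray(pi, dtype=float))
    inflated0 = np.logaddexp(log_pi, log_1mpi + base_logpmf)
    return np.where(np.asarray(y) == 0, inflated0, log_1mpi + base_logpmf)


def log_pmf_array(y, family: Family, mu, k=None, pi=None) -> np.ndarray:
    """Vectorised log P(Y = y); inputs broadcast. No validation (hot path)."""
    y = np.asarray(y, dtype=float)
    family = Family(family)
    if family is Family.POISSON:
        return _log_pmf_poisson(y, mu)
    if family is Family.NB:
        return _log_pmf_nb(y, mu, k)
    if family is Family.ZIP:
        return _zero_inflate(y, _log_pmf_poisson(y, mu), pi)
    return _zero_inflate(y, _log_pmf_nb(y, mu, k), pi)


def log_pmf(y, params: FamilyParams) -> np.ndarray | float:
    """Log probability mass log P(Y = y) for one parameterised family.

    ``y`` may be a scalar or an array of non-negative integers.
    """
    y_arr = np.asarray(y)
    if not np.issubdtype(y_arr.dtype, np.integer):
        if not np.all(np.asarray(y_arr, dtype=float) == np.floor(y_arr)):
            raise ValueError(f"y must be integer, got {y}")
    if np.any(y_arr < 0):
        raise ValueError(f"y must be non-negative, got {y}")
    out = log_pmf_array(y_arr, params.family, params.mu, params.k, params.pi)
    return float(out) if np.isscalar(y) or y_arr.ndim == 0 else out


def mean_variance(params: FamilyParams) -> tuple[float, float]:
    """Analytic mean and variance of the family.

    poisson: (mu, mu); nb: (mu, mu + mu^2/k);
    zip:  mean (1-pi)mu, var (1-pi)mu(1 + pi mu);
    zinb: mean (1-pi)mu, var (1-pi)mu(1 + mu/k + pi mu).
    """
    fam, mu = params.family, params.mu
    if fam is Family.POISSON:
        return mu, mu
    if fam is Family.NB:
        return mu, mu + mu**2 / params.k
    pi = params.pi
    m = (1 - pi) * mu
    if fam is Family.ZIP:
        return m, m * (1 + pi * mu)
    return m, m * (1 + mu / params.k + pi * mu)


def sample(params: FamilyParams, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. counts; reproducible given ``seed``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return sample_with_rng(rng, params.family, params.mu, params.k, params.pi, n)


def sample_with_rng(rng, family: Family, mu, k=None, pi=None, n: int | None = None):
    """Sampling core reused by the hierarchical generator.

    ``mu``/``pi`` may be arrays (per-observation parameters); ``n`` is only
    needed when all parameters are scalars.
    """
    family = Family(family)
    mu = np.asarray(mu, dtype=float)
    size = mu.shape if mu.ndim else (n,)
    mu = np.broadcast_to(mu, size)
    if family in (Family.POISSON, Family.ZIP):
        counts = rng.poisson(mu)
    else:
        # NB as gamma-Poisson mixture: shape k, mean mu
        lam = rng.gamma(shape=k, scale=mu / k)
        counts = rng.poisson(lam)
    if family.has_zero_inflation:
        structural = rng.random(size) < np.broadcast_to(np.asarray(pi, dtype=float), size)
        counts = np.where(structural, 0, counts)
    return counts.astype(np.int64)


def adaptive_support(params: FamilyParams, tail: float = 1e-12) -> int:
    """Upper support bound Y* leaving at most ``tail`` mass above it."""
    m, v = mean_variance(params)
    hi = int(np.ceil(m + 20 * np.sqrt(v) + 20))
    while True:
        y = np.arange(hi + 1)
        total = np.exp(logsumexp(log_pmf_array(y, params.family, params.mu, params.k, params.pi)))
        if total >= 1 - tail or hi > 10**7:
            return hi
        hi *= 2
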