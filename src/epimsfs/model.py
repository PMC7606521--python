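"""Stationary distribution of methylated-epiallele frequency and the
mSFS likelihood.

For a hypermutable biallelic locus with methylation gain rate mu,
loss rate nu and selection coefficient s in a population of effective
size Ne, the stationary density of the methylated-allele frequency q is

    phi(q) = C * exp(gamma*q) * (1-q)**(alpha-1) * q**(beta-1)

with alpha = 4*Ne*mu, beta = 4*Ne*nu, gamma = 4*Ne*s, and C the
normalization constant making phi integrate to 1 on (0, 1). Because mu
and nu are much larger than point-mutation rates, alpha and beta are
O(0.01-1) and the density is typically singular at both endpoints.

Only the scaled parameters (alpha, beta, gamma) are identifiable from
an mSFS; fits at different assumed Ne trade (mu, nu, s) against Ne
while Ne*s stays constant.

Numerics: integrals against the (1-q)**(alpha-1) * q**(beta-1) weight
use Gauss-Jacobi quadrature (order 128 by default), which absorbs the
endpoint singularities exactly. The expected spectrum additionally has
an exact closed form through Kummer's confluent hypergeometric
function, used as the fast evaluation route in the likelihood:

    p_k = C(m,k) * B(k+beta, m-k+alpha) * 1F1(k+beta; m+alpha+beta; gamma)
          / (B(beta, alpha) * 1F1(beta; alpha+beta; gamma))

For gamma beyond ~600 the 1F1 values overflow double precision and the
evaluation falls back to log-space Gauss-Jacobi sums.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln, hyp1f1, roots_jacobi

LOG_CLAMP = -745.0  # smallest log representable before exp underflows
_HYP1F1_GAMMA_MAX = 600.0

_jacobi_cache: dict = {}


@dataclass(frozen=True)
class ModelParams:
    """Epimutation rates, selection coefficient and population size.

    ``swap_exponents`` selects the conventional mutation-drift exponent
    assignment (alpha-1 on q, beta-1 on 1-q) instead of the default
    parameterization above; both are exposed because the default places
    the gain-rate exponent on the unmethylated-allele frequency, which
    is at odds with standard notation for two-allele mutation models.
    """

    mu: float
    nu: float
    s: float
    ne: float
    swap_exponents: bool = False

    def __post_init__(self):
        if self.mu <= 0 or self.nu <= 0:
            raise ValueError("epimutation rates must be positive")
        if self.ne <= 0:
            raise ValueError("Ne must be positive")

    @property
    def alpha(self) -> float:
        return 4.0 * self.ne * self.mu

    @property
    def beta(self) -> float:
        return 4.0 * self.ne * self.nu

    @property
    def gamma(self) -> float:
        return 4.0 * self.ne * self.s

    def exponents(self) -> tuple[float, float]:
        """(exponent base on 1-q, exponent base on q), i.e. phi has
        (1-q)**(a-1) * q**(b-1)."""
        if self.swap_exponents:
            return self.beta, self.alpha
        return self.alpha, self.beta

    @classmethod
    def from_scaled(cls, alpha: float, beta: float, gamma: float,
                    ne: float, **kw) -> "ModelParams":
        f = 4.0 * ne
        return cls(alpha / f, beta / f, gamma / f, ne, **kw)


def _jacobi_nodes(order: int, a: float, b: float):
    """Nodes/weights on (0,1) for weight q**(b-1) * (1-q)**(a-1).

    Returns (q, w) such that integral f(q) q^(b-1) (1-q)^(a-1) dq
    ~= sum w_i f(q_i); the 2**(1-a-b) change-of-interval factor is
    folded into w.
    """
    key = (order, a, b)
    hit = _jacobi_cache.get(key)
    if hit is not None:
        return hit
    x, w = roots_jacobi(order, a - 1.0, b - 1.0)
    q = 0.5 * (x + 1.0)
    w = w * 2.0 ** (1.0 - a - b)
    if len(_jacobi_cache) > 256:
        _jacobi_cache.clear()
    _jacobi_cache[key] = (q, w)
    return q, w


def _log_norm_integral(a: float, b: float, gamma: float, order: int) -> float:
    """log of integral_0^1 e^(gamma q) (1-q)^(a-1) q^(b-1) dq."""
    if a <= 0 or b <= 0:
        raise ValueError("alpha and beta must be positive")
    q, w = _jacobi_nodes(order, a, b)
    logs = np.log(w) + gamma * q
    mx = logs.max()
    val = mx + np.log(np.exp(logs - mx).sum())
    if not np.isfinite(val):
        raise FloatingPointError("non-finite normalization integral")
    return float(val)


def normalization_constant(params: ModelParams, order: int = 128) -> float:
    """The constant C making the stationary density integrate to 1."""
    a, b = params.exponents()
    return float(np.exp(-_log_norm_integral(a, b, params.gamma, order)))


def log_density(q, params: ModelParams, order: int = 128):
    """Normalized log phi(q) for q strictly inside (0, 1)."""
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("q must lie strictly inside (0, 1); the density "
                         "may be singular at the endpoints")
    a, b = params.exponents()
    log_c = -_log_norm_integral(a, b, params.gamma, order)
    out = log_c + params.gamma * q + (a - 1) * np.log1p(-q) + (b - 1) * np.log(q)
    return float(out) if out.ndim == 0 else out


def _log_expected_sfs_closed(a: float, b: float, gamma: float,
                             m: int) -> np.ndarray:
    k = np.arange(m + 1)
    lbinom = gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)
    log_f = np.log(hyp1f1(k + b, m + a + b, gamma))
    log_f0 = np.log(hyp1f1(b, a + b, gamma))
    out = (lbinom + betaln(k + b, m - k + a) - betaln(b, a) + log_f - log_f0)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("closed-form evaluation failed")
    return out


def _log_expected_sfs_jacobi(a: float, b: float, gamma: float, m: int,
                             order: int) -> np.ndarray:
    q, w = _jacobi_nodes(order, a, b)
    k = np.arange(m + 1)
    lbinom = gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)
    # (m+1, order) log-integrand matrix
    logs = (np.log(w)[None, :] + gamma * q[None, :]
            + k[:, None] * np.log(q)[None, :]
            + (m - k)[:, None] * np.log1p(-q)[None, :])
    mx = logs.max(axis=1, keepdims=True)
    log_int = mx[:, 0] + np.log(np.exp(logs - mx).sum(axis=1))
    return lbinom + log_int - _log_norm_integral(a, b, gamma, order)


def log_expected_sfs(params: ModelParams, m: int, order: int = 128,
                     method: str = "auto") -> np.ndarray:
    """log p_k, k = 0..m, of the binomially sampled stationary density.

    ``method``: "closed_form" (Kummer 1F1), "jacobi" (Gauss-Jacobi),
    or "auto" — closed form where it is numerically safe, quadrature
    otherwise.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    a, b = params.exponents()
    gamma = params.gamma
    if method == "auto":
        method = ("closed_form" if abs(gamma) < _HYP1F1_GAMMA_MAX
                  else "jacobi")
    if method == "closed_form":
        try:
            return _log_expected_sfs_closed(a, b, gamma, m)
        except FloatingPointError:
            return _log_expected_sfs_jacobi(a, b, gamma, m, order)
    if method == "jacobi":
        return _log_expected_sfs_jacobi(a, b, gamma, m, order)
    raise ValueError("method must be 'auto', 'closed_form' or 'jacobi'")


def expected_sfs(params: ModelParams, m: int, order: int = 128,
                 method: str = "jacobi") -> np.ndarray:
    """Expected mSFS probabilities p_k = integral C(m,k) q^k (1-q)^(m-k)
    phi(q) dq for k = 0..m."""
    return np.exp(log_expected_sfs(params, m, order=order, method=method))


def msfs_loglik(msfs, params: ModelParams, order: int = 128,
                method: str = "auto") -> float:
    """Multinomial log-likelihood (up to a constant) of one or more
    observed spectra under shared parameters.

    Bins with zero observed count contribute nothing even when p_k
    underflows. log p_k is evaluated in log space, so positive-count
    bins keep their exact (possibly far below -745) log-probability and
    the likelihood surface stays informative in the extreme-selection
    regime; a clamp at -745 applies only where the evaluation yields
    -inf outright.
    """
    spectra = msfs if isinstance(msfs, (list, tuple)) else [msfs]
    if not spectra:
        raise ValueError("no spectra supplied")
    total = 0.0
    for s in spectra:
        logp = log_expected_sfs(params, s.m, order=order, method=method)
        logp = np.where(np.isfinite(logp), logp, LOG_CLAMP)
        mask = s.counts > 0
        total += float(np.sum(s.counts[mask] * logp[mask]))
    return total


class StationaryDensity:
    """Cached view of phi(q) for one parameter set: normalization,
    moments, expected spectra and an inverse-CDF grid for sampling."""

    def __init__(self, params: ModelParams, order: int = 128):
        self.params = params
        self.order = order
        a, b = params.exponents()
        self._a, self._b = a, b
        self._log_i = _log_norm_integral(a, b, params.gamma, order)

    @property
    def c(self) -> float:
        return float(np.exp(-self._log_i))

    def logpdf(self, q):
        return log_density(q, self.params, self.order)

    def pdf(self, q):
        return np.exp(self.logpdf(q))

    def mean(self) -> float:
        q, w = _jacobi_nodes(self.order, self._a, self._b)
        logs = np.log(w) + self.params.gamma * q
        return float(np.exp(logs - self._log_i) @ q)

    def expected_sfs(self, m: int, method: str = "jacobi") -> np.ndarray:
        return expected_sfs(self.params, m, order=self.order, method=method)

    def cdf_grid(self, order: int | None = None):
        """(q_nodes, cdf_at_nodes) on the quadrature grid, for
        inverse-CDF sampling."""
        order = order or self.order
        q, w = _jacobi_nodes(order, self._a, self._b)
        logs = np.log(w) + self.params.gamma * q
        mass = np.exp(logs - logs.max())
        cdf = np.cumsum(mass)
        cdf /= cdf[-1]
        return q, cdf
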