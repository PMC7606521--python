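"""Methylation-state calling from tile levels.

Tile methylation levels in a population of heterozygous (outbred)
individuals fall into three mixture components — unmethylated near 0,
heterozygous near 0.5, methylated near 1 — and into two components
(near 0 and 1) for inbred lines. A one-dimensional Gaussian mixture is
fitted by expectation maximization; discrete epigenotype calls use
fixed thresholds 0.3/0.7 (outbred) and 0.5 (inbred) by default, or
thresholds derived from the crossing points of the fitted weighted
component densities.

Call coding: 0 unmethylated, 1 heterozygous (outbred only),
2 (outbred) / 1 (inbred) methylated; NaN is missing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

VARIANCE_FLOOR = 1e-4  # prevents component collapse onto a single point


@dataclass
class MixtureFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.converged:
            assert abs(self.weights.sum() - 1.0) < 1e-9
            assert np.all(np.diff(self.means) >= 0)


@dataclass(frozen=True)
class CallingThresholds:
    t_low: float = 0.3
    t_high: float = 0.7
    inbred_cut: float = 0.5

    def __post_init__(self):
        if not (0 < self.t_low < self.t_high < 1):
            raise ValueError("need 0 < t_low < t_high < 1")
        if not (0 < self.inbred_cut < 1):
            raise ValueError("need 0 < inbred_cut < 1")


DEFAULT_THRESHOLDS = CallingThresholds()


@dataclass
class CallMatrix:
    """Discrete epigenotype calls, tiles x individuals."""

    tiles: list
    individuals: list
    calls: np.ndarray  # float array; NaN = missing
    ploidy_mode: str  # "outbred" | "inbred"

    def __post_init__(self):
        if self.ploidy_mode not in ("outbred", "inbred"):
            raise ValueError("ploidy_mode must be 'outbred' or 'inbred'")
        self.calls = np.atleast_2d(np.asarray(self.calls, dtype=float))
        allowed = {0.0, 1.0, 2.0} if self.ploidy_mode == "outbred" else {0.0, 1.0}
        vals = set(np.unique(self.calls[~np.isnan(self.calls)]))
        if not vals <= allowed:
            raise ValueError(f"invalid call values {vals - allowed} "
                             f"for {self.ploidy_mode} mode")

    @property
    def alleles_per_individual(self) -> int:
        return 2 if self.ploidy_mode == "outbred" else 1

    @property
    def n_tiles(self) -> int:
        return self.calls.shape[0]


def _em_once(x: np.ndarray, weights, means, sds, max_iter: int, tol: float):
    n, k = len(x), len(means)
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space
        logp = (np.log(weights)[None, :]
                + norm.logpdf(x[:, None], means[None, :], sds[None, :]))
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        loglik = float(lse.sum())
        trace.append(loglik)
        resp = np.exp(logp - lse[:, None])
        # M-step
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, VARIANCE_FLOOR))
        if loglik - prev < tol and it > 1:
            converged = True
            break
        prev = loglik
    order = np.argsort(means)
    return (weights[order], means[order], sds[order], trace[-1], converged,
            it, np.array(trace))


def fit_mixture(levels, k: int, seed: int = 0, max_iter: int = 1000,
                tol: float = 1e-6, n_restarts: int = 1) -> MixtureFit:
    """Fit a k-component normal mixture to tile levels by EM.

    Initialization places component means at the 5th/50th/95th (k=3) or
    5th/95th (k=2) percentiles with equal weights and sd = sample sd/2;
    ``n_restarts`` additional random initializations (seeded) guard
    against poor local optima, and the best log-likelihood wins. The
    log-likelihood is non-decreasing within each EM run; variances are
    floored at 1e-4. Degenerate data (no spread) yields a flagged
    non-converged fit at the sample moments.
    """
    x = np.asarray(levels, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10 * k:
        raise ValueError(f"need at least {10 * k} finite values for k={k}")
    if np.ptp(x) == 0:
        return MixtureFit(
            k, np.full(k, 1 / k), np.full(k, x[0]),
            np.full(k, np.sqrt(VARIANCE_FLOOR)), -np.inf, False, 0,
            np.array([]),
        )
    sd0 = max(np.std(x) / 2, np.sqrt(VARIANCE_FLOOR))
    pct = {1: [50], 2: [5, 95], 3: [5, 50, 95]}.get(k)
    if pct is None:
        pct = list(np.linspace(5, 95, k))
    inits = [np.percentile(x, pct)]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        inits.append(np.sort(rng.choice(x, size=k, replace=False)))
    best = None
    for means0 in inits:
        means0 = np.asarray(means0, float)
        if len(np.unique(means0)) < k:  # collapsed init: spread slightly
            means0 = means0 + np.linspace(-1e-3, 1e-3, k)
        w, m, s, ll, conv, it, trace = _em_once(
            x, np.full(k, 1 / k), means0.copy(), np.full(k, sd0), max_iter, tol)
        if best is None or ll > best[3]:
            best = (w, m, s, ll, conv, it, trace)
    w, m, s, ll, conv, it, trace = best
    return MixtureFit(k, w, m, s, ll, conv, it, trace)


def _crossing(w1, m1, s1, w2, m2, s2):
    """Crossing point of two weighted normal densities between their means."""
    def diff(q):
        return (np.log(w1) + norm.logpdf(q, m1, s1)
                - np.log(w2) - norm.logpdf(q, m2, s2))
    grid = np.linspace(m1, m2, 1001)[1:-1]
    vals = diff(grid)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        return None
    i = sign_change[0]
    return float(brentq(diff, grid[i], grid[i + 1]))


def derive_thresholds(fit: MixtureFit) -> CallingThresholds:
    """Thresholds at the density crossings of adjacent mixture components.

    Falls back to the fixed defaults (0.3, 0.7) / 0.5 — the values the
    calling rule uses in practice — when the fit did not converge or a
    crossing is absent or outside (0, 1).
    """
    if fit.k not in (2, 3):
        raise ValueError("threshold derivation needs a 2- or 3-component fit")
    if not fit.converged:
        warnings.warn("mixture fit not converged; using default thresholds")
        return DEFAULT_THRESHOLDS
    cuts = []
    for i in range(fit.k - 1):
        c = _crossing(fit.weights[i], fit.means[i], fit.sds[i],
                      fit.weights[i + 1], fit.means[i + 1], fit.sds[i + 1])
        cuts.append(c if c is not None and 0 < c < 1 else None)
    if fit.k == 3:
        t_low = cuts[0] if cuts[0] is not None else 0.3
        t_high = cuts[1] if cuts[1] is not None else 0.7
        if not t_low < t_high:
            warnings.warn("crossings out of order; using default thresholds")
            return DEFAULT_THRESHOLDS
        return CallingThresholds(t_low, t_high, 0.5)
    cut = cuts[0] if cuts[0] is not None else 0.5
    return CallingThresholds(0.3, 0.7, cut)


def call_states(tiles, thr: CallingThresholds = DEFAULT_THRESHOLDS,
                ploidy_mode: str = "outbred") -> CallMatrix:
    """Convert tile levels to discrete epigenotype calls.

    Outbred: level > t_high -> 2, level < t_low -> 0, otherwise 1
    (strict inequalities; a level exactly at a threshold falls into the
    heterozygous class). Inbred: level > inbred_cut -> 1 else 0.
    Missing levels propagate to missing calls.
    """
    levels = tiles.levels
    calls = np.full(levels.shape, np.nan)
    finite = np.isfinite(levels)
    if ploidy_mode == "outbred":
        calls[finite] = 1.0
        calls[finite & (levels > thr.t_high)] = 2.0
        calls[finite & (levels < thr.t_low)] = 0.0
    elif ploidy_mode == "inbred":
        calls[finite] = 0.0
        calls[finite & (levels > thr.inbred_cut)] = 1.0
    else:
        raise ValueError("ploidy_mode must be 'outbred' or 'inbred'")
    return CallMatrix(tiles.tiles, tiles.individuals, calls, ploidy_mode)


def cutoff_sensitivity(tiles, cutoff_grid, ploidy_mode: str = "outbred"):
    """Pairwise total-variation distances between mSFS built at different cutoffs.

    Quantifies how sensitive the methylome site frequency spectrum is to
    the calling thresholds; well-separated mixtures give near-zero
    distances across reasonable cutoff pairs.
    """
    from .sfs import build_msfs

    cutoff_grid = list(cutoff_grid)
    if len(cutoff_grid) < 2:
        raise ValueError("need at least two cutoff pairs")
    spectra = []
    for t_low, t_high in cutoff_grid:
        thr = CallingThresholds(t_low, t_high, (t_low + t_high) / 2)
        calls = call_states(tiles, thr, ploidy_mode)
        s = build_msfs(calls)
        p = s.counts / s.counts.sum() if s.counts.sum() else s.counts
        spectra.append(p)
    n = len(spectra)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 0.5 * np.abs(spectra[i] - spectra[j]).sum()
    return dist
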