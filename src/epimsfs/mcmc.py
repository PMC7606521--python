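"""Metropolis-Hastings inference of (mu, nu, s) from observed mSFS.

The sampler holds Ne fixed (only 4*Ne*mu, 4*Ne*nu and 4*Ne*s are
identifiable from a spectrum; running the fit across a grid of Ne
values shows the scaled parameters to be stable while the raw rates
trade off against Ne). Priors on the three rates are exponential;
proposals are a multiplicative log-normal random walk, whose asymmetry
is corrected by the Hastings ratio prod(theta'/theta).

Defaults follow the study design: 1,000,000 iterations, first 20%
discarded as burn-in, thinning by 500 — retaining exactly 1600
posterior samples per chain.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .model import ModelParams, msfs_loglik


@dataclass(frozen=True)
class PriorSpec:
    """Exponential priors on mu, nu and s; prior mean = 1/rate.

    Rates default to 1e5 for the epimutation rates (prior mean 1e-5,
    the order of magnitude of plant epimutation rates) and 1e2 for the
    selection coefficient. ``s_support="signed"`` swaps the exponential
    on s for a symmetric two-sided (Laplace) prior and enables a
    sign-flip proposal move.
    """

    rate_mu: float = 1e5
    rate_nu: float = 1e5
    rate_s: float = 1e2
    s_support: str = "nonnegative"

    def __post_init__(self):
        if min(self.rate_mu, self.rate_nu, self.rate_s) <= 0:
            raise ValueError("prior rates must be positive")
        if self.s_support not in ("nonnegative", "signed"):
            raise ValueError("s_support must be 'nonnegative' or 'signed'")

    def log_prior(self, mu: float, nu: float, s: float) -> float:
        if mu <= 0 or nu <= 0:
            return -np.inf
        lp = (np.log(self.rate_mu) - self.rate_mu * mu
              + np.log(self.rate_nu) - self.rate_nu * nu)
        if self.s_support == "nonnegative":
            if s < 0:
                return -np.inf
            lp += np.log(self.rate_s) - self.rate_s * s
        else:
            lp += np.log(self.rate_s / 2.0) - self.rate_s * abs(s)
        return float(lp)

    def mean_init(self) -> np.ndarray:
        return np.array([1.0 / self.rate_mu, 1.0 / self.rate_nu,
                         1.0 / self.rate_s])


@dataclass(frozen=True)
class McmcConfig:
    n_iter: int = 1_000_000
    burnin_frac: float = 0.2
    thin: int = 500
    lam: float = 0.05  # scale of the multiplicative proposal
    seed: int = 0
    ne: float = 50_000
    swap_exponents: bool = False

    def __post_init__(self):
        if not (0 <= self.burnin_frac < 1):
            raise ValueError("burnin_frac must lie in [0, 1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")

    @property
    def n_burnin(self) -> int:
        return int(self.n_iter * self.burnin_frac)

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin


@dataclass
class PosteriorSummary:
    """Retained samples plus per-parameter summaries.

    ``scaled`` reports 4*Ne*mu, 4*Ne*nu and Ne*s computed per sample
    and then summarized, so credible intervals are quantiles of the
    scaled draws, not rescaled quantiles.
    """

    samples: dict  # parameter name -> retained sample array
    means: dict
    sds: dict
    ci95: dict  # parameter name -> (2.5%, 97.5%)
    acceptance_rate: float
    config: McmcConfig
    prior: PriorSpec

    @property
    def n_retained(self) -> int:
        return len(next(iter(self.samples.values())))

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "samples": {k: v.tolist() for k, v in self.samples.items()},
            "means": self.means, "sds": self.sds,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "acceptance_rate": self.acceptance_rate,
            "config": asdict(self.config), "prior": asdict(self.prior),
        })
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def propose(current: np.ndarray, lam: float, rng: np.random.Generator,
            sign_flip: bool = False):
    """Multiplicative log-normal step on each of (mu, nu, s).

    Returns the proposal and the log Hastings correction
    sum log(theta'/theta) of the asymmetric walk. With ``sign_flip``
    the sign of s is flipped with probability 1/2 afterwards (a
    symmetric move; no extra correction).
    """
    z = rng.standard_normal(3)
    proposal = current * np.exp(lam * z)
    log_correction = float(lam * z.sum())
    if sign_flip and rng.random() < 0.5:
        proposal = proposal.copy()
        proposal[2] = -proposal[2]
    return proposal, log_correction


def run_mcmc(msfs, prior: PriorSpec = PriorSpec(),
             config: McmcConfig = McmcConfig(),
             likelihood: bool = True, scheme: str = "componentwise",
             _skip_hastings_correction: bool = False) -> PosteriorSummary:
    """Metropolis-Hastings chain over (mu, nu, s) at fixed Ne.

    One iteration is a sweep updating mu, nu and s in turn, each with
    its own multiplicative log-normal step and accept/reject decision
    (``scheme="joint"`` instead proposes all three at once via
    ``propose``). Component-wise sweeps keep the acceptance rate
    usable when the posterior scales of the three rates differ by
    orders of magnitude, as they do for sharply informative spectra.

    The chain starts at the prior means (re-drawn from the priors if
    the target is non-finite there), runs ``config.n_iter`` iterations
    and retains every ``config.thin``-th state after the burn-in.
    ``likelihood=False`` samples the prior alone — a validation mode:
    the retained marginals must then match the exponential priors.
    ``_skip_hastings_correction`` deliberately omits the proposal
    asymmetry correction; it exists only so tests can demonstrate the
    resulting bias.
    """
    if scheme not in ("componentwise", "joint"):
        raise ValueError("scheme must be 'componentwise' or 'joint'")
    spectra = msfs if isinstance(msfs, (list, tuple)) else [msfs]
    if likelihood and not spectra:
        raise ValueError("no spectra supplied")
    rng = np.random.default_rng(config.seed)
    sign_flip = prior.s_support == "signed"

    def log_target(theta: np.ndarray) -> float:
        lp = prior.log_prior(*theta)
        if not np.isfinite(lp):
            return -np.inf
        if likelihood:
            params = ModelParams(theta[0], theta[1], theta[2], config.ne,
                                 swap_exponents=config.swap_exponents)
            lp += msfs_loglik(spectra, params)
        return lp

    # Start at the prior means, clamped so the initial scaled parameters
    # (4Ne*mu, 4Ne*nu, 4Ne*s) stay within the range the spectrum can
    # inform (the likelihood is numerically flat for |gamma| in the tens
    # of thousands, where a chain would only diffuse).
    scale_cap = 50.0 / (4.0 * config.ne)

    def clamp(theta: np.ndarray) -> np.ndarray:
        out = np.minimum(np.abs(theta), scale_cap) * np.sign(theta)
        out[:2] = np.abs(out[:2])
        return out

    theta = clamp(prior.mean_init())
    lt = log_target(theta)
    attempts = 0
    while not np.isfinite(lt):
        attempts += 1
        if attempts > 100:
            raise RuntimeError("could not find a finite-target start point")
        theta = np.array([rng.exponential(1.0 / prior.rate_mu),
                          rng.exponential(1.0 / prior.rate_nu),
                          rng.exponential(1.0 / prior.rate_s)])
        if sign_flip and rng.random() < 0.5:
            theta[2] = -theta[2]
        theta = clamp(theta)
        lt = log_target(theta)

    n_burn = config.n_burnin
    retained = np.empty((config.n_retained, 3))
    n_accept = 0
    n_moves = 0
    r = 0
    for i in range(config.n_iter):
        if scheme == "joint":
            proposal, log_corr = propose(theta, config.lam, rng,
                                         sign_flip=sign_flip)
            lt_prop = log_target(proposal)
            log_alpha = lt_prop - lt
            if not _skip_hastings_correction:
                log_alpha += log_corr
            n_moves += 1
            if log_alpha >= 0 or np.log(rng.random()) < log_alpha:
                theta, lt = proposal, lt_prop
                n_accept += 1
        else:
            for j in range(3):
                z = rng.standard_normal()
                proposal = theta.copy()
                proposal[j] = theta[j] * np.exp(config.lam * z)
                if j == 2 and sign_flip and rng.random() < 0.5:
                    proposal[j] = -proposal[j]
                lt_prop = log_target(proposal)
                log_alpha = lt_prop - lt
                if not _skip_hastings_correction:
                    log_alpha += config.lam * z
                n_moves += 1
                if log_alpha >= 0 or np.log(rng.random()) < log_alpha:
                    theta, lt = proposal, lt_prop
                    n_accept += 1
        if i >= n_burn and (i - n_burn + 1) % config.thin == 0:
            retained[r] = theta
            r += 1
    retained = retained[:r]
    return posterior_summary(retained, config.ne, config=config, prior=prior,
                             acceptance_rate=n_accept / max(n_moves, 1))


def posterior_summary(samples: np.ndarray, ne: float,
                      config: McmcConfig | None = None,
                      prior: PriorSpec | None = None,
                      acceptance_rate: float = np.nan) -> PosteriorSummary:
    """Means, SDs and 95% credible intervals for raw and Ne-scaled
    parameters from a (n, 3) array of (mu, nu, s) draws."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 2:
        raise ValueError("need at least two retained samples")
    cols = {
        "mu": samples[:, 0], "nu": samples[:, 1], "s": samples[:, 2],
        "4Ne_mu": 4 * ne * samples[:, 0],
        "4Ne_nu": 4 * ne * samples[:, 1],
        "Ne_s": ne * samples[:, 2],
    }
    means = {k: float(v.mean()) for k, v in cols.items()}
    sds = {k: float(v.std(ddof=1)) for k, v in cols.items()}
    ci95 = {k: (float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975)))
            for k, v in cols.items()}
    return PosteriorSummary(cols, means, sds, ci95, acceptance_rate,
                            config or McmcConfig(ne=ne),
                            prior or PriorSpec())


def ne_grid_fit(msfs, prior: PriorSpec = PriorSpec(),
                config: McmcConfig = McmcConfig(),
                ne_grid=(50_000, 100_000, 500_000, 1_000_000)) -> dict:
    """Independent chains across a grid of assumed Ne values.

    Each grid point runs ``run_mcmc`` with seed derived as
    config.seed + index, so fits are reproducible yet independent.
    The scaled summaries (4Ne*mu, 4Ne*nu, Ne*s) are the cross-Ne
    comparable quantities.
    """
    ne_grid = list(ne_grid)
    if not ne_grid:
        raise ValueError("Ne grid is empty")
    out = {}
    from dataclasses import replace
    for i, ne in enumerate(ne_grid):
        cfg = replace(config, ne=ne, seed=config.seed + i)
        out[ne] = run_mcmc(msfs, prior, cfg)
    return out
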