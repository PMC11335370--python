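"""Single-individual hierarchical Bayesian turnover model.

The model places log-normal priors on lam and kc (normal priors on their
logarithms), a normal prior on the vertical shift s, a vague gamma prior on
the observation precision, and a weighted normal likelihood on the RIAs:

    ln(lam) ~ N(mu_llam, var_llam)
    ln(kc)  ~ N(mu_lkc,  var_lkc)
    s       ~ N(mu_s,    var_s)
    sigma^-2 ~ Gamma(0.001, 0.001)
    RIA_i   ~ N(beta(t_i) - s, sigma^2 / w_i)

Inference is by Metropolis-within-Gibbs: a jointly adapted random-walk
Metropolis block updates (ln lam, ln kc, s), and the precision sigma^-2 is
drawn exactly from its conjugate gamma full conditional.  Proposal
adaptation runs only during burn-in and is frozen afterwards so retained
draws satisfy detailed balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinetics import TracerProtocol, beta_values

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "log_posterior",
    "sample_individual",
    "credible_interval",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """All prior constants of the individual model.

    Means/variances of ln(lam) and ln(kc) are typically learned from a
    large reference collection of QNB fits; the shift prior is centered at
    zero with matrix-specific variance (1e-3 plasma, 1/500 CSF); the gamma
    prior on the precision is the standard vague Gamma(0.001, 0.001).
    """

    mu_llam: float = -3.0
    var_llam: float = 1.0
    mu_lkc: float = -2.3
    var_lkc: float = 1.0
    mu_s: float = 0.0
    var_s: float = 1e-3
    gamma_shape: float = 0.001
    gamma_rate: float = 0.001

    def __post_init__(self) -> None:
        for name in ("var_llam", "var_lkc", "var_s", "gamma_shape", "gamma_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length and initialization settings.

    Defaults mirror a conservative production run: two chains of 100 000
    iterations, first 50 000 discarded as burn-in.
    """

    n_iter: int = 100_000
    n_burn: int = 50_000
    n_chains: int = 2
    seed: int | None = None
    init_strategy: str = "prior-draw"  # or "qnb-start"
    adapt_interval: int = 100
    target_accept: float = 0.3

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be < n_iter")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.init_strategy not in ("prior-draw", "qnb-start"):
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")


@dataclass
class PosteriorSamples:
    """Post-burn-in draws per chain, with acceptance rates and summaries.

    ``chains`` has shape (n_chains, n_kept, 4) with columns
    (ln lam, ln kc, s, sigma).
    """

    chains: np.ndarray
    param_names: tuple = ("log_lam", "log_kc", "shift", "sigma")
    accept_rates: list = field(default_factory=list)

    @property
    def flat(self) -> np.ndarray:
        return self.chains.reshape(-1, self.chains.shape[-1])

    def summary(self) -> dict:
        out = {}
        for j, name in enumerate(self.param_names):
            x = self.flat[:, j]
            out[name] = {
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)),
                "q2.5": float(np.percentile(x, 2.5)),
                "q97.5": float(np.percentile(x, 97.5)),
            }
        return out


def log_posterior(state, times, ria, weights, prior: PriorSpec,
                  protocol: TracerProtocol = TracerProtocol()) -> float:
    """Unnormalized log posterior density at (ln lam, ln kc, s, sigma).

    Outliers must already be excluded (QNB calling is the upstream step).
    Invalid or non-finite states return -inf rather than raising.
    """
    llam, lkc, s, sigma = state
    if not all(map(math.isfinite, (llam, lkc, s, sigma))) or sigma <= 0:
        return -math.inf
    lp = (
        -0.5 * (llam - prior.mu_llam) ** 2 / prior.var_llam
        - 0.5 * (lkc - prior.mu_lkc) ** 2 / prior.var_lkc
        - 0.5 * (s - prior.mu_s) ** 2 / prior.var_s
    )
    # gamma prior on the precision tau = sigma^-2
    tau = sigma ** -2
    lp += (prior.gamma_shape - 1.0) * math.log(tau) - prior.gamma_rate * tau
    times = np.asarray(times, dtype=float)
    if times.size:
        beta = beta_values(llam, lkc, times, protocol)
        resid = np.asarray(ria, dtype=float) - (beta - s)
        w = np.asarray(weights, dtype=float)
        n = times.size
        lp += -n * math.log(sigma) + 0.5 * float(np.sum(np.log(w)))
        lp += -0.5 * float(np.sum(w * resid ** 2)) / sigma ** 2 - 0.5 * n * _LOG2PI
    return lp if math.isfinite(lp) else -math.inf


def _log_like_core(llam, lkc, s, times, ria, w, protocol):
    """Weighted residual sum of squares (the sigma-free likelihood core)."""
    beta = beta_values(llam, lkc, times, protocol)
    resid = ria - (beta - s)
    return float(np.dot(w, resid * resid))


def _log_prior_theta(llam, lkc, s, prior):
    return (
        -0.5 * (llam - prior.mu_llam) ** 2 / prior.var_llam
        - 0.5 * (lkc - prior.mu_lkc) ** 2 / prior.var_lkc
        - 0.5 * (s - prior.mu_s) ** 2 / prior.var_s
    )


def _run_chain(times, ria, w, prior, config, protocol, rng, init_theta):
    n_obs = times.size
    llam, lkc, s = init_theta
    sigma2 = 0.1  # observation variance initialized at 0.1
    step = np.array([0.2, 0.2, 0.02])
    n_accept = 0
    n_prop = 0
    window_accept = 0
    kept = np.empty((config.n_iter - config.n_burn, 4))
    wss = _log_like_core(llam, lkc, s, times, ria, w, protocol)
    lp_theta = _log_prior_theta(llam, lkc, s, prior)

    normals = None
    for it in range(config.n_iter):
        if it % 4096 == 0:
            normals = rng.standard_normal((min(4096, config.n_iter - it), 3))
            unifs = rng.random(normals.shape[0])
        z = normals[it % 4096]
        u = unifs[it % 4096]
        prop = np.array([llam, lkc, s]) + step * z
        if np.all(np.abs(prop[:2]) < 30):
            wss_p = _log_like_core(prop[0], prop[1], prop[2], times, ria, w, protocol)
            lp_p = _log_prior_theta(prop[0], prop[1], prop[2], prior)
            log_ratio = (lp_p - lp_theta) - 0.5 * (wss_p - wss) / sigma2
            if math.log(u + 1e-300) < log_ratio:
                llam, lkc, s = prop
                wss, lp_theta = wss_p, lp_p
                n_accept += 1
                window_accept += 1
        n_prop += 1
        # conjugate gamma draw for the precision
        shape = prior.gamma_shape + 0.5 * n_obs
        rate = prior.gamma_rate + 0.5 * wss
        # vague shapes (0.001) can underflow the gamma draw to exactly 0
        tau = max(rng.gamma(shape, 1.0 / rate), 1e-300)
        sigma2 = 1.0 / tau
        # scale adaptation, burn-in only
        if it < config.n_burn and (it + 1) % config.adapt_interval == 0:
            acc = window_accept / config.adapt_interval
            step *= math.exp(0.6 * (acc - config.target_accept))
            window_accept = 0
        if it >= config.n_burn:
            kept[it - config.n_burn] = (llam, lkc, s, math.sqrt(sigma2))
    return kept, n_accept / n_prop


def sample_individual(times, ria, weights, prior: PriorSpec,
                      config: MCMCConfig = MCMCConfig(),
                      protocol: TracerProtocol = TracerProtocol(),
                      qnb_init=None) -> PosteriorSamples:
    """Run the Metropolis-within-Gibbs sampler on one observation series.

    Each chain initializes (ln lam, ln kc) from the prior (``prior-draw``)
    or at a supplied QNB estimate (``qnb-start``); the shift starts at 0
    and the observation variance at 0.1.  Weights are normalized to mean 1.
    """
    times = np.asarray(times, dtype=float)
    ria = np.asarray(ria, dtype=float)
    w = np.asarray(weights, dtype=float)
    if 0 < times.size < 3:
        raise ValueError("need >= 3 usable observations (or none, to sample the prior)")
    if times.size:
        w = w / w.mean()
    rng = np.random.default_rng(config.seed)
    chains = []
    rates = []
    for _ in range(config.n_chains):
        if config.init_strategy == "qnb-start" and qnb_init is not None:
            theta0 = (qnb_init.log_lam, qnb_init.log_kc, 0.0)
        else:
            theta0 = (
                prior.mu_llam + math.sqrt(prior.var_llam) * rng.standard_normal(),
                prior.mu_lkc + math.sqrt(prior.var_lkc) * rng.standard_normal(),
                0.0,
            )
        kept, rate = _run_chain(times, ria, w, prior, config, protocol, rng, theta0)
        chains.append(kept)
        rates.append(rate)
    return PosteriorSamples(chains=np.stack(chains), accept_rates=rates)


def credible_interval(samples: PosteriorSamples, level: float = 0.95) -> dict:
    """Equal-tailed credible intervals on the natural scale.

    ln(lam) and ln(kc) are exponentiated; the interval on lam equals the
    exponential of the interval on ln(lam) by percentile equivariance.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0,1)")
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    flat = samples.flat
    out = {}
    for j, name in enumerate(samples.param_names):
        lo, hi = np.percentile(flat[:, j], [lo_q, hi_q])
        if name in ("log_lam", "log_kc"):
            out[name.replace("log_", "")] = (math.exp(lo), math.exp(hi))
        else:
            out[name] = (float(lo), float(hi))
        out[name] = (float(lo), float(hi))
    return out
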