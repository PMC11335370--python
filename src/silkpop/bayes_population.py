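"""Hierarchical population model of protein turnover across a cohort.

Each patient k has kinetic parameters theta_k = (ln lam_k, ln kc_k) drawn
from a bivariate normal population distribution N2(mu_theta, Omega), a
patient-specific vertical shift s_k, and all patients share one residual
variance sigma^2:

    theta_k    ~ N2(mu_theta, Omega)
    mu_theta   ~ N2(mu, Sigma)            (normal hyper-prior)
    Omega^-1   ~ Wishart_2(R, df=2)       (BUGS convention, see below)
    s_k        ~ N(mu_s, var_s)
    sigma^-2   ~ Gamma(0.001, 0.001)
    RIA_ki     ~ N(beta_k(t_i) - s_k, sigma^2 / w_ki)

Wishart convention: Wi_2(R, nu) is the distribution over the PRECISION
matrix Omega^-1 with density proportional to
|Omega^-1|^{(nu-p-1)/2} exp(-tr(R Omega^-1)/2) and prior expectation
E[Omega^-1] = nu * R^-1 (the BUGS parameterization).  In scipy terms this
is ``wishart(df=nu, scale=inv(R))``.  Conventions differ across
ecosystems; every draw here goes through :func:`_wishart_bugs`.

Sampling is Metropolis-within-Gibbs: mu_theta, Omega^-1, each s_k and
sigma^-2 have exact conjugate full-conditional draws; each theta_k (which
enters the likelihood through the nonlinear ODE solution) is updated by an
independently adapted random-walk Metropolis step, with adaptation frozen
after burn-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bayes_individual import MCMCConfig
from .kinetics import KineticParams, TracerProtocol, beta_values

__all__ = [
    "PopulationHyperPrior",
    "PatientData",
    "PopulationPosterior",
    "DivergenceError",
    "build_informative_prior",
    "sample_population",
    "detect_divergence",
    "log_posterior_population",
]


@dataclass(frozen=True)
class PopulationHyperPrior:
    """Hyper-prior constants of the population model.

    Vague defaults: hyper-mean precision Sigma^-1 = diag(1e-4) (an almost
    flat normal on mu_theta) and Wishart scale R = diag(0.175) with 2
    degrees of freedom.  The informative mode centers the hyper-mean on
    per-patient QNB estimates instead (see :func:`build_informative_prior`).
    """

    mu: np.ndarray = field(default_factory=lambda: np.array([-3.0, -2.3]))
    sigma_inv: np.ndarray = field(default_factory=lambda: np.diag([1e-4, 1e-4]))
    wishart_R: np.ndarray = field(default_factory=lambda: np.diag([0.175, 0.175]))
    wishart_df: float = 2.0
    mode: str = "vague"
    mu_s: float = 0.0
    var_s: float = 1e-3
    gamma_shape: float = 0.001
    gamma_rate: float = 0.001

    def __post_init__(self) -> None:
        for name in ("sigma_inv", "wishart_R"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (2, 2) or not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric 2x2")
            if np.any(np.linalg.eigvalsh(m) <= 0):
                raise ValueError(f"{name} must be positive definite")
        if self.wishart_df < 2:
            raise ValueError("wishart_df must be >= 2")
        if self.mode not in ("vague", "informative"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class PatientData:
    """One patient's usable (outlier-free) observation series."""

    patient_id: str
    times: np.ndarray
    ria: np.ndarray
    weights: np.ndarray
    qnb_estimate: KineticParams | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ria = np.asarray(self.ria, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if self.times.size < 3:
            raise ValueError(f"patient {self.patient_id}: need >= 3 usable observations")
        if np.any(w <= 0):
            raise ValueError("weights must be > 0")
        self.weights = w / w.mean()


@dataclass
class PopulationPosterior:
    """Post-burn-in draws of all population quantities, per chain.

    Shapes (m = chains, n = kept draws, K = patients):
    mu_theta (m,n,2); omega (m,n,2,2); theta (m,n,K,2); shifts (m,n,K);
    sigma (m,n).
    """

    patient_ids: list
    mu_theta: np.ndarray
    omega: np.ndarray
    theta: np.ndarray
    shifts: np.ndarray
    sigma: np.ndarray
    accept_rates: np.ndarray
    mode: str = "vague"

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])


class DivergenceError(RuntimeError):
    """Raised when chains diverge; carries remediation advice."""


def build_informative_prior(qnb_estimates: dict,
                            base: PopulationHyperPrior | None = None) -> PopulationHyperPrior:
    """Informative hyper-prior learned from per-patient QNB estimates.

    The hyper-mean ``mu`` is set to the average of (ln lam_k, ln kc_k)
    across patients and the diagonal of Sigma^-1 to the reciprocal sample
    variances; the Wishart settings stay at their vague defaults.
    """
    if len(qnb_estimates) < 2:
        raise ValueError("need >= 2 patients with QNB estimates")
    base = base or PopulationHyperPrior()
    pts = np.array([[p.log_lam, p.log_kc] for p in qnb_estimates.values()])
    var = pts.var(axis=0, ddof=1)
    if np.any(var <= 0):
        raise ValueError("degenerate QNB estimates: zero variance across patients")
    return PopulationHyperPrior(
        mu=pts.mean(axis=0),
        sigma_inv=np.diag(1.0 / var),
        wishart_R=base.wishart_R,
        wishart_df=base.wishart_df,
        mode="informative",
        mu_s=base.mu_s, var_s=base.var_s,
        gamma_shape=base.gamma_shape, gamma_rate=base.gamma_rate,
    )


def _wishart_bugs(R: np.ndarray, df: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a precision matrix from the BUGS-style Wishart Wi(R, df).

    E[draw] = df * R^-1 (equivalently scipy's ``wishart(df, scale=R^-1)``,
    cross-checked in the test suite).  Uses the Bartlett decomposition:
    with V = R^-1 = L L^T and A lower-triangular with chi(df-i) diagonal
    and N(0,1) sub-diagonal entries, (L A)(L A)^T ~ Wishart(df, V).
    """
    p = R.shape[0]
    V = _inv2(R) if p == 2 else np.linalg.inv(R)
    L = _chol2(V) if p == 2 else np.linalg.cholesky(V)
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = math.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    LA = L @ A
    return LA @ LA.T


def log_posterior_population(state: dict, cohort: list, hyper: PopulationHyperPrior,
                             protocol: TracerProtocol = TracerProtocol()) -> float:
    """Full joint log density (up to a constant) of the population model.

    ``state``: dict with mu_theta (2,), omega (2,2), theta (K,2),
    shifts (K,), sigma (scalar).  Invalid states (sigma <= 0, Omega not
    SPD) return -inf.  Used by Metropolis steps' validation oracle.
    """
    mu_theta = np.asarray(state["mu_theta"], dtype=float)
    omega = np.asarray(state["omega"], dtype=float)
    theta = np.asarray(state["theta"], dtype=float)
    shifts = np.asarray(state["shifts"], dtype=float)
    sigma = float(state["sigma"])
    if sigma <= 0 or not np.all(np.isfinite(mu_theta)):
        return -math.inf
    try:
        omega_chol = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        return -math.inf
    omega_inv = np.linalg.inv(omega)
    logdet_omega = 2.0 * float(np.sum(np.log(np.diag(omega_chol))))
    K = len(cohort)
    lp = 0.0
    # hyper-priors
    d = mu_theta - hyper.mu
    lp += -0.5 * float(d @ hyper.sigma_inv @ d)
    # Wishart prior on Omega^-1, BUGS parameterization, p=2, df=nu:
    # (nu-p-1)/2 * log|Omega^-1| - tr(R Omega^-1)/2
    nu, p = hyper.wishart_df, 2
    lp += 0.5 * (nu - p - 1) * (-logdet_omega) - 0.5 * float(np.trace(hyper.wishart_R @ omega_inv))
    # gamma prior on precision
    tau = sigma ** -2
    lp += (hyper.gamma_shape - 1.0) * math.log(tau) - hyper.gamma_rate * tau
    for k, pat in enumerate(cohort):
        dk = theta[k] - mu_theta
        lp += -0.5 * logdet_omega - 0.5 * float(dk @ omega_inv @ dk)
        lp += -0.5 * (shifts[k] - hyper.mu_s) ** 2 / hyper.var_s
        beta = beta_values(theta[k, 0], theta[k, 1], pat.times, protocol)
        resid = pat.ria - (beta - shifts[k])
        n = pat.times.size
        lp += -n * math.log(sigma) - 0.5 * float(np.dot(pat.weights, resid ** 2)) / sigma ** 2
    return lp if math.isfinite(lp) else -math.inf


def detect_divergence(chains_theta: np.ndarray,
                      window: int | None = None,
                      slope_bound: float = 2.0,
                      sanity_bound: float = 15.0) -> dict:
    """Flag opposite-direction drift of ln(lam) and ln(kc) within chains.

    The hallmark failure mode is one component trending toward +inf while
    the other compensates toward -inf.  ``chains_theta``: array
    (m, n, 2) per patient (or (m, n, K, 2), checked per patient).  A chain
    is flagged when the fitted linear trends of the two components over
    the trailing ``window`` draws have opposite signs and each moves by
    more than ``slope_bound`` over the window, or when any |component|
    exceeds ``sanity_bound``.
    """
    arr = np.asarray(chains_theta, dtype=float)
    if arr.ndim == 3:
        arr = arr[:, :, None, :]
    m, n, K, _ = arr.shape
    window = window or n
    window = min(window, n)
    seg = arr[:, -window:, :, :]
    t = np.arange(window, dtype=float)
    t = t - t.mean()
    denom = float(np.sum(t ** 2))
    flagged = []
    for c in range(m):
        for k in range(K):
            comp = seg[c, :, k, :]
            if np.any(np.abs(comp) > sanity_bound):
                flagged.append({"chain": c, "patient": k, "reason": "sanity-bound"})
                continue
            slopes = (t @ comp) / denom
            moves = slopes * window
            if slopes[0] * slopes[1] < 0 and np.all(np.abs(moves) > slope_bound):
                flagged.append({"chain": c, "patient": k, "reason": "opposite-drift",
                                "moves": moves.tolist()})
    return {"diverged": bool(flagged), "details": flagged}


def _inv2(m: np.ndarray) -> np.ndarray:
    """Closed-form inverse of a 2x2 matrix (sampler hot path)."""
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    return np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det


def _chol2(m: np.ndarray) -> np.ndarray:
    """Closed-form lower Cholesky factor of a 2x2 SPD matrix."""
    l11 = math.sqrt(m[0, 0])
    l21 = m[1, 0] / l11
    l22 = math.sqrt(max(m[1, 1] - l21 * l21, 0.0))
    return np.array([[l11, 0.0], [l21, l22]])


def _run_pop_chain(cohort, hyper, config, protocol, rng, theta0):
    K = len(cohort)
    theta = np.array(theta0, dtype=float)          # (K,2)
    shifts = np.zeros(K)
    sigma2 = 0.01                                  # paper-style chain start
    mu_theta = theta.mean(axis=0)
    omega = np.eye(2) * 0.5
    steps = np.full((K, 2), 0.15)
    win_acc = np.zeros(K)
    n_acc = np.zeros(K)
    n_prop = 0

    times = [p.times for p in cohort]
    ria = [p.ria for p in cohort]
    w = [p.weights for p in cohort]
    n_k = np.array([p.times.size for p in cohort])
    sum_w = np.array([wi.sum() for wi in w])
    n_tot = int(n_k.sum())

    def wss_patient(k, th, s):
        beta = beta_values(th[0], th[1], times[k], protocol)
        resid = ria[k] - (beta - s)
        return float(np.dot(w[k], resid * resid)), beta

    wss = np.empty(K)
    betas = []
    for k in range(K):
        wss[k], b = wss_patient(k, theta[k], shifts[k])
        betas.append(b)

    n_keep = config.n_iter - config.n_burn
    kept_mu = np.empty((n_keep, 2))
    kept_omega = np.empty((n_keep, 2, 2))
    kept_theta = np.empty((n_keep, K, 2))
    kept_s = np.empty((n_keep, K))
    kept_sigma = np.empty(n_keep)

    prior_prec = hyper.sigma_inv
    prior_prec_mu = prior_prec @ hyper.mu

    for it in range(config.n_iter):
        omega_inv = _inv2(omega)
        # --- conjugate: mu_theta | theta, Omega ---
        prec = prior_prec + K * omega_inv
        cov = _inv2(prec)
        mean = cov @ (prior_prec_mu + omega_inv @ theta.sum(axis=0))
        mu_theta = mean + _chol2(cov) @ rng.standard_normal(2)
        # --- conjugate: Omega^-1 | theta, mu_theta (BUGS Wishart) ---
        dev = theta - mu_theta
        S = dev.T @ dev
        omega_inv = _wishart_bugs(hyper.wishart_R + S, hyper.wishart_df + K, rng)
        omega = _inv2(omega_inv)
        # --- Metropolis per patient: theta_k ---
        for k in range(K):
            prop = theta[k] + steps[k] * rng.standard_normal(2)
            if np.any(np.abs(prop) > 30):
                continue
            wss_p, beta_p = wss_patient(k, prop, shifts[k])
            d0 = theta[k] - mu_theta
            d1 = prop - mu_theta
            log_ratio = (
                -0.5 * (d1 @ omega_inv @ d1 - d0 @ omega_inv @ d0)
                - 0.5 * (wss_p - wss[k]) / sigma2
            )
            if math.log(rng.random() + 1e-300) < log_ratio:
                theta[k] = prop
                wss[k] = wss_p
                betas[k] = beta_p
                n_acc[k] += 1
                win_acc[k] += 1
        n_prop += 1
        # --- conjugate: s_k | rest ---
        for k in range(K):
            # d_ki = beta_ki - ria_ki ~ N(s_k, sigma^2 / w_ki)
            d = betas[k] - ria[k]
            prec_s = 1.0 / hyper.var_s + sum_w[k] / sigma2
            mean_s = (hyper.mu_s / hyper.var_s + float(np.dot(w[k], d)) / sigma2) / prec_s
            shifts[k] = mean_s + rng.standard_normal() / math.sqrt(prec_s)
            resid = ria[k] - (betas[k] - shifts[k])
            wss[k] = float(np.dot(w[k], resid * resid))
        # --- conjugate: sigma^-2 | rest ---
        shape = hyper.gamma_shape + 0.5 * n_tot
        rate = hyper.gamma_rate + 0.5 * float(wss.sum())
        sigma2 = 1.0 / max(rng.gamma(shape, 1.0 / rate), 1e-300)
        # --- adaptation during burn-in ---
        if it < config.n_burn and (it + 1) % config.adapt_interval == 0:
            acc = win_acc / config.adapt_interval
            steps *= np.exp(0.6 * (acc - config.target_accept))[:, None]
            win_acc[:] = 0.0
        if it >= config.n_burn:
            j = it - config.n_burn
            kept_mu[j] = mu_theta
            kept_omega[j] = omega
            kept_theta[j] = theta
            kept_s[j] = shifts
            kept_sigma[j] = math.sqrt(sigma2)
    return kept_mu, kept_omega, kept_theta, kept_s, kept_sigma, n_acc / n_prop


def sample_population(cohort: list, hyper: PopulationHyperPrior,
                      config: MCMCConfig = MCMCConfig(),
                      init: str = "prior-draw",
                      protocol: TracerProtocol = TracerProtocol(),
                      divergence_check: bool = True) -> PopulationPosterior:
    """Fit the population model to a cohort by Metropolis-within-Gibbs.

    ``init='prior-draw'`` starts each theta_k at a draw from N2(mu, prior
    covariance) (chains start at s_k = 0, sigma^2 = 0.01); ``init='qnb-
    start'`` starts theta_k at the per-patient QNB estimates, the remedy
    for cohorts whose chains otherwise diverge.  Divergent runs raise
    :class:`DivergenceError` with advice to switch init or prior mode.
    """
    if len(cohort) < 2:
        raise ValueError("need >= 2 patients")
    if init not in ("prior-draw", "qnb-start"):
        raise ValueError(f"unknown init {init!r}")
    rng = np.random.default_rng(config.seed)
    # a proper covariance for initial theta draws: vague hyper-priors have
    # near-zero precision, so cap the init spread at the reference scale
    prior_cov = np.linalg.inv(hyper.sigma_inv)
    cap = np.diag([1.0, 1.0])
    init_cov = cap if prior_cov[0, 0] > 1.0 else prior_cov
    out_mu, out_omega, out_theta, out_s, out_sigma, rates = [], [], [], [], [], []
    for _ in range(config.n_chains):
        if init == "qnb-start":
            missing = [p.patient_id for p in cohort if p.qnb_estimate is None]
            if missing:
                raise ValueError(f"qnb-start init requires QNB estimates; missing for {missing}")
            theta0 = np.array([[p.qnb_estimate.log_lam, p.qnb_estimate.log_kc]
                               for p in cohort])
        else:
            theta0 = rng.multivariate_normal(hyper.mu, init_cov, size=len(cohort),
                                             method="cholesky")
        res = _run_pop_chain(cohort, hyper, config, protocol, rng, theta0)
        out_mu.append(res[0]); out_omega.append(res[1]); out_theta.append(res[2])
        out_s.append(res[3]); out_sigma.append(res[4]); rates.append(res[5])
    post = PopulationPosterior(
        patient_ids=[p.patient_id for p in cohort],
        mu_theta=np.stack(out_mu), omega=np.stack(out_omega),
        theta=np.stack(out_theta), shifts=np.stack(out_s),
        sigma=np.stack(out_sigma), accept_rates=np.stack(rates),
        mode=hyper.mode,
    )
    if divergence_check:
        verdict = detect_divergence(post.theta)
        if verdict["diverged"]:
            raise DivergenceError(
                "population chains diverged (ln lam / ln kc drifting in opposite "
                "directions or beyond sanity bounds); retry with init='qnb-start' "
                f"or an informative prior. Details: {verdict['details'][:3]}"
            )
    return post
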