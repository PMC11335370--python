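"""Posterior-predictive summaries of a fitted population model.

Two views of "what the population looks like": coverage regions in the
(lam, kc) parameter plane enclosing a stated fraction of the population,
and time-course bands containing 95% of population RIA curves beta(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde
from skimage import measure

from .bayes_population import PopulationPosterior
from .kinetics import TracerProtocol, beta_values

__all__ = ["CoverageRegion", "DynamicsBand", "predictive_draws",
           "coverage_region", "dynamics_band"]


@dataclass
class CoverageRegion:
    """Highest-density region at one level, estimated on the log plane.

    ``boundaries`` is a list of closed polylines (arrays of (lam, kc)
    rows, positive quadrant); ``boundaries_log`` the same in
    (ln lam, ln kc).  Membership tests use the KDE density threshold, so
    regions at increasing levels nest by construction.
    """

    level: float
    threshold: float
    boundaries: list
    boundaries_log: list
    _kde: gaussian_kde

    def contains(self, draws_log) -> np.ndarray:
        """Membership of (n,2) log-parameter points: density >= threshold."""
        pts = np.atleast_2d(np.asarray(draws_log, dtype=float))
        return self._kde(pts.T) >= self.threshold


@dataclass
class DynamicsBand:
    """Pointwise equal-tailed 95% envelope of population beta(t) curves."""

    times: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_draws: int


def predictive_draws(posterior: PopulationPosterior, n: int = 500,
                     seed: int | None = None, plug_in: bool = False) -> np.ndarray:
    """Sample (lam, kc) pairs for fresh, unobserved members of the population.

    For each draw a posterior sample of (mu_theta, Omega) is selected and
    theta* ~ N2(mu_theta, Omega) drawn, integrating over posterior
    uncertainty.  ``plug_in=True`` instead fixes (mu_theta, Omega) at
    their posterior means.  Returns an (n, 2) array of (lam, kc).
    """
    rng = np.random.default_rng(seed)
    mus = posterior.flat("mu_theta")
    omegas = posterior.flat("omega")
    if mus.shape[0] == 0:
        raise ValueError("empty posterior")
    if plug_in:
        mu = mus.mean(axis=0)
        om = omegas.mean(axis=0)
        chol = np.linalg.cholesky(om)
        z = rng.standard_normal((n, 2))
        theta = mu + z @ chol.T
    else:
        idx = rng.integers(0, mus.shape[0], size=n)
        z = rng.standard_normal((n, 2))
        theta = np.empty((n, 2))
        for i, j in enumerate(idx):
            chol = np.linalg.cholesky(omegas[j])
            theta[i] = mus[j] + chol @ z[i]
    return np.exp(theta)


def coverage_region(draws, levels=(0.95, 0.99, 0.995),
                    grid_size: int = 200, pad: float = 0.8) -> list:
    """Highest-density coverage regions of the population in (lam, kc).

    A Gaussian KDE is fitted on the log-parameter plane (where the model
    is Gaussian); for each level the density threshold retaining that
    fraction of the draws defines the region, and its contour lines are
    traced on a grid and mapped back to the natural scale.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.shape[0] < 500:
        raise ValueError("need >= 500 draws for a stable region estimate")
    if np.any(draws <= 0):
        raise ValueError("draws must be positive (lam, kc) pairs")
    logd = np.log(draws)
    spans = logd.max(axis=0) - logd.min(axis=0)
    if np.any(spans < 1e-12) or abs(np.corrcoef(logd.T)[0, 1]) > 0.9999:
        raise ValueError("degenerate (collinear or constant) draws; no 2D region exists")
    kde = gaussian_kde(logd.T)
    dens_at_draws = kde(logd.T)

    lo = logd.min(axis=0) - pad
    hi = logd.max(axis=0) + pad
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    XX, YY = np.meshgrid(gx, gy, indexing="ij")
    dens_grid = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(grid_size, grid_size)

    regions = []
    for level in sorted(levels):
        thr = float(np.quantile(dens_at_draws, 1.0 - level))
        contours = measure.find_contours(dens_grid, thr)
        blog, bnat = [], []
        for c in contours:
            xs = np.interp(c[:, 0], np.arange(grid_size), gx)
            ys = np.interp(c[:, 1], np.arange(grid_size), gy)
            poly = np.column_stack([xs, ys])
            blog.append(poly)
            bnat.append(np.exp(poly))
        regions.append(CoverageRegion(level=level, threshold=thr,
                                      boundaries=bnat, boundaries_log=blog,
                                      _kde=kde))
    return regions


def dynamics_band(draws, protocol: TracerProtocol = TracerProtocol(),
                  times=None, level: float = 0.95) -> DynamicsBand:
    """Pointwise envelope containing ``level`` of population beta(t) curves.

    Each (lam, kc) draw is evaluated by closed form with zero shift; at
    every grid time the equal-tailed interval across draws is taken.
    Intervals are pointwise, not simultaneous.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.shape[0] < 2:
        raise ValueError("need >= 2 draws")
    if times is None:
        times = np.arange(0.0, 36.01, 0.25)
    times = np.asarray(times, dtype=float)
    curves = np.empty((draws.shape[0], times.size))
    for i, (lam, kc) in enumerate(draws):
        curves[i] = beta_values(math.log(lam), math.log(kc), times, protocol)
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    lower, upper = np.percentile(curves, [lo_q, hi_q], axis=0)
    return DynamicsBand(times=times, lower=lower, upper=upper,
                        n_draws=draws.shape[0])
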