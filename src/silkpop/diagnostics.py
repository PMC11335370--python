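"""Convergence and sampling-quality diagnostics for MCMC output.

Implements the classical potential scale reduction factor (PSRF, within-
versus between-chain variance), a batch-means Monte-Carlo standard error
that accounts for chain autocorrelation, and the practical adequacy rule
that the MCSE should stay below 5% of the posterior standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["DiagnosticsReport", "gelman_rubin", "mcse_timeseries", "adequacy_check",
           "diagnose"]


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor for one parameter.

    ``chains``: array (m, n) of m >= 2 equal-length chains.  Returns
    sqrt([(n-1)/n * W + B/n] / W) with W the mean within-chain variance and
    B the between-chain variance of chain means (times n).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    if n < 10:
        raise ValueError("chains too short for PSRF")
    W = chains.var(axis=1, ddof=1).mean()
    B = n * chains.mean(axis=1).var(ddof=1)
    if W == 0:
        if np.all(chains == chains.flat[0]):
            return 1.0
        raise ValueError("zero within-chain variance with differing chains")
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))


def mcse_timeseries(draws, batch_len: int | None = None) -> float:
    """Batch-means Monte-Carlo standard error of the mean of one chain.

    Splits the chain into batches of length ~sqrt(n); the variance of the
    batch means, scaled by the batch length, estimates the long-run
    variance, so autocorrelation inflates the result relative to the naive
    sd/sqrt(n).  Constant chains return 0.
    """
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    if n < 100:
        raise ValueError("need >= 100 draws for a batch-means MCSE")
    if np.all(x == x[0]):
        return 0.0
    b = batch_len or int(math.floor(math.sqrt(n)))
    a = n // b
    means = x[: a * b].reshape(a, b).mean(axis=1)
    var_bm = b * means.var(ddof=1)
    return float(math.sqrt(var_bm / n))


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence summary for a multi-chain run."""

    params: dict  # name -> {psrf, mcse, sd, mcse_ratio, ess}

    def to_records(self):
        return [{"parameter": k, **v} for k, v in self.params.items()]


def diagnose(chains_by_param: dict) -> DiagnosticsReport:
    """Compute PSRF, MCSE, sd, MCSE/SD ratio and ESS per parameter.

    ``chains_by_param`` maps a parameter name to an (m, n) array.  The
    MCSE is computed per chain and pooled (root mean square across chains,
    divided by sqrt(m)), matching the variance of the pooled mean.
    """
    out = {}
    for name, chains in chains_by_param.items():
        chains = np.asarray(chains, dtype=float)
        m, n = chains.shape
        psrf = gelman_rubin(chains)
        per_chain = np.array([mcse_timeseries(c) for c in chains])
        mcse = float(np.sqrt(np.mean(per_chain ** 2) / m))
        sd = float(chains.std(ddof=1))
        ratio = mcse / sd if sd > 0 else 0.0
        ess = (sd / mcse) ** 2 if mcse > 0 else float(m * n)
        out[name] = {
            "psrf": psrf,
            "mcse": mcse,
            "sd": sd,
            "mcse_ratio": ratio,
            "ess": float(ess),
        }
    return DiagnosticsReport(params=out)


def adequacy_check(report: DiagnosticsReport,
                   ratio_threshold: float = 0.05,
                   psrf_threshold: float = 1.05) -> dict:
    """Pass/fail per parameter: MCSE/SD <= threshold (inclusive) and PSRF ok."""
    return {
        name: (v["mcse_ratio"] <= ratio_threshold and v["psrf"] <= psrf_threshold)
        for name, v in report.params.items()
    }
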