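"""Seeded adaptive random-walk Metropolis and convergence diagnostics.

The sampler targets an arbitrary log density over a real coefficient vector.
During burn-in the proposal is adapted: a global scale is tuned toward the
0.234 multivariate optimal acceptance rate, and the proposal covariance
tracks the running empirical covariance of the chain (scaled by 2.38^2/d).
Adaptation is frozen at the end of burn-in so the sampling phase is a
time-homogeneous Markov chain; draws are then recorded at the configured
thinning interval.  All randomness flows from a single ``numpy`` SeedSequence
so a fixed seed reproduces every draw bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["run_chain", "run_chains", "gelman_rubin_rhat", "DegenerateChainError"]


class DegenerateChainError(ValueError):
    """Within-chain variance is zero; the diagnostic is undefined."""


TARGET_ACCEPT = 0.234


def run_chain(
    log_density: Callable[[np.ndarray], float],
    start: np.ndarray,
    n_samples: int,
    burn_in: int,
    thinning: int,
    rng: np.random.Generator,
    initial_scale: float = 0.5,
) -> np.ndarray:
    """One adaptive Metropolis chain; returns (n_samples, dim) retained draws."""
    x = np.asarray(start, dtype=float).copy()
    dim = x.size
    lp = float(log_density(x))
    if not np.isfinite(lp):
        raise ValueError("log density not finite at the chain start point")

    # proposal: x + lam * (2.38/sqrt(d)) * chol(cov_hat) @ z
    lam = initial_scale
    base = 2.38 / np.sqrt(dim)
    mean = x.copy()
    cov = np.eye(dim)
    chol = np.eye(dim)
    count = 1
    accepted = 0
    window = 0
    adapt_block = 50

    draws = np.empty((n_samples, dim))
    kept = 0
    since_last = 0
    total = burn_in + n_samples * thinning
    for it in range(total):
        adapting = it < burn_in
        prop = x + (lam * base) * (chol @ rng.standard_normal(dim))
        lp_prop = float(log_density(prop))
        if np.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted += 1
        window += 1

        if adapting:
            count += 1
            delta = x - mean
            mean += delta / count
            cov += (np.outer(delta, x - mean) - cov) / count
            if window == adapt_block:
                lam *= np.exp(accepted / window - TARGET_ACCEPT)
                accepted = 0
                window = 0
                if count > 2 * dim:
                    try:
                        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(dim))
                    except np.linalg.LinAlgError:
                        pass
        else:
            since_last += 1
            if since_last == thinning:
                draws[kept] = x
                kept += 1
                since_last = 0
    assert kept == n_samples
    return draws


def run_chains(
    log_density: Callable[[np.ndarray], float],
    dim: int,
    n_chains: int,
    n_samples: int,
    burn_in: int,
    thinning: int,
    seed: int | np.random.SeedSequence,
    start_spread: float = 1.0,
) -> np.ndarray:
    """Independent chains from over-dispersed starts; (chains, samples, dim)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_chains)
    out = np.empty((n_chains, n_samples, dim))
    for c, child in enumerate(child_seeds):
        rng = np.random.Generator(np.random.PCG64(child))
        start = start_spread * rng.standard_normal(dim)
        out[c] = run_chain(log_density, start, n_samples, burn_in, thinning, rng)
    return out


def gelman_rubin_rhat(chains: np.ndarray) -> float:
    """Classic Gelman–Rubin potential scale reduction factor for one scalar.

    With m chains of length n, W the mean within-chain (ddof=1) variance and
    B = n * var(chain means, ddof=1):

        R-hat = sqrt( (((n-1)/n) * W + B/n) / W )

    Duplicated chains give sqrt((n-1)/n) < 1; separated chains exceed 1.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    n = arr.shape[1]
    within = arr.var(axis=1, ddof=1).mean()
    if within == 0:
        raise DegenerateChainError("all chains are internally constant; R-hat undefined")
    between = n * arr.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))
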