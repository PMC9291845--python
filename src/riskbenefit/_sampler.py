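"""Adaptive random-walk Metropolis sampling for smooth low-dimensional posteriors.

The proposal is a multivariate normal whose covariance is a scaled
Laplace-approximation covariance supplied by the caller; the global scale
adapts toward a target acceptance rate during burn-in only, so the
post-burn-in chain is a valid time-homogeneous Metropolis chain.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def sample_posterior(
    log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    proposal_cov: np.ndarray,
    chains: int = 2,
    iterations: int = 10_000,
    burn_in: int = 1_000,
    thin: int = 10,
    seed: int = 0,
    target_accept: float = 0.3,
    init_jitter: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Run ``chains`` adaptive Metropolis chains.

    Returns ``(draws, accept_rates)`` where ``draws`` has shape
    ``(chains, (iterations - burn_in) // thin, dim)``.
    """
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    dim = len(x0)
    L = np.linalg.cholesky(proposal_cov)
    n_keep = (iterations - burn_in) // thin
    draws = np.empty((chains, n_keep, dim))
    accept_rates = np.empty(chains)

    for c in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, c]))
        x = x0 + init_jitter * (L @ rng.standard_normal(dim))
        lp = log_post(x)
        log_scale = np.log(2.38 / np.sqrt(dim))
        accepted = 0
        kept = 0
        for it in range(iterations):
            scale = np.exp(log_scale)
            prop = x + scale * (L @ rng.standard_normal(dim))
            lp_prop = log_post(prop)
            accept = np.log(rng.random()) < lp_prop - lp
            if accept:
                x, lp = prop, lp_prop
            if it < burn_in:
                # Robbins-Monro scale adaptation, frozen after burn-in
                log_scale += (float(accept) - target_accept) / np.sqrt(it + 1)
            else:
                accepted += int(accept)
                k = it - burn_in
                if (k + 1) % thin == 0 and kept < n_keep:
                    draws[c, kept] = x
                    kept += 1
        accept_rates[c] = accepted / (iterations - burn_in)
    return draws, accept_rates
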