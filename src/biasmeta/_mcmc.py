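"""Shared numerics for the Metropolis-within-Gibbs samplers.

All log-likelihood evaluations use the exact binomial likelihood (constants
dropped) with numerically stable log-sigmoid terms, so zero-cell arms need no
continuity correction.
"""

from __future__ import annotations

import numpy as np
from scipy import special

_TINY = 1e-300


def log_expit(z: np.ndarray) -> np.ndarray:
    """log(1 / (1 + exp(-z))), stable for large |z|."""
    return -np.logaddexp(0.0, -z)


def binom_loglik(events, n, logit_p):
    """Binomial log-likelihood (up to the data-only constant) at logit(p)."""
    return events * log_expit(logit_p) + (n - events) * log_expit(-logit_p)


def truncated_sd_draw(rng, sum_sq, count, upper=2.0):
    """Gibbs draw of a normal scale parameter under a uniform(0, upper) prior.

    For n iid deviations with sum of squares S, the full conditional of the
    precision lambda = sd^-2 is Gamma((n-1)/2, rate S/2) truncated to
    lambda >= upper^-2 (the uniform prior on sd contributes the Jacobian).
    Sampled exactly via the regularized incomplete gamma inverse.
    """
    sum_sq = np.maximum(np.asarray(sum_sq, dtype=float), 1e-12)
    # n = 1 gives a shape-0 (log-divergent) conditional; a small positive
    # floor keeps the draw proper for that degenerate, prior-driven case
    a = np.maximum((np.asarray(count, dtype=float) - 1.0) / 2.0, 0.005)
    b = sum_sq / 2.0
    lam_min = upper**-2
    p0 = special.gammainc(a, b * lam_min)
    u = p0 + rng.random(np.shape(sum_sq)) * (1.0 - p0)
    u = np.clip(u, 1e-16, 1.0 - 1e-16)
    lam = special.gammaincinv(a, u) / b
    return np.minimum(np.maximum(lam, _TINY) ** -0.5, upper)


def split_rhat(chains: np.ndarray) -> float:
    """Potential scale reduction factor from the second halves of chains.

    ``chains`` has shape (n_chains, n_draws). Degenerate conventions: if the
    within-chain variance vanishes, returns 1.0 when the chains agree and
    +inf when they sit at distinct constants.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected a 2-D (n_chains, n_draws) array")
    m, n_total = chains.shape
    if m < 2:
        raise ValueError("the diagnostic requires at least two chains")
    arr = chains[:, n_total // 2 :]
    n = arr.shape[1]
    if n < 2:
        raise ValueError("chains too short for the diagnostic")
    within = float(arr.var(axis=1, ddof=1).mean())
    b_over_n = float(arr.mean(axis=1).var(ddof=1))
    if within <= 1e-300:
        return 1.0 if b_over_n <= 1e-300 else float("inf")
    var_plus = (n - 1) / n * within + b_over_n
    # the finite-sample (n-1)/n factor can push the ratio a hair below 1
    return float(max(np.sqrt(var_plus / within), 1.0))
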