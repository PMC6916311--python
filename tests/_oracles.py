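"""Independent oracles shared across tests.

These deliberately avoid the library code paths they are used to check:
truncated-normal quartiles by bisection on the normalized CDF, and the
normal-normal Bayesian update by random-walk Metropolis sampling.
"""

import numpy as np
from scipy.stats import norm


def trunc_quantile_bisect(mu, sd, areas, q, tol=1e-12):
    """Quantile of a normal truncated to quartile areas, by bisection."""
    idx = sorted("ABCD".index(a) for a in areas)
    p_lo, p_hi = 0.25 * idx[0], 0.25 * (idx[-1] + 1)
    a = norm.ppf(p_lo) if p_lo > 0 else -50.0
    b = norm.ppf(p_hi) if p_hi < 1 else 50.0
    mass = p_hi - p_lo

    def cdf(z):
        return (norm.cdf(z) - p_lo) / mass

    lo, hi = a, b
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if cdf(mid) < q:
            lo = mid
        else:
            hi = mid
    return mu + sd * 0.5 * (lo + hi)


def mcmc_two_level(mu_o, sd_o, mu_d, sd_d, seed=0, n_iter=80_000, burn=5_000):
    """Vectorized RW Metropolis for beta in: mu_o ~ N(beta, sd_o^2),
    beta ~ N(mu_d, sd_d^2). Returns posterior means and sds."""
    rng = np.random.default_rng(seed)
    mu_o = np.asarray(mu_o, dtype=float)
    sd_o = np.asarray(sd_o, dtype=float)
    mu_d = np.asarray(mu_d, dtype=float)
    sd_d = np.asarray(sd_d, dtype=float)
    k = mu_o.size
    beta = mu_d.copy()
    step = 2.4 * np.minimum(sd_o, sd_d)

    def logp(b):
        return -0.5 * ((mu_o - b) / sd_o) ** 2 - 0.5 * ((b - mu_d) / sd_d) ** 2

    cur = logp(beta)
    total = np.zeros(k)
    total2 = np.zeros(k)
    n_kept = 0
    for it in range(n_iter):
        prop = beta + step * rng.standard_normal(k)
        new = logp(prop)
        acc = np.log(rng.random(k)) < new - cur
        beta = np.where(acc, prop, beta)
        cur = np.where(acc, new, cur)
        if it >= burn:
            total += beta
            total2 += beta * beta
            n_kept += 1
    mean = total / n_kept
    var = total2 / n_kept - mean**2
    return mean, np.sqrt(var)
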