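"""Bias-adjusted Bayesian random-effects meta-analysis for binary outcomes.

Model, per trial i with arms (events, n):

    events_ctrl_i ~ Bin(n_ctrl_i, expit(alpha_i))
    events_trt_i  ~ Bin(n_trt_i,  expit(alpha_i + delta_i + x_i beta_i))
    delta_i ~ N(d, tau^2)          random true effects (log odds ratios)
    beta_i  ~ N(mu_i, sigma_i^2)   fixed informative bias prior, flagged only
    d ~ N(0, 1e5),  tau ~ U(0, 2),  alpha_i ~ N(0, 1e5)

x_i = 1 when the trial has any high-or-unclear risk-of-bias flag, in which
case an informative prior for its bias (log-ROR) must be supplied; all-low
trials carry no bias term.  Posterior sampling is Metropolis-within-Gibbs:
random-walk updates for alpha_i and for eta_i = delta_i + x_i beta_i (with
the exact conditional decomposition of eta into delta and beta), conjugate
Gibbs for d, an exact truncated-gamma Gibbs step for tau, and a joint
translation move on (d, delta) that removes the small-tau funnel.  Proposal
scales adapt only during burn-in.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.special import logit

from ._mcmc import binom_loglik, split_rhat, truncated_sd_draw
from .data_model import (
    BiasDistribution,
    MCMCConfig,
    PosteriorSummary,
    TrialRecord,
    ValidationError,
)

__all__ = ["RHAT_THRESHOLD", "fit_bias_adjusted", "gelman_rubin", "summarize"]

RHAT_THRESHOLD = 1.05

_D_PRIOR_VAR = 1e5
_ALPHA_PRIOR_VAR = 1e5
_TAU_UPPER = 2.0


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor for one parameter.

    ``chains`` is an (n_chains, n_draws) array; the statistic uses
    between/within-chain variances on the second halves of the chains.
    Identical constant chains return 1.0 by convention; chains stuck at
    distinct constants return +inf.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValidationError("gelman_rubin requires >= 2 chains of equal length")
    if chains.shape[1] < 10:
        raise ValidationError("chains must have length >= 10")
    return split_rhat(chains)


_TRANSFORMS = {
    "identity": lambda a: a,
    "exp": np.exp,
    "square": np.square,
}


def summarize(samples, transform: str = "identity") -> tuple[float, float, float]:
    """(median, 2.5%, 97.5%) of transformed draws.

    Quantiles use linear interpolation of order statistics (the type-7
    convention), which matters for credible-interval endpoints.
    """
    if transform not in _TRANSFORMS:
        raise ValidationError(f"transform must be one of {sorted(_TRANSFORMS)}")
    arr = np.asarray(samples, dtype=float).ravel()
    if arr.size < 100:
        raise ValidationError(f"need >= 100 retained draws, got {arr.size}")
    t = _TRANSFORMS[transform](arr)
    med, lo, hi = np.quantile(t, [0.5, 0.025, 0.975])
    return float(med), float(lo), float(hi)


def _prepare_arrays(
    trials: Sequence[TrialRecord],
    priors: Mapping[str, BiasDistribution] | None,
):
    n = len(trials)
    if n < 2:
        raise ValidationError("need at least 2 trials")
    rc = np.array([t.events_ctrl for t in trials], dtype=float)
    nc = np.array([t.n_ctrl for t in trials], dtype=float)
    rt = np.array([t.events_trt for t in trials], dtype=float)
    nt = np.array([t.n_trt for t in trials], dtype=float)
    mu = np.zeros(n)
    sig2 = np.zeros(n)
    if priors is None:
        x = np.zeros(n, dtype=bool)
    else:
        x = np.array([not t.profile.is_all_low for t in trials], dtype=bool)
        for i, t in enumerate(trials):
            if x[i]:
                if t.trial_id not in priors:
                    raise ValidationError(
                        f"flagged trial {t.trial_id!r} has no bias prior"
                    )
                mu[i] = priors[t.trial_id].mean
                sig2[i] = priors[t.trial_id].sd ** 2
            elif t.trial_id in priors:
                raise ValidationError(
                    f"trial {t.trial_id!r} is at low risk of bias in all domains "
                    f"and must not have a bias prior"
                )
    return rc, nc, rt, nt, x, mu, sig2


def fit_bias_adjusted(
    trials: Sequence[TrialRecord],
    priors: Mapping[str, BiasDistribution] | None,
    config: MCMCConfig,
    *,
    tau_fixed: float | None = None,
):
    """Fit the bias-adjusted meta-analysis by MCMC.

    ``priors`` maps trial_id -> bias distribution for every flagged trial
    (all-low trials must not appear); passing ``None`` fits the unadjusted
    model in which every trial is taken at face value.  ``tau_fixed`` pins
    the between-trial standard deviation (``0`` gives the common-effect
    limit); by default tau is sampled under its uniform(0, 2) prior.

    Returns ``(samples, summary)``: a dict of retained draws on the
    reporting scale (``d`` and ``delta`` in log odds ratios oriented as the
    input data, ``tau``, ``beta``) and a :class:`PosteriorSummary` of
    exp(d) and tau^2.
    """
    rc, nc, rt, nt, x, mu, sig2 = _prepare_arrays(trials, priors)
    flip = config.benefit_direction == "or_gt_1"
    if flip:
        # recode events as non-events in both arms: benefit becomes OR < 1
        # internally, so bias priors (benefit-exaggeration orientation) apply
        # unchanged; effect draws are flipped back for reporting
        rc, rt = nc - rc, nt - rt
    if tau_fixed is not None and tau_fixed == 0.0:
        draws = _sample_common_effect(rc, nc, rt, nt, x, mu, sig2, config)
    else:
        draws = _sample_random_effects(
            rc, nc, rt, nt, x, mu, sig2, config, tau_fixed
        )
    if flip:
        draws["d"] = -draws["d"]
        draws["delta"] = -draws["delta"]

    rhats = [split_rhat(draws["d"])]
    if tau_fixed is None:
        rhats.append(split_rhat(draws["tau"]))
    for i in range(len(trials)):
        rhats.append(split_rhat(draws["delta"][:, :, i]))
    rhat_max = float(np.max(rhats))

    or_med, or_lo, or_hi = summarize(draws["d"], "exp")
    t2_med, t2_lo, t2_hi = summarize(draws["tau"], "square")
    summary = PosteriorSummary(
        or_median=or_med,
        or_lo=or_lo,
        or_hi=or_hi,
        tau2_median=t2_med,
        tau2_lo=t2_lo,
        tau2_hi=t2_hi,
        rhat_max=rhat_max,
    )
    return draws, summary


def _initial_state(rc, nc, rt, nt, n_chains):
    a_hat = logit((rc + 0.5) / (nc + 1.0))
    e_hat = logit((rt + 0.5) / (nt + 1.0)) - a_hat
    disp = np.linspace(-1.0, 1.0, n_chains)[:, None]
    alpha = np.tile(a_hat, (n_chains, 1)) + 0.25 * disp
    eta = np.tile(e_hat, (n_chains, 1)) + disp
    return alpha, eta


def _sample_random_effects(rc, nc, rt, nt, x, mu, sig2, cfg, tau_fixed):
    C, T = cfg.n_chains, rc.size
    keep = cfg.n_iter - cfg.n_burnin
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    alpha, eta = _initial_state(rc, nc, rt, nt, C)
    d = np.linspace(-1.0, 1.0, C).copy()
    if tau_fixed is None:
        tau = np.linspace(0.2, 1.8, C)
    else:
        if not 0 < tau_fixed <= _TAU_UPPER:
            raise ValidationError("tau_fixed must lie in (0, 2] or be exactly 0")
        tau = np.full(C, float(tau_fixed))
    sig2_safe = np.where(x, sig2, 1.0)

    step_a = np.full((C, T), 0.5)
    step_e = np.full((C, T), 0.5)
    step_s = np.full(C, 0.3)

    ll_c = binom_loglik(rc, nc, alpha)
    ll_t = binom_loglik(rt, nt, alpha + eta)
    delta = eta.copy()

    d_out = np.empty((C, keep))
    tau_out = np.empty((C, keep))
    delta_out = np.empty((C, keep, T))
    beta_out = np.empty((C, keep, T))

    for it in range(cfg.n_iter):
        # --- alpha: random-walk Metropolis, vectorized over chains x trials
        prop = alpha + step_a * rng.standard_normal((C, T))
        pll_c = binom_loglik(rc, nc, prop)
        pll_t = binom_loglik(rt, nt, prop + eta)
        logr = (
            pll_c + pll_t - ll_c - ll_t
            + (alpha * alpha - prop * prop) / (2.0 * _ALPHA_PRIOR_VAR)
        )
        acc_a = np.log(rng.random((C, T))) < logr
        alpha = np.where(acc_a, prop, alpha)
        ll_c = np.where(acc_a, pll_c, ll_c)
        ll_t = np.where(acc_a, pll_t, ll_t)

        # --- eta = delta + x beta: RW Metropolis on the collapsed prior
        tau2 = (tau**2)[:, None]
        pm = d[:, None] + mu[None, :]
        pv = tau2 + sig2[None, :]
        prop = eta + step_e * rng.standard_normal((C, T))
        pll_t = binom_loglik(rt, nt, alpha + prop)
        logr = pll_t - ll_t + ((eta - pm) ** 2 - (prop - pm) ** 2) / (2.0 * pv)
        acc_e = np.log(rng.random((C, T))) < logr
        eta = np.where(acc_e, prop, eta)
        ll_t = np.where(acc_e, pll_t, ll_t)

        # --- exact decomposition of eta into (delta, beta) for flagged trials
        v_post = 1.0 / (1.0 / tau2 + 1.0 / sig2_safe[None, :])
        m_post = v_post * (d[:, None] / tau2 + (eta - mu[None, :]) / sig2_safe)
        dlt = m_post + np.sqrt(v_post) * rng.standard_normal((C, T))
        delta = np.where(x[None, :], dlt, eta)

        # --- joint translation of (d, delta): likelihood-driven MH move
        eps = step_s * rng.standard_normal(C)
        pll_t = binom_loglik(rt, nt, alpha + eta + eps[:, None])
        logr = (pll_t - ll_t).sum(axis=1) + (d**2 - (d + eps) ** 2) / (
            2.0 * _D_PRIOR_VAR
        )
        acc_s = np.log(rng.random(C)) < logr
        eps = np.where(acc_s, eps, 0.0)
        d = d + eps
        delta = delta + eps[:, None]
        eta = eta + eps[:, None]
        ll_t = np.where(acc_s[:, None], pll_t, ll_t)

        # --- d: conjugate Gibbs
        tau2v = tau**2
        prec = T / tau2v + 1.0 / _D_PRIOR_VAR
        mean = (delta.sum(axis=1) / tau2v) / prec
        d = mean + rng.standard_normal(C) / np.sqrt(prec)

        # --- tau: exact Gibbs under the uniform(0, 2) prior
        if tau_fixed is None:
            S = ((delta - d[:, None]) ** 2).sum(axis=1)
            tau = truncated_sd_draw(rng, S, T, upper=_TAU_UPPER)

        if it < cfg.n_burnin:
            g = (it + 1.0) ** -0.6
            step_a *= np.exp(g * (acc_a - 0.44))
            step_e *= np.exp(g * (acc_e - 0.44))
            step_s *= np.exp(g * (acc_s - 0.30))
        else:
            k = it - cfg.n_burnin
            d_out[:, k] = d
            tau_out[:, k] = tau
            delta_out[:, k, :] = delta
            beta_out[:, k, :] = np.where(x[None, :], eta - delta, 0.0)

    return {"d": d_out, "tau": tau_out, "delta": delta_out, "beta": beta_out}


def _sample_common_effect(rc, nc, rt, nt, x, mu, sig2, cfg):
    """Degenerate-heterogeneity limit: delta_i = d for every trial."""
    C, T = cfg.n_chains, rc.size
    keep = cfg.n_iter - cfg.n_burnin
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    alpha, eta0 = _initial_state(rc, nc, rt, nt, C)
    d = np.median(eta0, axis=1) + np.linspace(-0.5, 0.5, C)
    beta = np.zeros((C, T))
    sig2_safe = np.where(x, sig2, 1.0)

    step_a = np.full((C, T), 0.5)
    step_b = np.full((C, T), 0.3)
    step_d = np.full(C, 0.2)

    eta = d[:, None] + beta
    ll_c = binom_loglik(rc, nc, alpha)
    ll_t = binom_loglik(rt, nt, alpha + eta)

    d_out = np.empty((C, keep))
    delta_out = np.empty((C, keep, T))
    beta_out = np.empty((C, keep, T))

    for it in range(cfg.n_iter):
        prop = alpha + step_a * rng.standard_normal((C, T))
        pll_c = binom_loglik(rc, nc, prop)
        pll_t = binom_loglik(rt, nt, prop + eta)
        logr = (
            pll_c + pll_t - ll_c - ll_t
            + (alpha * alpha - prop * prop) / (2.0 * _ALPHA_PRIOR_VAR)
        )
        acc_a = np.log(rng.random((C, T))) < logr
        alpha = np.where(acc_a, prop, alpha)
        ll_c = np.where(acc_a, pll_c, ll_c)
        ll_t = np.where(acc_a, pll_t, ll_t)

        # d: RW Metropolis against the joint treatment-arm likelihood
        prop_d = d + step_d * rng.standard_normal(C)
        prop_eta = prop_d[:, None] + beta
        pll_t = binom_loglik(rt, nt, alpha + prop_eta)
        logr = (pll_t - ll_t).sum(axis=1) + (d**2 - prop_d**2) / (2.0 * _D_PRIOR_VAR)
        acc_d = np.log(rng.random(C)) < logr
        d = np.where(acc_d, prop_d, d)
        eta = np.where(acc_d[:, None], prop_eta, eta)
        ll_t = np.where(acc_d[:, None], pll_t, ll_t)

        # beta (flagged trials): RW Metropolis with the informative prior
        prop_b = beta + step_b * rng.standard_normal((C, T))
        prop_eta = d[:, None] + prop_b
        pll_t = binom_loglik(rt, nt, alpha + prop_eta)
        logr = (
            pll_t - ll_t
            + ((beta - mu) ** 2 - (prop_b - mu) ** 2) / (2.0 * sig2_safe)
        )
        acc_b = (np.log(rng.random((C, T))) < logr) & x[None, :]
        beta = np.where(acc_b, prop_b, beta)
        eta = np.where(acc_b, prop_eta, eta)
        ll_t = np.where(acc_b, pll_t, ll_t)

        if it < cfg.n_burnin:
            g = (it + 1.0) ** -0.6
            step_a *= np.exp(g * (acc_a - 0.44))
            step_b *= np.exp(g * (np.where(x[None, :], acc_b, 0.44) - 0.44))
            step_d *= np.exp(g * (acc_d - 0.30))
        else:
            k = it - cfg.n_burnin
            d_out[:, k] = d
            delta_out[:, k, :] = d[:, None]
            beta_out[:, k, :] = beta

    tau_out = np.zeros((C, keep))
    return {"d": d_out, "tau": tau_out, "delta": delta_out, "beta": beta_out}
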