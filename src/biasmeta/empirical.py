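"""Data-based bias evidence from a meta-epidemiological collection.

Fits an additive, per-domain, two-level hierarchical bias model to a
collection of meta-analyses that each contain trials at low risk of bias and
trials flagged (high-or-unclear) in at least one domain.  Within
meta-analysis m, trial t has log odds ratio

    theta_mt = delta_mt + sum_c x_mtc beta_mtc
    delta_mt ~ N(d_m, tau_m^2)          true effects within the meta-analysis
    beta_mtc ~ N(b_mc, kappa_c^2)       within-meta-analysis bias variation
    b_mc     ~ N(b0_c, phi_c^2)         between-meta-analysis bias variation

with binomial arm likelihoods and priors d_m ~ N(0, 1e5), tau_m ~ U(0, 2),
b0_c ~ N(0, 1e3), phi_c, kappa_c ~ U(0, 2).  Domains are a priori independent
and biases additive, so the predictive distribution for total bias in a new
trial with a given profile is the sum of its flagged domains' predictives
beta_new,c ~ N(b0_c, phi_c^2 + kappa_c^2).

This is an approximating model: published per-profile bias distributions are
the only external constraint on its exact form, and ``load_bias_table``
allows running the downstream methods from any published table instead of
refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._mcmc import binom_loglik, split_rhat, truncated_sd_draw
from .data_model import (
    BiasDistribution,
    BiasProfile,
    DOMAINS,
    FormatError,
    MCMCConfig,
    TrialRecord,
    ValidationError,
)
from .metaanalysis import RHAT_THRESHOLD, _initial_state

__all__ = [
    "BiasComponentPosterior",
    "IdentificationError",
    "MetaEpiRecord",
    "fit_meta_epi",
    "load_bias_table",
    "predictive_bias",
    "predictive_bias_table",
    "priors_from_table",
    "write_bias_table",
]

#: a meta-epidemiological record is a trial record whose meta_id groups it
MetaEpiRecord = TrialRecord

_B0_PRIOR_VAR = 1e3
_D_PRIOR_VAR = 1e5
_SD_UPPER = 2.0
_SD_FLOOR = 1e-6


class IdentificationError(ValueError):
    """The collection cannot identify the bias parameters."""


@dataclass
class BiasComponentPosterior:
    """Posterior samples for the per-domain bias components.

    Arrays have shape (n_chains, n_draws, 3) with the last axis in domain
    order (seq_gen, alloc_conc, blinding).
    """

    b0: np.ndarray
    phi: np.ndarray
    kappa: np.ndarray
    domains: tuple[str, ...] = DOMAINS
    rhat_max: float = float("nan")
    warnings: tuple[str, ...] = ()

    def flat(self, name: str) -> np.ndarray:
        """Pooled-chain samples, shape (n_samples, 3)."""
        arr = getattr(self, name)
        return arr.reshape(-1, arr.shape[-1])

    def summary(self) -> pd.DataFrame:
        rows = []
        for ci, domain in enumerate(self.domains):
            for name in ("b0", "phi", "kappa"):
                samp = self.flat(name)[:, ci]
                rows.append(
                    {
                        "domain": domain,
                        "parameter": name,
                        "mean": float(samp.mean()),
                        "sd": float(samp.std(ddof=1)),
                    }
                )
        return pd.DataFrame(rows)


def fit_meta_epi(
    records: Sequence[MetaEpiRecord], config: MCMCConfig
) -> BiasComponentPosterior:
    """Fit the hierarchical bias model to a meta-epidemiological collection.

    Requires flagged trials (for the bias contrast) and all-low trials (for
    the reference effects); a single-meta-analysis collection runs but the
    between-meta-analysis spread is then prior-driven, which is flagged in
    ``warnings`` rather than silently accepted.
    """
    if len(records) < 2:
        raise IdentificationError("need at least 2 trials")
    meta_ids = sorted({r.meta_id for r in records})
    m_index = {m: i for i, m in enumerate(meta_ids)}
    M, T = len(meta_ids), len(records)
    m_idx = np.array([m_index[r.meta_id] for r in records])
    x = np.array([r.profile.flags for r in records], dtype=float)  # (T, 3)
    if not x.any():
        raise IdentificationError("no flagged trials: bias parameters are unidentified")
    if not (x.sum(axis=1) == 0).any():
        raise IdentificationError("no all-low trials: reference effects are unidentified")
    warnings: list[str] = []
    if M < 2:
        warnings.append(
            "single meta-analysis: between-meta-analysis sds are prior-driven"
        )

    rc = np.array([r.events_ctrl for r in records], dtype=float)
    nc = np.array([r.n_ctrl for r in records], dtype=float)
    rt = np.array([r.events_trt for r in records], dtype=float)
    nt = np.array([r.n_trt for r in records], dtype=float)

    draws = _sample_meta_epi(rc, nc, rt, nt, x, m_idx, M, config)

    rhats = []
    for name in ("b0", "phi", "kappa"):
        for ci in range(3):
            rhats.append(split_rhat(draws[name][:, :, ci]))
    rhat_max = float(np.max(rhats))
    if rhat_max > RHAT_THRESHOLD:
        warnings.append(f"non-convergence: max Rhat {rhat_max:.3f} > {RHAT_THRESHOLD}")

    return BiasComponentPosterior(
        b0=draws["b0"],
        phi=draws["phi"],
        kappa=draws["kappa"],
        rhat_max=rhat_max,
        warnings=tuple(warnings),
    )


def _sample_meta_epi(rc, nc, rt, nt, x, m_idx, M, cfg):
    C, T = cfg.n_chains, rc.size
    keep = cfg.n_iter - cfg.n_burnin
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    # membership matrices for per-meta / per-domain aggregation
    onehot = np.zeros((M, T))
    onehot[m_idx, np.arange(T)] = 1.0
    n_m = onehot.sum(axis=1)  # trials per meta
    A = onehot[None, :, :] * x.T[:, None, :]  # (3, M, T) flagged membership
    k_mc = A.sum(axis=2)  # (3, M) flagged trials per meta per domain
    n_c = x.sum(axis=0)  # (3,) flagged trials per domain

    alpha, eta = _initial_state(rc, nc, rt, nt, C)
    disp = np.linspace(-0.5, 0.5, C)
    b0 = np.tile(disp[:, None], (1, 3))
    phi = np.tile(np.linspace(0.1, 1.0, C)[:, None], (1, 3))
    kap = np.tile(np.linspace(0.1, 1.0, C)[:, None], (1, 3))
    b = np.zeros((C, M, 3)) + b0[:, None, :]
    d_m = np.zeros((C, M)) + disp[:, None]
    tau_m = np.full((C, M), 0.3)
    beta = np.zeros((C, T, 3))
    delta = eta.copy()

    step_a = np.full((C, T), 0.5)
    step_e = np.full((C, T), 0.5)

    ll_c = binom_loglik(rc, nc, alpha)
    ll_t = binom_loglik(rt, nt, alpha + eta)

    out_b0 = np.empty((C, keep, 3))
    out_phi = np.empty((C, keep, 3))
    out_kap = np.empty((C, keep, 3))

    xb = x[None, :, :]  # (1, T, 3)

    for it in range(cfg.n_iter):
        # --- alpha
        prop = alpha + step_a * rng.standard_normal((C, T))
        pll_c = binom_loglik(rc, nc, prop)
        pll_t = binom_loglik(rt, nt, prop + eta)
        logr = pll_c + pll_t - ll_c - ll_t + (alpha**2 - prop**2) / (2.0 * 1e5)
        acc_a = np.log(rng.random((C, T))) < logr
        alpha = np.where(acc_a, prop, alpha)
        ll_c = np.where(acc_a, pll_c, ll_c)
        ll_t = np.where(acc_a, pll_t, ll_t)

        # --- eta with the (delta, beta_c) components collapsed out
        kap2 = kap**2  # (C, 3)
        tau2 = tau_m**2  # (C, M)
        var_beta = xb * kap2[:, None, :]  # (C, T, 3)
        pm = d_m[:, m_idx] + (xb * b[:, m_idx, :]).sum(axis=2)
        pv = tau2[:, m_idx] + var_beta.sum(axis=2)
        prop = eta + step_e * rng.standard_normal((C, T))
        pll_t = binom_loglik(rt, nt, alpha + prop)
        logr = pll_t - ll_t + ((eta - pm) ** 2 - (prop - pm) ** 2) / (2.0 * pv)
        acc_e = np.log(rng.random((C, T))) < logr
        eta = np.where(acc_e, prop, eta)
        ll_t = np.where(acc_e, pll_t, ll_t)

        # --- decompose eta into delta + flagged betas: draw the independent
        # components from their priors, then shift them onto the constraint
        z_d = d_m[:, m_idx] + np.sqrt(tau2[:, m_idx]) * rng.standard_normal((C, T))
        z_b = (
            b[:, m_idx, :] + np.sqrt(kap2)[:, None, :] * rng.standard_normal((C, T, 3))
        ) * xb
        resid = (eta - z_d - z_b.sum(axis=2)) / pv
        delta = z_d + tau2[:, m_idx] * resid
        beta = z_b + var_beta * resid[:, :, None]

        # --- b_mc: conjugate Gibbs
        sums = np.einsum("dmt,ctd->cmd", A, beta)  # (C, M, 3)
        phi2 = np.maximum(phi**2, _SD_FLOOR**2)
        kap2s = np.maximum(kap2, _SD_FLOOR**2)
        prec = k_mc.T[None, :, :] / kap2s[:, None, :] + 1.0 / phi2[:, None, :]
        mean = (sums / kap2s[:, None, :] + b0[:, None, :] / phi2[:, None, :]) / prec
        b = mean + rng.standard_normal((C, M, 3)) / np.sqrt(prec)

        # --- b0_c: conjugate Gibbs
        prec0 = M / phi2 + 1.0 / _B0_PRIOR_VAR
        mean0 = (b.sum(axis=1) / phi2) / prec0
        b0 = mean0 + rng.standard_normal((C, 3)) / np.sqrt(prec0)

        # --- phi_c, kappa_c: truncated-gamma Gibbs
        S_phi = ((b - b0[:, None, :]) ** 2).sum(axis=1)
        phi = truncated_sd_draw(rng, S_phi, M, upper=_SD_UPPER)
        S_kap = (xb * (beta - b[:, m_idx, :]) ** 2).sum(axis=1)
        kap = truncated_sd_draw(rng, S_kap, n_c[None, :], upper=_SD_UPPER)

        # --- d_m, tau_m: Gibbs per meta-analysis
        dsum = np.einsum("mt,ct->cm", onehot, delta)
        prec_d = n_m[None, :] / tau2 + 1.0 / _D_PRIOR_VAR
        mean_d = (dsum / tau2) / prec_d
        d_m = mean_d + rng.standard_normal((C, M)) / np.sqrt(prec_d)
        S_tau = np.einsum("mt,ct->cm", onehot, (delta - d_m[:, m_idx]) ** 2)
        tau_m = truncated_sd_draw(rng, S_tau, n_m[None, :], upper=_SD_UPPER)

        if it < cfg.n_burnin:
            g = (it + 1.0) ** -0.6
            step_a *= np.exp(g * (acc_a - 0.44))
            step_e *= np.exp(g * (acc_e - 0.44))
        else:
            k = it - cfg.n_burnin
            out_b0[:, k, :] = b0
            out_phi[:, k, :] = phi
            out_kap[:, k, :] = kap

    return {"b0": out_b0, "phi": out_phi, "kappa": out_kap}


def predictive_bias(
    posterior: BiasComponentPosterior,
    profile: BiasProfile,
    *,
    sd_floor: float = _SD_FLOOR,
) -> BiasDistribution:
    """Predictive distribution for total bias in a new trial with ``profile``.

    Per posterior sample the predictive for each flagged domain is
    N(b0_c, phi_c^2 + kappa_c^2); domains add independently.  The returned
    normal matches the pooled predictive draws exactly via the law of total
    variance: mean = E[sum b0_c], var = Var(sum b0_c) + E[sum phi^2+kappa^2].
    """
    flags = np.array(profile.flags, dtype=bool)
    if not flags.any():
        raise ValidationError("no bias term for all-low trials")
    b0 = posterior.flat("b0")[:, flags].sum(axis=1)
    v = (posterior.flat("phi") ** 2 + posterior.flat("kappa") ** 2)[:, flags].sum(axis=1)
    mean = float(b0.mean())
    var = float(b0.var()) + float(v.mean())
    sd = math.sqrt(var)
    if sd < sd_floor:
        sd = sd_floor  # protects downstream samplers from degenerate priors
    return BiasDistribution(mean=mean, sd=sd, source="data", profile_key=profile.key)


def predictive_bias_table(
    posterior: BiasComponentPosterior,
) -> dict[str, BiasDistribution]:
    """Predictive distributions for all 7 flagged bias profiles."""
    from .data_model import FLAGGED_PROFILE_KEYS

    return {
        key: predictive_bias(posterior, BiasProfile.from_key(key))
        for key in FLAGGED_PROFILE_KEYS
    }


def load_bias_table(path: str | Path) -> dict[str, BiasDistribution]:
    """Read a profile-keyed bias table (columns profile_key, mean_logror,
    sd_logror), e.g. one published from a meta-epidemiological fit."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("profile_key", "mean_logror", "sd_logror"):
        if col not in df.columns:
            raise FormatError(f"bias table {path} is missing column {col!r}")
    out: dict[str, BiasDistribution] = {}
    for row in df.itertuples(index=False):
        key = str(row.profile_key)
        if key in out:
            raise FormatError(f"duplicate profile_key {key!r} in bias table")
        sd = float(row.sd_logror)
        if sd <= 0:
            raise ValidationError(f"profile {key!r}: sd_logror must be > 0, got {sd}")
        out[key] = BiasDistribution(
            mean=float(row.mean_logror), sd=sd, source="data", profile_key=key
        )
    return out


def write_bias_table(table: Mapping[str, BiasDistribution], path: str | Path) -> None:
    rows = [
        {
            "profile_key": key,
            "mean_logror": repr(dist.mean),
            "sd_logror": repr(dist.sd),
        }
        for key, dist in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["profile_key", "mean_logror", "sd_logror"]).to_csv(
        path, index=False
    )


def priors_from_table(
    trials: Sequence[TrialRecord], table: Mapping[str, BiasDistribution]
) -> dict[str, BiasDistribution]:
    """Trial-keyed bias priors for the flagged trials, looked up by profile."""
    out: dict[str, BiasDistribution] = {}
    for t in trials:
        if t.profile.is_all_low:
            continue
        key = t.profile.key
        if key not in table:
            raise FormatError(
                f"bias table has no entry for profile {key!r} (trial {t.trial_id!r})"
            )
        ref = table[key]
        out[t.trial_id] = BiasDistribution(
            mean=ref.mean, sd=ref.sd, source=ref.source, profile_key=key
        )
    return out
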