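"""Inter-assessor consistency of elicited bias means.

Fits the mixed model  mean_ij = a_j + u_i + e_ij  with assessors j as fixed
effects and trials i as random effects (u_i ~ N(0, sigma_trial^2),
e_ij ~ N(0, sigma_resid^2)) by direct maximum likelihood, profiling the
likelihood over the variance ratio.  The intraclass correlation coefficient

    ICC = sigma_trial^2 / (sigma_trial^2 + sigma_resid^2)

is the proportion of variation in elicited bias means attributable to trials
rather than assessors; its approximate 95% confidence interval is the
percentile interval of ICCs refit on parametric-bootstrap datasets simulated
from the fitted model (same layout, conditioning on the fitted fixed
effects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .data_model import FormatError, ValidationError

__all__ = ["IccResult", "MixedFitResult", "fit_mixed", "icc_with_ci"]

_PSI_MAX = 16.0  # bound on log variance ratio in the profile search


@dataclass
class MixedFitResult:
    assessor_effects: dict[str, float]
    sigma2_trial: float
    sigma2_resid: float
    loglik: float


@dataclass
class IccResult:
    icc: float
    ci: tuple[float, float]
    sigma2_trial: float
    sigma2_resid: float
    degenerate: bool = False


def _prepare(table: pd.DataFrame):
    for col in ("trial_id", "assessor_id", "mean"):
        if col not in table.columns:
            raise FormatError(f"opinion-means table is missing column {col!r}")
    key_cols = ["trial_id", "assessor_id"]
    if "strategy" in table.columns:
        key_cols.append("strategy")
    if table.duplicated(subset=key_cols).any():
        raise ValidationError("each (trial, assessor, strategy) may appear at most once")
    trials, g = np.unique(table["trial_id"].to_numpy(), return_inverse=True)
    assessors, j = np.unique(table["assessor_id"].to_numpy(), return_inverse=True)
    y = table["mean"].to_numpy(dtype=float)
    if trials.size < 3:
        raise ValidationError("need at least 3 trials")
    if assessors.size < 2:
        raise ValidationError("need at least 2 assessors (layout unidentifiable)")
    per_trial = np.bincount(g)
    if (per_trial < 2).any():
        bad = trials[per_trial < 2]
        raise ValidationError(f"every trial needs >= 2 assessments; short: {list(bad)}")
    X = np.zeros((y.size, assessors.size))
    X[np.arange(y.size), j] = 1.0
    return y, X, g, per_trial.astype(float), trials, assessors


def _profile(lam: float, y, X, g, sizes):
    """Profile negative log-likelihood at variance ratio lam, with the GLS
    fit done by fractional group-demeaning (Woodbury on I + lam J)."""
    w = 1.0 - 1.0 / np.sqrt(1.0 + lam * sizes)  # per-group shrink fraction
    ybar = np.bincount(g, weights=y) / sizes
    yt = y - w[g] * ybar[g]
    xbar = np.vstack(
        [np.bincount(g, weights=X[:, c]) / sizes for c in range(X.shape[1])]
    ).T
    Xt = X - w[g][:, None] * xbar[g]
    coef, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
    rss = float(((yt - Xt @ coef) ** 2).sum())
    n = y.size
    sigma2 = rss / n
    if sigma2 < 1e-14:
        return -np.inf, coef, 0.0, rss
    nll = 0.5 * (
        n * np.log(2.0 * np.pi * sigma2) + np.log1p(lam * sizes).sum() + n
    )
    return nll, coef, sigma2, rss


def fit_mixed(table: pd.DataFrame) -> MixedFitResult:
    """Maximum-likelihood fit of the assessor-fixed, trial-random model.

    Variance estimates may sit on the zero boundary (they are clipped there
    rather than allowed to go negative).
    """
    y, X, g, sizes, trials, assessors = _prepare(table)
    return _fit_prepared(y, X, g, sizes, assessors)


def _fit_prepared(y, X, g, sizes, assessors=None) -> MixedFitResult:
    names = assessors if assessors is not None else range(X.shape[1])
    if float(np.var(y)) < 1e-14:
        coef = np.full(X.shape[1], float(y[0]))
        return MixedFitResult(
            {str(a): float(c) for a, c in zip(names, coef)}, 0.0, 0.0, float("inf")
        )
    # sigma_resid = 0 boundary: the within-group (lam -> inf) fit is exact
    ybar = np.bincount(g, weights=y) / sizes
    xbar = np.vstack(
        [np.bincount(g, weights=X[:, c]) / sizes for c in range(X.shape[1])]
    ).T
    coef_w, *_ = np.linalg.lstsq(X - xbar[g], y - ybar[g], rcond=None)
    rss_w = float((((y - ybar[g]) - (X - xbar[g]) @ coef_w) ** 2).sum())
    if rss_w / y.size < 1e-14:
        means = np.bincount(g, weights=y - X @ coef_w) / sizes
        means = means - means.mean()
        return MixedFitResult(
            {str(a): float(c) for a, c in zip(names, coef_w)},
            float(np.var(means)),
            0.0,
            float("inf"),
        )
    nll0, coef0, sig0, rss0 = _profile(0.0, y, X, g, sizes)
    res = minimize_scalar(
        lambda psi: _profile(float(np.exp(psi)), y, X, g, sizes)[0],
        bounds=(-_PSI_MAX, _PSI_MAX),
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam_hat = float(np.exp(res.x))
    nll1, coef1, sig1, rss1 = _profile(lam_hat, y, X, g, sizes)
    if nll0 <= nll1:
        lam_hat, nll, coef, sigma2 = 0.0, nll0, coef0, sig0
    else:
        nll, coef, sigma2 = nll1, coef1, sig1
    if lam_hat < 1e-8:
        lam_hat = 0.0
    if not np.isfinite(nll):
        # perfect fit: residual variance collapses to zero
        sigma2 = 0.0
    return MixedFitResult(
        assessor_effects={str(a): float(c) for a, c in zip(names, coef)},
        sigma2_trial=lam_hat * sigma2,
        sigma2_resid=sigma2,
        loglik=-nll,
    )


def _icc(fit: MixedFitResult) -> float:
    total = fit.sigma2_trial + fit.sigma2_resid
    if total <= 0:
        return 0.0
    return fit.sigma2_trial / total


def icc_with_ci(
    table: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> IccResult:
    """ICC point estimate with a percentile parametric-bootstrap 95% CI.

    Bootstrap datasets keep the observed (trial, assessor) layout and the
    fitted assessor effects, redrawing trial effects and residuals from the
    fitted variances; each is refit by the same profile-likelihood routine.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    y, X, g, sizes, trials, assessors = _prepare(table)
    fit = _fit_prepared(y, X, g, sizes, assessors)
    icc = _icc(fit)
    if fit.sigma2_trial == 0.0 and fit.sigma2_resid == 0.0:
        return IccResult(0.0, (0.0, 0.0), 0.0, 0.0, degenerate=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    coef = np.array([fit.assessor_effects[str(a)] for a in assessors])
    fixed_part = X @ coef
    sd_u = np.sqrt(fit.sigma2_trial)
    sd_e = np.sqrt(fit.sigma2_resid)
    G = sizes.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        u = rng.normal(0.0, sd_u, G)
        yb = fixed_part + u[g] + rng.normal(0.0, sd_e, y.size)
        boots[b] = _icc(_fit_prepared(yb, X, g, sizes))
    lo, hi = np.quantile(boots, [0.025, 0.975])
    return IccResult(
        icc=float(icc),
        ci=(float(lo), float(hi)),
        sigma2_trial=fit.sigma2_trial,
        sigma2_resid=fit.sigma2_resid,
    )
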