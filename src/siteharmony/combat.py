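"""Empirical-Bayes ComBat harmonization of site effects in mean and variance.

The model per feature v is

    y_ijv = alpha_v + X_ij . beta_v + gamma_iv + delta_iv * eps_ijv,

with site i, subject j, covariate design X, additive site effect gamma_iv and
multiplicative site effect delta_iv.  Site effects are estimated per site and
feature, then shrunk toward site-level priors shared across features —
a normal prior on gamma and an inverse-gamma prior on delta^2 — either with
parametric method-of-moments hyperparameters and a coupled fixed-point
iteration, or nonparametrically by Monte-Carlo (likelihood-weighted) averaging
over the other features' raw estimates.

Identifiability follows the reference convention: the sample-size-weighted sum
of site effects is zero, so the grand intercept alpha_v is the weighted mean
of per-site means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import FeatureMatrix, HarmonizationError, ValidatedDemographics
from ._parallel import parallel_map

EB_CONV_TOL = 1e-4
EB_MAX_ITER = 100


@dataclass
class CombatFit:
    """Fitted ComBat parameters, sufficient to reproduce the output."""

    alpha_v: np.ndarray          # (p,) grand intercept per feature
    beta_v: np.ndarray           # (q, p) covariate coefficients
    sigma_v: np.ndarray          # (p,) pooled residual SD
    gamma_hat: np.ndarray        # (n_site, p) raw location estimates
    delta2_hat: np.ndarray       # (n_site, p) raw scale estimates
    gamma_star: np.ndarray       # (n_site, p) EB-shrunk location
    delta2_star: np.ndarray      # (n_site, p) EB-shrunk scale
    hyper: dict                  # per-site prior parameters (parametric mode)
    mode: str                    # parametric | nonparametric
    adjusted: bool
    site_order: list
    covariate_names: list


def _design(demographics: ValidatedDemographics, adjusted: bool,
            adjust_vars=None) -> tuple[np.ndarray, np.ndarray, list]:
    """Site one-hot block plus (optionally) covariates; no global intercept."""
    site_block = demographics.site_design()
    if adjusted:
        X_cov, names = demographics.covariate_design(adjust_vars)
    else:
        X_cov, names = np.empty((demographics.n_subjects, 0)), []
    return site_block, X_cov, names


def standardize_features(Y: FeatureMatrix, demographics: ValidatedDemographics,
                         adjusted: bool = False, adjust_vars=None):
    """Least-squares fit of site + covariate effects, then per-feature scaling.

    Returns the standardized matrix Z = (Y - alpha - X.beta) / sigma and a
    partial :class:`CombatFit` holding alpha, beta, sigma and the raw per-site
    estimates.  Z has weighted zero mean and unit pooled variance per feature.
    """
    values = Y.values  # (n, p)
    n, p = values.shape
    zero_var = np.flatnonzero(values.std(axis=0) == 0)
    if zero_var.size:
        raise HarmonizationError(
            f"zero-variance feature(s) at index {zero_var[:10].tolist()}: cannot standardize"
        )
    site_block, X_cov, cov_names = _design(demographics, adjusted, adjust_vars)
    design = np.hstack([site_block, X_cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise HarmonizationError(
            "rank-deficient design: a covariate is perfectly confounded with site"
        )
    n_site = site_block.shape[1]
    sizes = site_block.sum(axis=0)  # subjects per site

    B_hat = np.linalg.solve(design.T @ design, design.T @ values)  # (n_site+q, p)
    site_coef = B_hat[:n_site]
    beta = B_hat[n_site:]

    # weighted grand intercept; residual variance pooled over all subjects
    alpha = (sizes / n) @ site_coef
    fitted_full = design @ B_hat
    sigma2 = ((values - fitted_full) ** 2).sum(axis=0) / n
    sigma = np.sqrt(sigma2)
    if np.any(sigma == 0):
        idx = np.flatnonzero(sigma == 0)
        raise HarmonizationError(
            f"feature(s) {idx[:10].tolist()} have zero residual variance; cannot standardize"
        )

    stand_mean = alpha[None, :] + X_cov @ beta  # (n, p)
    Z = (values - stand_mean) / sigma[None, :]

    codes = demographics.site_codes()
    gamma_hat = np.vstack([Z[codes == i].mean(axis=0) for i in range(n_site)])
    delta2_hat = np.vstack([Z[codes == i].var(axis=0, ddof=1) for i in range(n_site)])

    fit = CombatFit(
        alpha_v=alpha, beta_v=beta, sigma_v=sigma,
        gamma_hat=gamma_hat, delta2_hat=delta2_hat,
        gamma_star=gamma_hat.copy(), delta2_star=delta2_hat.copy(),
        hyper={}, mode="raw", adjusted=adjusted,
        site_order=list(demographics.site_order), covariate_names=cov_names,
    )
    return Z, fit


# ---------------------------------------------------------------------------
# parametric empirical Bayes

def _aprior(delta2: np.ndarray) -> float:
    m, s2 = delta2.mean(), delta2.var(ddof=1)
    return (2 * s2 + m ** 2) / s2


def _bprior(delta2: np.ndarray) -> float:
    m, s2 = delta2.mean(), delta2.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _parametric_site(z_site: np.ndarray, g_hat: np.ndarray, d2_hat: np.ndarray):
    """Coupled posterior fixed-point updates for one site (all features)."""
    n = z_site.shape[0]
    g_bar = g_hat.mean()
    t2 = g_hat.var(ddof=1)
    if t2 == 0 or d2_hat.var(ddof=1) == 0:
        # degenerate prior (all features identical within the site):
        # nothing to borrow across features, keep the raw estimates
        return g_hat.copy(), d2_hat.copy(), dict(
            gamma_bar=g_bar, tau2=t2, a_prior=np.nan, b_prior=np.nan)
    a = _aprior(d2_hat)
    b = _bprior(d2_hat)
    g_old, d_old = g_hat.copy(), d2_hat.copy()
    converged = False
    for _ in range(EB_MAX_ITER):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((z_site - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(np.abs((g_new - g_old) / g_old).max(),
                     np.abs((d_new - d_old) / d_old).max())
        g_old, d_old = g_new, d_new
        if change < EB_CONV_TOL:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"parametric EB did not converge within {EB_MAX_ITER} iterations; "
            "returning best iterate", UserWarning,
        )
    return g_old, d_old, dict(gamma_bar=g_bar, tau2=t2, a_prior=a, b_prior=b)


# ---------------------------------------------------------------------------
# nonparametric empirical Bayes (Monte-Carlo integration across features)

def _nonparametric_feature(v: int, z_site: np.ndarray, g_hat: np.ndarray,
                           d2_hat: np.ndarray) -> tuple[float, float]:
    """Likelihood-weighted average of the *other* features' raw estimates."""
    z = z_site[:, v]
    n = z.shape[0]
    g = np.delete(g_hat, v)
    d2 = np.delete(d2_hat, v)
    resid2 = (z[:, None] - g[None, :]) ** 2  # (n, p-1)
    LH = (1.0 / np.sqrt(2 * np.pi * d2)) ** n * np.exp(-resid2.sum(axis=0) / (2 * d2))
    LH = np.where(np.isfinite(LH), LH, 0.0)
    total = LH.sum()
    if total <= 0:
        # all weights underflow: fall back to the raw estimate
        return float(g_hat[v]), float(d2_hat[v])
    return float((g * LH).sum() / total), float((d2 * LH).sum() / total)


def estimate_eb(Z: np.ndarray, demographics: ValidatedDemographics,
                mode: str = "parametric", workers: int = 0):
    """EB-shrunk (gamma_star, delta2_star) per site and feature.

    Borrows strength across features; requires p >= 2.  The nonparametric
    route is parallelizable over features with worker-invariant results.
    """
    if mode not in ("parametric", "nonparametric"):
        raise HarmonizationError(f"unknown EB mode {mode!r}")
    n_site = len(demographics.site_order)
    p = Z.shape[1]
    if p < 2:
        raise HarmonizationError("empirical Bayes needs at least 2 features")
    codes = demographics.site_codes()
    gamma_hat = np.vstack([Z[codes == i].mean(axis=0) for i in range(n_site)])
    delta2_hat = np.vstack([Z[codes == i].var(axis=0, ddof=1) for i in range(n_site)])
    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    hyper = {}
    for i in range(n_site):
        z_site = Z[codes == i]
        if mode == "parametric":
            g, d, h = _parametric_site(z_site, gamma_hat[i], delta2_hat[i])
            gamma_star[i], delta2_star[i] = g, d
            hyper[demographics.site_order[i]] = h
        else:
            results = parallel_map(
                lambda v: _nonparametric_feature(v, z_site, gamma_hat[i], delta2_hat[i]),
                range(p), workers,
            )
            gamma_star[i] = [r[0] for r in results]
            delta2_star[i] = [r[1] for r in results]
    return gamma_star, delta2_star, hyper


def combat_harmonize(Y: FeatureMatrix, demographics: ValidatedDemographics,
                     mode: str = "parametric", adjusted: bool = False,
                     adjust_vars=None, workers: int = 0):
    """Remove site effects in mean and variance; keep covariate effects.

    Y_harm = sigma_v * (Z - gamma_star) / sqrt(delta2_star) + alpha_v + X.beta_v
    """
    if len(demographics.site_order) < 2:
        raise HarmonizationError("ComBat requires at least 2 sites")
    Z, fit = standardize_features(Y, demographics, adjusted, adjust_vars)
    gamma_star, delta2_star, hyper = estimate_eb(Z, demographics, mode, workers)
    fit.gamma_star, fit.delta2_star = gamma_star, delta2_star
    fit.hyper, fit.mode = hyper, mode

    codes = demographics.site_codes()
    g_sub = gamma_star[codes]          # (n, p)
    # floor protects the degenerate zero-within-site-variance edge: the
    # numerator is exactly zero there, so the scaled term vanishes cleanly
    d_sub = np.maximum(delta2_star[codes], 1e-300)
    _, X_cov, _ = _design(demographics, adjusted, adjust_vars)
    stand_mean = fit.alpha_v[None, :] + X_cov @ fit.beta_v
    values = fit.sigma_v[None, :] * (Z - g_sub) / np.sqrt(d_sub) + stand_mean
    return Y.with_values(values), fit
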