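"""Site-effect removal by fixed-effect GLM or random-intercept mixed model.

Both treat site as additive: the GLM estimates per-site offsets (sum-to-zero
coded, so the grand mean is preserved) by least squares and subtracts them;
the LMM treats site as a random intercept u_i ~ N(0, sigma_u^2) fitted by
REML and subtracts the predicted (BLUP) intercepts.  Covariate effects stay
in the data either way.  Features are fitted independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .core import FeatureMatrix, HarmonizationError, ValidatedDemographics
from ._parallel import parallel_map


@dataclass
class LinearFit:
    model_kind: str              # glm | lmm
    intercept: np.ndarray        # (p,)
    beta: np.ndarray             # (q, p)
    site_effects: np.ndarray     # (n_site, p): fixed estimates or BLUPs
    variance_components: np.ndarray | None  # (2, p) = (sigma_u2, sigma_e2) for lmm
    site_order: list
    covariate_names: list


def _covariates(demographics: ValidatedDemographics, adjust_vars):
    X_cov, names = demographics.covariate_design(adjust_vars)
    return X_cov, names


def glm_harmonize(Y: FeatureMatrix, demographics: ValidatedDemographics,
                  adjust_vars=None, adjusted: bool = True):
    """Subtract least-squares fixed site effects (sum-to-zero coded)."""
    values = Y.values
    n, p = values.shape
    n_site = len(demographics.site_order)
    codes = demographics.site_codes()

    # sum-to-zero (effect) coding: last site = -(sum of others)
    S = np.zeros((n, n_site - 1))
    for i in range(n_site - 1):
        S[codes == i, i] = 1.0
    S[codes == n_site - 1, :] = -1.0

    if adjusted:
        X_cov, cov_names = _covariates(demographics, adjust_vars)
    else:
        X_cov, cov_names = np.empty((n, 0)), []
    design = np.hstack([np.ones((n, 1)), X_cov, S])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise HarmonizationError(
            "rank-deficient design: a covariate is perfectly confounded with site")
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    q = X_cov.shape[1]
    site_coef = coef[1 + q:]                          # (n_site-1, p)
    site_full = np.vstack([site_coef, -site_coef.sum(axis=0)])  # sums to zero
    harmonized = values - site_full[codes]
    fit = LinearFit("glm", coef[0], coef[1:1 + q], site_full, None,
                    list(demographics.site_order), cov_names)
    return Y.with_values(harmonized), fit


def _lmm_feature(y, X_fixed, groups):
    model = sm.MixedLM(y, X_fixed, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    if not result.converged:
        raise RuntimeError("non-convergence")
    sigma_u2 = float(np.asarray(result.cov_re).ravel()[0])
    sigma_e2 = float(result.scale)
    fe = np.asarray(result.fe_params, dtype=float)
    if sigma_u2 <= 1e-12 * sigma_e2:
        # boundary solution: no between-site variance, BLUPs are exactly zero
        u = {g: 0.0 for g in np.unique(groups)}
        return u, 0.0, sigma_e2, fe
    re = result.random_effects
    u = {g: float(np.asarray(v).ravel()[0]) for g, v in re.items()}
    return u, sigma_u2, sigma_e2, fe


def lmm_harmonize(Y: FeatureMatrix, demographics: ValidatedDemographics,
                  adjust_vars=None, adjusted: bool = True, workers: int = 0):
    """Subtract REML-predicted random site intercepts (BLUPs) per feature.

    With only 2 sites the between-site variance component is weakly
    identified; a warning is emitted but the run completes.  Features whose
    REML optimizer fails fall back to the GLM fixed-effect estimate.
    """
    if len(demographics.site_order) < 3:
        warnings.warn(
            "fewer than 3 sites: the site variance component is weakly "
            "identified; interpret LMM output with caution", UserWarning)
    values = Y.values
    n, p = values.shape
    if adjusted:
        X_cov, cov_names = _covariates(demographics, adjust_vars)
    else:
        X_cov, cov_names = np.empty((n, 0)), []
    X_fixed = np.hstack([np.ones((n, 1)), X_cov])
    groups = demographics.site.to_numpy()
    codes = demographics.site_codes()
    site_order = list(demographics.site_order)

    glm_out, glm_fit = glm_harmonize(Y, demographics, adjust_vars, adjusted)

    def fit_one(v):
        try:
            return _lmm_feature(values[:, v], X_fixed, groups)
        except Exception:
            return None

    results = parallel_map(fit_one, range(p), workers)

    site_effects = np.zeros((len(site_order), p))
    varcomp = np.zeros((2, p))
    intercept = np.zeros(p)
    beta = np.zeros((X_cov.shape[1], p))
    harmonized = values.copy()
    fallbacks = []
    for v, res in enumerate(results):
        if res is None:
            fallbacks.append(v)
            site_effects[:, v] = glm_fit.site_effects[:, v]
            intercept[v] = glm_fit.intercept[v]
            beta[:, v] = glm_fit.beta[:, v]
            varcomp[:, v] = np.nan
        else:
            u, s_u2, s_e2, fe = res
            site_effects[:, v] = [u.get(s, 0.0) for s in site_order]
            intercept[v] = fe[0]
            beta[:, v] = fe[1:]
            varcomp[:, v] = (s_u2, s_e2)
        harmonized[:, v] = values[:, v] - site_effects[codes, v]
    if fallbacks:
        warnings.warn(
            f"REML failed to converge for feature(s) {fallbacks[:10]}; "
            "fell back to the GLM site-effect estimate", UserWarning)
    fit = LinearFit("lmm", intercept, beta, site_effects, varcomp,
                    site_order, cov_names)
    return Y.with_values(harmonized), fit
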