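"""ComBat: standardization, empirical-Bayes shrinkage, harmonization."""

import numpy as np
import pandas as pd
import pytest

from siteharmony import (FeatureMatrix, HarmonizationError, combat_harmonize,
                         estimate_eb, mean_site_f, standardize_features,
                         validate_demographics)
from siteharmony.synthetic import SyntheticSpec, generate_multisite_dataset


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(values, list(range(len(values))),
                         list(range(values.shape[1])), "table")


def _demo(sites, **cols):
    table = pd.DataFrame({"SiteName": sites, **cols})
    return validate_demographics(table, len(sites))


class TestStandardize:
    def test_intercept_is_weighted_site_mean(self):
        # equal-n sites at levels 1 and 3 -> grand intercept 2 per feature
        Y = _matrix([[1, 1], [1.2, 0.8], [3, 3], [3.2, 2.8]])
        demo = _demo(["s1", "s1", "s2", "s2"])
        _, fit = standardize_features(Y, demo)
        assert fit.alpha_v == pytest.approx([2.1, 1.9], abs=1e-12)

    def test_zero_variance_feature_rejected(self):
        Y = _matrix([[1, 5], [2, 5], [3, 5], [4, 5]])
        demo = _demo(["a", "a", "b", "b"])
        with pytest.raises(HarmonizationError, match="zero-variance.*\\[1\\]"):
            standardize_features(Y, demo)

    def test_covariate_coefficient_recovered_noise_free(self):
        # oracle: solve the same normal equations independently
        rng = np.random.default_rng(3)
        age = rng.uniform(20, 60, 20)
        sites = ["a"] * 10 + ["b"] * 10
        offsets = np.where(np.array(sites) == "a", -1.0, 1.0)
        Y = np.outer(0.5 * age + offsets, np.ones(4))
        Y += rng.standard_normal((20, 4)) * 1e-9  # break exact zero variance
        demo = _demo(sites, Age=age)
        _, fit = standardize_features(_matrix(Y), demo, adjusted=True)
        assert fit.beta_v[0] == pytest.approx(0.5, abs=1e-6)

    def test_confounded_covariate_rejected(self):
        sites = ["a", "a", "b", "b"]
        indicator = [1.0, 1.0, 0.0, 0.0]
        Y = _matrix(np.random.default_rng(0).standard_normal((4, 3)))
        with pytest.raises(HarmonizationError, match="confounded"):
            standardize_features(Y, _demo(sites, Ind=indicator), adjusted=True)

    def test_standardized_matrix_zero_weighted_mean_unit_residual_variance(
            self, two_site_matrix):
        Y, demo = two_site_matrix
        Z, fit = standardize_features(Y, demo)
        sizes = np.array(list(demo.site_sizes().values()), dtype=float)
        codes = demo.site_codes()
        site_means = np.vstack([Z[codes == i].mean(axis=0) for i in range(2)])
        # weighted mean of site effects is zero by the identifiability constraint
        assert np.abs((sizes / sizes.sum()) @ site_means).max() < 1e-10
        # pooled residual variance (around the site fit) is one
        resid = Z - site_means[codes]
        assert np.allclose((resid ** 2).mean(axis=0), 1.0, atol=1e-10)


def _brute_force_parametric(z_site, g_hat, d2_hat, iters=5000):
    """Independent fixed-point oracle, iterated far past convergence."""
    n = z_site.shape[0]
    g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
    m, s2 = d2_hat.mean(), d2_hat.var(ddof=1)
    a = (2 * s2 + m ** 2) / s2
    b = (m * s2 + m ** 3) / s2
    g, d = g_hat.copy(), d2_hat.copy()
    for _ in range(iters):
        g = (t2 * n * g_hat + d * g_bar) / (t2 * n + d)
        d = (0.5 * ((z_site - g) ** 2).sum(axis=0) + b) / (n / 2 + a - 1)
    return g, d


class TestEmpiricalBayes:
    def test_parametric_matches_brute_force_fixed_point(self, two_site_matrix):
        Y, demo = two_site_matrix
        Z, _ = standardize_features(Y, demo)
        gamma_star, delta2_star, _ = estimate_eb(Z, demo, "parametric")
        codes = demo.site_codes()
        for i in range(2):
            z_site = Z[codes == i]
            g_hat = z_site.mean(axis=0)
            d2_hat = z_site.var(axis=0, ddof=1)
            g_ref, d_ref = _brute_force_parametric(z_site, g_hat, d2_hat)
            assert np.abs(gamma_star[i] - g_ref).max() < 1e-4
            assert np.abs(delta2_star[i] - d_ref).max() < 1e-4

    def test_parametric_shrinks_toward_site_prior_mean(self, two_site_matrix):
        Y, demo = two_site_matrix
        Z, _ = standardize_features(Y, demo)
        gamma_star, _, hyper = estimate_eb(Z, demo, "parametric")
        codes = demo.site_codes()
        for i, site in enumerate(demo.site_order):
            g_hat = Z[codes == i].mean(axis=0)
            g_bar = hyper[site]["gamma_bar"]
            lo = np.minimum(g_hat, g_bar) - 1e-12
            hi = np.maximum(g_hat, g_bar) + 1e-12
            assert np.all((gamma_star[i] >= lo) & (gamma_star[i] <= hi))

    def test_degenerate_identical_features_keep_raw_estimates(self):
        base = np.array([[0.0], [1.0], [5.0], [6.0]])
        Y = _matrix(np.hstack([base, base, base]) + [[0], [0], [0], [0]])
        demo = _demo(["a", "a", "b", "b"])
        Z, _ = standardize_features(Y, demo)
        gamma_star, delta2_star, _ = estimate_eb(Z, demo, "parametric")
        codes = demo.site_codes()
        for i in range(2):
            g_hat = Z[codes == i].mean(axis=0)
            assert gamma_star[i] == pytest.approx(g_hat, abs=1e-12)

    def test_nonparametric_invariant_to_workers(self, two_site_matrix):
        Y, demo = two_site_matrix
        Z, _ = standardize_features(Y, demo)
        g0, d0, _ = estimate_eb(Z, demo, "nonparametric", workers=0)
        g4, d4, _ = estimate_eb(Z, demo, "nonparametric", workers=4)
        assert np.array_equal(g0, g4) and np.array_equal(d0, d4)

    def test_single_feature_rejected(self, two_site_matrix):
        Y, demo = two_site_matrix
        Z, _ = standardize_features(Y, demo)
        with pytest.raises(HarmonizationError, match="at least 2 features"):
            estimate_eb(Z[:, :1], demo)


class TestCombatHarmonize:
    def test_pure_additive_shift_removed_in_no_noise_limit(self):
        # vanishing within-site noise: the shift is removed essentially exactly
        rng = np.random.default_rng(9)
        Y = np.tile(rng.standard_normal(8), (30, 1))
        Y += rng.standard_normal((30, 8)) * 1e-9
        Y[:15] += 2.5  # pure site shift
        demo = _demo(["a"] * 15 + ["b"] * 15)
        out, _ = combat_harmonize(_matrix(Y), demo, "parametric")
        site_means = [out.values[:15].mean(axis=0), out.values[15:].mean(axis=0)]
        assert np.abs(site_means[0] - site_means[1]).max() < 1e-8

    def test_single_site_rejected(self):
        Y = _matrix(np.random.default_rng(0).standard_normal((6, 3)))
        table = pd.DataFrame({"SiteName": ["only"] * 6})
        with pytest.raises(HarmonizationError):
            demo = validate_demographics(table, 6)
            combat_harmonize(Y, demo)

    def test_site_anova_f_near_null_after_harmonization(self, three_site_dataset):
        Y, demo, _ = three_site_dataset
        codes = demo.site_codes()
        assert mean_site_f(Y.values, codes) > 5
        out, _ = combat_harmonize(Y, demo, "parametric")
        # in-sample removal pushes residual site differences below the null
        # expectation of 1; the essential check is the collapse from >>1
        assert mean_site_f(out.values, codes) < 1.5

    def test_covariate_effect_preserved(self):
        spec = SyntheticSpec(
            n_sites=3, n_per_site=40, n_features=60, gamma=(-1, 0, 1),
            gamma_tau=0.3, delta=(0.8, 1.0, 1.25),
            covariates={"Age": {"kind": "normal", "mean": 40.0, "sd": 10.0}},
            beta={"Age": 0.5}, seed=21)
        Y, demo, _ = generate_multisite_dataset(spec)
        out, _ = combat_harmonize(Y, demo, "parametric", adjusted=True)
        age = demo.table["Age"].to_numpy(float)
        X = np.column_stack([np.ones(len(age)), age])
        beta = np.linalg.lstsq(X, out.values, rcond=None)[0][1]
        assert abs(beta.mean() - 0.5) < 0.05

    def test_idempotent_up_to_tolerance(self, three_site_dataset):
        Y, demo, _ = three_site_dataset
        once, _ = combat_harmonize(Y, demo, "parametric")
        twice, _ = combat_harmonize(once, demo, "parametric")
        sd = once.values.std(axis=0)
        # the second pass re-shrinks sampling noise; changes stay small
        assert (np.abs(twice.values - once.values) / sd).mean() < 0.05

    def test_nonparametric_removes_site_means(self, three_site_dataset):
        Y, demo, _ = three_site_dataset
        out, fit = combat_harmonize(Y, demo, "nonparametric")
        assert fit.mode == "nonparametric"
        assert mean_site_f(out.values, demo.site_codes()) < 2.0
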