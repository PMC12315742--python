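"""Fixed-effect GLM and random-intercept LMM site-effect removal."""

import numpy as np
import pandas as pd
import pytest

from siteharmony import (FeatureMatrix, HarmonizationError, glm_harmonize,
                         lmm_harmonize, validate_demographics)
from siteharmony.synthetic import SyntheticSpec, generate_multisite_dataset


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(values, list(range(len(values))),
                         list(range(values.shape[1])), "table")


def _demo(sites, **cols):
    table = pd.DataFrame({"SiteName": sites, **cols})
    return validate_demographics(table, len(sites))


def _icc(values, codes, n_sites, n_per):
    iccs = []
    for v in range(values.shape[1]):
        groups = [values[codes == i, v] for i in range(n_sites)]
        grand = values[:, v].mean()
        msb = n_per * sum((g.mean() - grand) ** 2 for g in groups) / (n_sites - 1)
        msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (len(values) - n_sites)
        iccs.append((msb - msw) / (msb + (n_per - 1) * msw))
    return float(np.mean(iccs))


class TestGLM:
    def test_noise_free_offsets_removed(self):
        Y = np.full((20, 3), 5.0)
        Y[:10] -= 1.0
        Y[10:] += 1.0
        Y += np.random.default_rng(0).standard_normal((20, 3)) * 1e-12
        demo = _demo(["a"] * 10 + ["b"] * 10)
        out, fit = glm_harmonize(_matrix(Y), demo)
        assert np.abs(out.values - 5.0).max() < 1e-10
        assert np.abs(fit.site_effects.sum(axis=0)).max() < 1e-10

    def test_age_effect_retained(self):
        rng = np.random.default_rng(17)
        age = rng.uniform(20, 60, 90)
        sites = np.repeat(["a", "b", "c"], 30)
        offsets = {"a": -2.0, "b": 0.0, "c": 2.0}
        Y = (0.5 * age[:, None] + np.array([offsets[s] for s in sites])[:, None]
             + rng.standard_normal((90, 5)))
        demo = _demo(sites, Age=age)
        out, _ = glm_harmonize(_matrix(Y), demo, adjust_vars=["Age"])
        X = np.column_stack([np.ones(90), age])
        beta = np.linalg.lstsq(X, out.values, rcond=None)[0][1]
        se = 1.0 / (age.std() * np.sqrt(90))
        assert np.all(np.abs(beta - 0.5) < 2 * se + 0.05)

    def test_covariate_equal_to_site_indicator_rejected(self):
        demo = _demo(["a"] * 5 + ["b"] * 5, Ind=[1.0] * 5 + [0.0] * 5)
        Y = _matrix(np.random.default_rng(0).standard_normal((10, 2)))
        with pytest.raises(HarmonizationError, match="confounded"):
            glm_harmonize(Y, demo, adjust_vars=["Ind"])

    def test_grand_mean_preserved(self, three_site_dataset):
        Y, demo, _ = three_site_dataset
        out, _ = glm_harmonize(Y, demo, adjusted=False)
        assert np.abs(out.values.mean(axis=0) - Y.values.mean(axis=0)).max() < 1e-8

    def test_balanced_design_site_means_equalized(self, three_site_dataset):
        Y, demo, _ = three_site_dataset
        out, _ = glm_harmonize(Y, demo, adjusted=False)
        codes = demo.site_codes()
        means = np.vstack([out.values[codes == i].mean(axis=0) for i in range(3)])
        assert np.abs(means - means.mean(axis=0)).max() < 1e-8


class TestLMM:
    def test_null_random_effect_leaves_data_nearly_unchanged(self):
        spec = SyntheticSpec(n_sites=4, n_per_site=25, n_features=8,
                             gamma=(0.0, 0.0, 0.0, 0.0), delta=(1.0,) * 4,
                             seed=3)
        Y, demo, _ = generate_multisite_dataset(spec)
        out, fit = lmm_harmonize(Y, demo, adjusted=False)
        sd = Y.values.std(axis=0)
        assert (np.abs(out.values - Y.values) / sd).mean() < 0.1
        assert np.nanmean(fit.variance_components[0]) < 0.1

    def test_site_icc_removed_six_sites(self):
        rng_gamma = np.random.default_rng(31).normal(0, 1, 6)
        spec = SyntheticSpec(n_sites=6, n_per_site=30, n_features=12,
                             gamma=tuple(rng_gamma), delta=(1.0,) * 6, seed=31)
        Y, demo, _ = generate_multisite_dataset(spec)
        codes = demo.site_codes()
        assert _icc(Y.values, codes, 6, 30) > 0.1
        out, _ = lmm_harmonize(Y, demo, adjusted=False)
        assert _icc(out.values, codes, 6, 30) < 0.01

    def test_two_sites_warns_but_completes(self):
        rng = np.random.default_rng(5)
        Y = _matrix(rng.standard_normal((30, 3)))
        demo = _demo(["a"] * 15 + ["b"] * 15)
        with pytest.warns(UserWarning, match="fewer than 3 sites"):
            out, _ = lmm_harmonize(Y, demo, adjusted=False)
        assert out.values.shape == (30, 3)

    def test_blups_shrunk_relative_to_glm(self):
        spec = SyntheticSpec(n_sites=5, n_per_site=20, n_features=10,
                             gamma=(-1.0, -0.5, 0.0, 0.5, 1.0),
                             delta=(1.0,) * 5, seed=19)
        Y, demo, _ = generate_multisite_dataset(spec)
        _, glm_fit = glm_harmonize(Y, demo, adjusted=False)
        _, lmm_fit = lmm_harmonize(Y, demo, adjusted=False)
        # balanced design: predicted intercepts shrink toward zero
        ok = np.abs(lmm_fit.site_effects) <= np.abs(glm_fit.site_effects) + 1e-6
        assert ok.mean() > 0.95
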