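"""SMA: subgrouping, target-site ranking, MMD, affine alignment."""

import numpy as np
import pandas as pd
import pytest

from siteharmony import (FeatureMatrix, HarmonizationError, SubgroupSpec,
                         assign_subgroups, mmd_statistic,
                         recommend_target_site, sma_harmonize,
                         validate_demographics)


def _demo(sites, **cols):
    table = pd.DataFrame({"SiteName": sites, **cols})
    return validate_demographics(table, len(sites))


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(values, list(range(len(values))),
                         list(range(values.shape[1])), "table")


class TestSubgroups:
    def test_continuous_zcut_half_open_upper_inclusive(self):
        demo = _demo(["a", "a", "b", "b"], Age=[30.0, 40.0, 55.0, 20.0])
        spec = SubgroupSpec(["Age"], {"Age": [40.0]})
        labels, _ = assign_subgroups(demo, spec)
        assert labels == [(0,), (0,), (1,), (0,)]

    def test_categorical_zcut_zero_strata_by_value(self):
        demo = _demo(["a", "a", "b", "b"], Sex=["M", "F", "M", "F"])
        labels, occ = assign_subgroups(demo, SubgroupSpec(["Sex"], {"Sex": 0}))
        assert labels == [(0,), (1,), (0,), (1,)]
        assert occ[("a", (0,))] == 1 and occ[("b", (1,))] == 1

    def test_cartesian_product_of_strata(self):
        demo = _demo(["a"] * 4 + ["b"] * 4,
                     Sex=["M", "F"] * 4, Age=[30, 30, 50, 50] * 2)
        spec = SubgroupSpec(["Sex", "Age"], {"Sex": 0, "Age": [40.0]})
        labels, _ = assign_subgroups(demo, spec)
        assert len(set(labels)) <= 4

    def test_non_ascending_cuts_rejected(self):
        with pytest.raises(HarmonizationError, match="ascending"):
            SubgroupSpec(["Age"], {"Age": [50.0, 40.0]})

    def test_unknown_variable(self):
        demo = _demo(["a", "a", "b", "b"])
        with pytest.raises(HarmonizationError, match="unknown subgroup variable"):
            assign_subgroups(demo, SubgroupSpec(["Height"], {"Height": 0}))


class TestTargetSite:
    def test_size_times_coverage_score(self):
        sites = ["A"] * 100 + ["B"] * 200
        ages = list(np.linspace(20, 60, 100)) + [30.0] * 200
        demo = _demo(sites, Age=ages)
        _, occ = assign_subgroups(
            demo, SubgroupSpec(["Age"], {"Age": [25.0, 35.0, 45.0, 55.0]}))
        # A covers all 5 bins (score 100), B covers 1 of 5 (score 40)
        assert recommend_target_site(demo, occ)[0] == "A"

    def test_without_subgroups_ranked_by_size(self):
        demo = _demo(["s1"] * 5 + ["s2"] * 9 + ["s3"] * 2)
        assert recommend_target_site(demo) == ["s2", "s1", "s3"]

    def test_ties_break_by_first_appearance(self):
        demo = _demo(["x"] * 4 + ["y"] * 4)
        assert recommend_target_site(demo) == ["x", "y"]


class TestMMD:
    def test_identical_samples_zero(self):
        x = np.random.default_rng(0).standard_normal(15)
        assert mmd_statistic(x, x.copy()) < 1e-12

    def test_two_point_hand_computed_value(self):
        # k(0,0)=k(1,1)=1, cross term exp(-1/2): MMD^2 = 2 - 2 exp(-0.5)
        value = mmd_statistic(np.array([0.0]), np.array([1.0]), bandwidth=1.0)
        assert value == pytest.approx(2 - 2 * np.exp(-0.5), abs=1e-12)

    def test_distant_samples_approach_two(self):
        a = np.zeros(10)
        b = np.full(10, 1e6)
        assert mmd_statistic(a, b, bandwidth=1.0) == pytest.approx(2.0, abs=1e-9)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(17)
        b = rng.standard_normal(13) + 0.5
        h = 0.8

        def k(x, y):
            return np.exp(-((x - y) ** 2) / (2 * h * h))

        brute = (
            sum(k(x, y) for x in a for y in a) / len(a) ** 2
            + sum(k(x, y) for x in b for y in b) / len(b) ** 2
            - 2 * sum(k(x, y) for x in a for y in b) / (len(a) * len(b))
        )
        assert mmd_statistic(a, b, bandwidth=h) == pytest.approx(brute, abs=1e-10)

    def test_empty_sample_rejected(self):
        with pytest.raises(HarmonizationError, match="non-empty"):
            mmd_statistic(np.array([]), np.array([1.0]))


class TestSmaHarmonize:
    def test_exact_affine_relation_inverted(self):
        rng = np.random.default_rng(2)
        tgt = rng.standard_normal((60, 2))
        src = tgt * 1.5 + 2.0
        Y = _matrix(np.vstack([src, tgt]))
        demo = _demo(["S"] * 60 + ["T"] * 60)
        out, tr = sma_harmonize(Y, demo, target_site="T")
        assert np.allclose(tr.scale["S"], 1 / 1.5, atol=1e-3)
        assert np.allclose(tr.shift["S"], -2 / 1.5, atol=2e-3)
        for v in range(2):
            post = mmd_statistic(out.values[:60, v], tgt[:, v])
            assert post < 1e-5

    def test_target_site_returned_bit_identical(self):
        rng = np.random.default_rng(8)
        Y = _matrix(rng.standard_normal((40, 3)))
        demo = _demo(["S"] * 20 + ["T"] * 20)
        out, tr = sma_harmonize(Y, demo, target_site="T")
        assert np.array_equal(out.values[20:], Y.values[20:])
        assert np.all(tr.scale["T"] == 1.0) and np.all(tr.shift["T"] == 0.0)

    def test_mmd_never_worse_than_moment_matching_start(self):
        rng = np.random.default_rng(12)
        src = rng.gamma(2.0, 1.5, size=(80, 2))
        tgt = rng.standard_normal((80, 2))
        Y = _matrix(np.vstack([src, tgt]))
        demo = _demo(["S"] * 80 + ["T"] * 80)
        out, tr = sma_harmonize(Y, demo, target_site="T")
        for v in range(2):
            s, t = src[:, v], tgt[:, v]
            a0 = t.std() / s.std()
            b0 = t.mean() - a0 * s.mean()
            h = None
            pre = mmd_statistic(a0 * s + b0, t)
            post = mmd_statistic(out.values[:80, v], t)
            assert post <= pre + 1e-12

    def test_auto_target_uses_recommendation(self):
        rng = np.random.default_rng(3)
        Y = _matrix(rng.standard_normal((30, 2)))
        demo = _demo(["small"] * 10 + ["big"] * 20)
        _, tr = sma_harmonize(Y, demo, target_site="auto")
        assert tr.target_site == "big"

    def test_absent_target_rejected(self):
        Y = _matrix(np.random.default_rng(0).standard_normal((10, 2)))
        demo = _demo(["a"] * 5 + ["b"] * 5)
        with pytest.raises(HarmonizationError, match="not present"):
            sma_harmonize(Y, demo, target_site="zzz")

    def test_tiny_source_site_rejected(self):
        Y = _matrix(np.random.default_rng(0).standard_normal((22, 2)))
        demo = _demo(["a"] * 2 + ["b"] * 20)
        with pytest.raises(HarmonizationError, match="< 3 subjects"):
            sma_harmonize(Y, demo, target_site="b")

    def test_subsampling_invariant_to_workers(self):
        rng = np.random.default_rng(6)
        group = np.array([0] * 14 + [1] * 6 + [0] * 6 + [1] * 14)
        Y = _matrix(rng.standard_normal((40, 2)) + group[:, None])
        demo = _demo(["S"] * 20 + ["T"] * 20, Group=[str(g) for g in group])
        spec = SubgroupSpec(["Group"], {"Group": 0})
        out0, _ = sma_harmonize(Y, demo, "subsampling", spec, "T",
                                n_subsamples=10, seed=3, workers=0)
        out4, _ = sma_harmonize(Y, demo, "subsampling", spec, "T",
                                n_subsamples=10, seed=3, workers=4)
        assert np.array_equal(out0.values, out4.values)
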