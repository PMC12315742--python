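"""Data-model contracts: demographics, masks, network vectorization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from siteharmony import (HarmonizationError, MaskSpec, apply_mask,
                         rebuild_network, unmask, validate_demographics,
                         vectorize_network)


def _demo_table(sites, **cols):
    return pd.DataFrame({"SiteName": sites, **cols})


class TestValidateDemographics:
    def test_types_covariates_by_parseability(self):
        table = _demo_table(["a", "a", "a", "b", "b", "b"],
                            Age=[30, 40, 50, 35, 45, 55],
                            Sex=["M", "F", "M", "F", "M", "F"])
        demo = validate_demographics(table, 6)
        assert demo.covariate_types == {"Age": "continuous", "Sex": "categorical"}
        assert demo.site_order == ["a", "b"]

    def test_missing_site_column(self):
        with pytest.raises(HarmonizationError, match="missing required column"):
            validate_demographics(pd.DataFrame({"Age": [1, 2]}), 2)

    def test_row_count_mismatch(self):
        table = _demo_table(["a", "a", "b", "b", "b"])
        with pytest.raises(HarmonizationError, match="5 rows but 6"):
            validate_demographics(table, 6)

    @pytest.mark.parametrize("sites, message", [
        (["a"] * 4, "2 distinct sites"),
        (["a", "a", "a", "b"], "too small"),
    ])
    def test_site_structure_errors(self, sites, message):
        with pytest.raises(HarmonizationError, match=message):
            validate_demographics(_demo_table(sites), len(sites))

    def test_missing_covariate_values_rejected(self):
        table = _demo_table(["a", "a", "b", "b"], Age=[1.0, None, 3.0, 4.0])
        with pytest.raises(HarmonizationError, match="missing values"):
            validate_demographics(table, 4)

    def test_site_coding_is_first_appearance_order(self):
        table = _demo_table(["z", "z", "a", "a", "z"])
        demo = validate_demographics(table, 5)
        assert demo.site_order == ["z", "a"]
        assert demo.site_codes().tolist() == [0, 0, 1, 1, 0]


class TestMasking:
    def test_mask_selects_count_of_ones(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((2, 2, 2), dtype=int)
        mask.ravel()[[0, 2, 3, 5, 7]] = 1
        stack = [rng.standard_normal((2, 2, 2)) for _ in range(3)]
        fm = apply_mask(stack, MaskSpec("volume", mask))
        assert fm.values.shape == (3, 5)

    def test_non_binary_mask_rejected(self):
        with pytest.raises(HarmonizationError, match="only 1s and 0s"):
            MaskSpec("volume", np.array([[0.5, 1.0], [0.0, 1.0]]))

    def test_no_mask_includes_everything_with_warning(self):
        stack = [np.ones((2, 2)) * i for i in range(2)]
        with pytest.warns(UserWarning, match="not recommended"):
            fm = apply_mask(stack, MaskSpec("none"))
        assert fm.n_features == 4

    def test_shape_mismatch(self):
        mask = MaskSpec("volume", np.ones((2, 2, 2), dtype=int))
        with pytest.raises(HarmonizationError, match="does not match"):
            apply_mask([np.zeros((3, 3, 3))] * 2, mask)

    def test_empty_mask(self):
        mask = MaskSpec("volume", np.zeros((2, 2, 2), dtype=int))
        with pytest.raises(HarmonizationError, match="zero cells"):
            apply_mask([np.zeros((2, 2, 2))] * 2, mask)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_mask_unmask_round_trip_exact(self, seed):
        rng = np.random.default_rng(seed)
        shape = (3, 2, 4)
        mask_arr = rng.integers(0, 2, size=shape)
        if mask_arr.sum() == 0:
            mask_arr.ravel()[0] = 1
        mask = MaskSpec("volume", mask_arr)
        stack = [rng.standard_normal(shape) for _ in range(3)]
        fm = apply_mask(stack, mask)
        rebuilt = unmask(fm, mask, shape)
        fm2 = apply_mask(rebuilt, mask)
        assert np.array_equal(fm.values, fm2.values)
        # fill value occupies everything outside the mask
        outside = ~mask.grid
        assert all(np.all(arr[outside] == 0.0) for arr in rebuilt)

    def test_unmask_feature_count_mismatch(self):
        mask = MaskSpec("volume", np.ones((2, 2), dtype=int))
        fm = apply_mask([np.zeros((2, 2))] * 2, mask)
        small_mask = MaskSpec("volume", np.eye(2, dtype=int))
        with pytest.raises(HarmonizationError, match="selects 2 cells"):
            unmask(fm, small_mask, (2, 2))


class TestNetworkVectorization:
    def test_upper_triangle_row_major(self):
        square = np.array([[1, 2, 3], [2, 4, 5], [3, 5, 6]], dtype=float)
        assert vectorize_network(square).tolist() == [2, 3, 5]

    @pytest.mark.parametrize("n, expected_len", [(1, 0), (4, 6), (7, 21)])
    def test_feature_count_is_n_choose_2(self, n, expected_len):
        square = np.zeros((n, n))
        assert vectorize_network(square).size == expected_len

    def test_non_square_rejected(self):
        with pytest.raises(HarmonizationError, match="square"):
            vectorize_network(np.zeros((2, 3)))

    def test_rebuild_writes_only_upper_triangle(self):
        mat = rebuild_network(np.array([2.0, 3.0, 5.0]), 3)
        assert mat.tolist() == [[0, 2, 3], [0, 0, 5], [0, 0, 0]]

    def test_rebuild_symmetric_option(self):
        mat = rebuild_network(np.array([2.0, 3.0, 5.0]), 3, output="symmetric")
        assert np.array_equal(mat, mat.T)
        assert mat[0, 1] == 2.0 and np.all(np.diag(mat) == 0)

    def test_length_mismatch(self):
        with pytest.raises(HarmonizationError, match="n\\(n-1\\)/2"):
            rebuild_network(np.zeros(5), 3)

    @given(st.integers(2, 8), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_vectorize_rebuild_round_trip(self, n, seed):
        rng = np.random.default_rng(seed)
        vec = rng.standard_normal(n * (n - 1) // 2)
        assert np.array_equal(vectorize_network(rebuild_network(vec, n)), vec)
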