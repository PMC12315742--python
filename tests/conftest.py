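import numpy as np
import pandas as pd
import pytest

from siteharmony import FeatureMatrix, validate_demographics
from siteharmony.synthetic import SyntheticSpec, generate_multisite_dataset


@pytest.fixture
def two_site_matrix():
    """Tiny 2-site dataset with an additive offset and an Age covariate."""
    rng = np.random.default_rng(11)
    n1, n2, p = 12, 14, 6
    age = rng.uniform(20, 60, n1 + n2)
    Y = rng.standard_normal((n1 + n2, p)) + 0.5 * age[:, None]
    Y[:n1] += 1.0
    table = pd.DataFrame({"SiteName": ["A"] * n1 + ["B"] * n2, "Age": age})
    demo = validate_demographics(table, n1 + n2)
    fm = FeatureMatrix(Y, list(range(n1 + n2)), list(range(p)), "table")
    return fm, demo


@pytest.fixture
def three_site_dataset():
    spec = SyntheticSpec(n_sites=3, n_per_site=30, n_features=40,
                         gamma=(-1.0, 0.0, 1.0), delta=(0.8, 1.0, 1.25),
                         seed=7)
    return generate_multisite_dataset(spec)
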