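import numpy as np
import pytest

from mirset import ExpressionMatrix, GroupDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def toy_matrix():
    """3 features x 4 samples, two per group."""
    vals = np.array([
        [1.0, 2.0, 5.0, 6.0],
        [4.0, 4.5, 4.2, 4.1],
        [9.0, 8.0, 3.0, 2.0],
    ])
    return ExpressionMatrix(vals, ["gA", "gB", "gC"], ["s1", "s2", "s3", "s4"])


@pytest.fixture
def toy_design():
    return GroupDesign({"s1": 1, "s2": 1, "s3": 2, "s4": 2})


def make_null_data(rng, p=50, n_per_group=4, scale=1.0):
    """Independent Gaussian noise with no group effect."""
    vals = rng.normal(0.0, scale, (p, 2 * n_per_group))
    ids = [f"g{i:03d}" for i in range(p)]
    samples = [f"s{j:02d}" for j in range(2 * n_per_group)]
    design = GroupDesign({s: (1 if j < n_per_group else 2) for j, s in enumerate(samples)})
    return ExpressionMatrix(vals, ids, samples), design
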