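import numpy as np
import pytest

from txsubtypes import ExpressionMatrix, SyntheticConfig, generate


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples with two groups."""
    values = np.array([
        [1.0, 2.0, 3.0, 4.0],
        [5.0, 5.5, 6.0, 6.5],
        [9.0, 8.0, 7.0, 6.0],
    ])
    return ExpressionMatrix(
        ["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"], values,
        {"s1": "A", "s2": "A", "s3": "B", "s4": "B"})


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the default study conditions."""
    return generate(SyntheticConfig(seed=11))
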