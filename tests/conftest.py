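import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gwolfsel.io_prep import ExpressionMatrix  # noqa: E402
from gwolfsel.synthetic import SyntheticSpec, generate_dataset  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples with both classes."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [5.0, 6.0, 7.0, 8.0],
            [2.0, 2.5, 3.0, 3.5],
        ]
    )
    return ExpressionMatrix(
        values,
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        labels=np.array([1, 1, 0, 0]),
    )


@pytest.fixture(scope="session")
def small_planted():
    """120-sample, 200-gene dataset with 20 planted genes (strong effect)."""
    spec = SyntheticSpec(
        n_samples=120, n_genes=200, n_informative=20, imbalance=0.75, seed=20
    )
    return generate_dataset(spec)
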