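import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_two_cluster_dataset():
    """A small, well-separated two-cluster dataset for training smoke tests."""
    from fcgrclust.synthetic import SyntheticSpec, make_signature_models, sample_sequences

    spec = SyntheticSpec(
        c=2, n_per_cluster=100, length_range=(2000, 3000), delta=0.8, seed=7
    )
    return sample_sequences(make_signature_models(spec), spec), spec


def random_acgt(rng, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
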