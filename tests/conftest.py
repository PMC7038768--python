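import numpy as np
import pytest
from hypothesis import settings

from canopyscan import IsodataConfig, SampleSet

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")

TRUE_LAYERS = np.array([60.0, 66.0, 80.0])


def three_layer_values(
    seed: int, per_layer: int = 120, sd: float = 0.5
) -> np.ndarray:
    """Seeded 1-D fixture: three Gaussian echo layers at 60/66/80 cm."""
    rng = np.random.default_rng(seed)
    return np.concatenate(
        [rng.normal(m, sd, per_layer) for m in TRUE_LAYERS]
    )


@pytest.fixture
def three_layer_samples() -> SampleSet:
    return SampleSet.from_distances(three_layer_values(seed=7))


@pytest.fixture
def paper_config() -> IsodataConfig:
    """The driver settings used throughout: c_init=3, eps=1e-4, q=2,
    theta_n=20, theta_s=5, theta_c=2."""
    return IsodataConfig()


def random_partition(rng: np.random.Generator, c: int, n: int) -> np.ndarray:
    """Random valid membership matrix (columns Dirichlet over c clusters)."""
    u = rng.dirichlet(np.ones(c), size=n).T
    return u
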