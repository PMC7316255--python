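import numpy as np
import pytest
from hypothesis import settings

from msaptools import SyntheticSpec, generate
from msaptools.io import BandMatrix, pair_matrices
from msaptools.states import build_state_matrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small noiseless synthetic dataset with known truth (3 groups)."""
    spec = SyntheticSpec(
        n_loci=300,
        groups=(("Color", 8), ("Early-maturation", 7), ("Spur", 7)),
        n_outlier_loci=4,
        outlier_divergence=1.0,
        noise_rate=0.0,
        seed=42,
    )
    return spec, *generate(spec)


@pytest.fixture(scope="session")
def small_states(small_dataset):
    _, pair, _, _ = small_dataset
    return build_state_matrix(pair)


def random_band_matrix(rng, n_samples, n_loci, track="HPA", missing_rate=0.0):
    values = rng.integers(0, 2, size=(n_samples, n_loci)).astype(np.int8)
    if missing_rate:
        values[rng.random(values.shape) < missing_rate] = -1
    return BandMatrix(
        f"rand-{track}",
        track,
        [f"S{i}" for i in range(n_samples)],
        [f"L{j}" for j in range(n_loci)],
        values,
    )


@pytest.fixture
def random_pair():
    rng = np.random.default_rng(7)
    hpa = random_band_matrix(rng, 5, 12, "HPA", missing_rate=0.1)
    msp = random_band_matrix(rng, 5, 12, "MSP", missing_rate=0.1)
    return pair_matrices(hpa, msp)
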