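import numpy as np
import pytest

from seizeeg import FeatureMatrix, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """40 short two-class synthetic segments (20 per class)."""
    base = SynthConfig(n_samples=512)
    return generate_dataset(20, base_cfg=base, seed=0)


def make_informative_table(
    n_rows: int = 300,
    n_informative: int = 10,
    n_noise: int = 10,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> FeatureMatrix:
    """Binary-label table: informative columns = label + Gaussian noise,
    noise columns pure Gaussian.  Used to probe importance recovery."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n_rows)
    informative = y[:, None] + noise_sd * rng.standard_normal((n_rows, n_informative))
    noise = rng.standard_normal((n_rows, n_noise))
    names = [f"inf{j}" for j in range(n_informative)] + [
        f"noise{j}" for j in range(n_noise)
    ]
    return FeatureMatrix(names, np.hstack([informative, noise]), y)
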