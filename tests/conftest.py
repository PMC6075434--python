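import numpy as np
import pytest

from dnamclock import PreselectionSpec, SyntheticSpec, generate_dataset, train_clock


@pytest.fixture(scope="session")
def small_dataset():
    """Cross-sectional dataset with clear age signal and a platform split."""
    spec = SyntheticSpec(n_samples=150, n_causal=20, n_null=200,
                         noise_sd=0.02, platform_split=0.2, seed=11)
    m, ann, truth = generate_dataset(spec)
    return spec, m, ann, truth


@pytest.fixture(scope="session")
def small_clock(small_dataset):
    """A clock trained once on the small dataset; shared across tests."""
    _, m, ann, _ = small_dataset
    model = train_clock(
        m, ann, PreselectionSpec(k_pos=20, k_neg=20, k_null=50),
        folds=5, seed=1,
    )
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
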