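import numpy as np
import pytest
from hypothesis import settings

# property tests must be reproducible run to run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def random_meta_dataset(seed, n=None, n_cov=0):
    """A random small meta-analytic dataset (y, v, Z) for identity checks."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(3 + n_cov, 21))
    y = rng.normal(rng.normal(0, 0.5), 0.6, n)
    v = rng.uniform(0.02, 0.5, n)
    Z = rng.normal(size=(n, n_cov)) if n_cov else None
    return y, v, Z


@pytest.fixture
def dataset_factory():
    return random_meta_dataset


@pytest.fixture
def effects_csv(tmp_path):
    """A small valid effects CSV on disk."""
    p = tmp_path / "effects.csv"
    p.write_text(
        "study,yi,vi\n"
        "s1,0.10,0.20\n"
        "s2,0.50,0.10\n"
        "s3,-0.30,0.25\n"
    )
    return p
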