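import numpy as np
import pytest

from neuralsig import synthetic


@pytest.fixture(scope="session")
def atlas():
    """Default-sized synthetic atlas: 25 components, 10-CpG blocks, 250 CpGs."""
    return synthetic.make_reference_atlas(250, seed=0)


@pytest.fixture(scope="session")
def noisy_cohort(atlas):
    """100-sample cohort at the reference noise level (sd 0.005)."""
    return synthetic.make_bulk_cohort(atlas, n_samples=100, noise_sd=0.005, seed=11)


@pytest.fixture(scope="session")
def visium_sample():
    """Noise-free 10 x 10 hexagonal sample at mid score."""
    return synthetic.make_visium_sample(
        n_rows=10, n_cols=10, truth_score=0.5, n_genes=60, noise_sd=0.0, seed=3
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
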