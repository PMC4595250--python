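import numpy as np
import pytest

import sersdx


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort under the reference design (454 spectra)."""
    return sersdx.generate_cohort(sersdx.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_processed(default_cohort):
    return sersdx.preprocess_cohort(default_cohort)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two-group cohort small enough for I/O and plumbing tests."""
    cfg = sersdx.SyntheticConfig(
        patients_per_group={"PA": 3, "Normal": 3},
        spectra_per_patient=(2, 2),
        seed=7,
    )
    return sersdx.generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
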