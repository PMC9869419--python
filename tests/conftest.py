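import numpy as np
import pytest

import actisleep as a


@pytest.fixture(scope="session")
def small_cohort():
    """Four short synthetic subjects (150 epochs each) with hypnograms."""
    return a.simulate_cohort(n_subjects=4, n_epochs=150, seed=11)


@pytest.fixture(scope="session")
def epoch_table(small_cohort):
    """Pooled epoch feature table of the small cohort."""
    return a.build_dataset(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
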