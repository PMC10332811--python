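import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Mixed depressing/facilitating cohort through the full pipeline."""
    from stpkit import simulate_cohort

    return simulate_cohort(
        n_depressing=12, n_facilitating=8, n_sweeps=6, noise_sd_frac=0.05, seed=42
    )


@pytest.fixture(scope="session")
def feature_table():
    """Two-class intrinsic-feature population with mild missingness."""
    from stpkit import IntrinsicPopulationSpec, simulate_intrinsic_features

    spec = IntrinsicPopulationSpec(
        n_per_class=150, missing_rate=0.05, protocol_shift={"spike_width": 3.0}
    )
    return simulate_intrinsic_features(spec, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
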