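import numpy as np
import pytest

import seasonfc as sf


@pytest.fixture(scope="session")
def small_sim() -> sf.SimulationConfig:
    """A compact, strongly-coupled cohort config used across test modules."""
    return sf.SimulationConfig(
        n_per_season=(6, 5, 5, 5),
        n_gm_regions=5,
        n_wm_regions=4,
        n_networks=2,
        n_timepoints=256,
        n_latents=3,
        loading_scale=1.5,
        noise_sd=0.6,
        amp_true=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_sim) -> sf.Cohort:
    return sf.generate_cohort(small_sim)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250925)
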