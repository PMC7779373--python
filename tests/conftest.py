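import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_sim():
    """Small model-matched dataset with ground truth (shared across tests)."""
    from pfmlab import simulate

    cfg = simulate.model_matched_preset(
        n_voxels=150, n_timepoints=80, n_subjects=3, n_modes=3, seed=11
    )
    return simulate.generate(cfg)


@pytest.fixture(scope="session")
def tiny_fit(tiny_sim):
    """A converged-ish fit of the tiny dataset (shared across tests)."""
    from pfmlab import ModelConfig, fit

    ds, _truth = tiny_sim
    return fit(ds, ModelConfig(M=3, seed=1, max_sweeps=30))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
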