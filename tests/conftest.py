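"""Shared fixtures: synthetic shapes and (expensive) end-to-end study runs."""
import numpy as np
import pytest

from densemorph import StudyConfig, make_base_shape, run_study


@pytest.fixture(scope="session")
def base3():
    """642-vertex mandible-like base shape with its 26 + 5 landmark sets."""
    return make_base_shape(3, seed=0)


@pytest.fixture(scope="session")
def small_study():
    """Reduced study replica (6 unaltered / 4 operated, 7 observers, 3 reps,
    3 mapping rounds, 642-vertex meshes) with the default noise model."""
    config = StudyConfig(n_unaltered=6, n_operated=4, seed=101)
    report, manifest = run_study(config)
    return config, report, manifest


@pytest.fixture(scope="session")
def noiseless_study():
    """Same pipeline with zero observer noise (shape variation retained)."""
    config = StudyConfig(
        n_unaltered=5,
        n_operated=0,
        intra_sd=0.0,
        observer_bias_sd=0.0,
        seed=102,
    )
    report, manifest = run_study(config)
    return config, report, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
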