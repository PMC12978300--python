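import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def nucleus():
    from naquad.relaxation_core import NucleusContext
    return NucleusContext()


@pytest.fixture(scope="session")
def model1_fit():
    """One full-length model-1 fit of a synthetic dataset (shared)."""
    from naquad.inference import MCMCSettings, mcmc_fit
    from naquad.synthetic import default_model1_truth, generate_dataset
    ds = generate_dataset(default_model1_truth(seed=42))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = mcmc_fit(ds, 1, MCMCSettings(seed=7))
    return ds, post


@pytest.fixture(scope="session")
def sphere_walk_msd():
    """COM-frame sphere-walk trajectory and its MSD analysis (shared)."""
    from naquad.md_analysis import com_frame, msd_initial_slope
    from naquad.synthetic import TrajectorySpec, generate_sphere_walk
    spec = TrajectorySpec(seed=5)
    traj = com_frame(generate_sphere_walk(spec))
    result = msd_initial_slope(traj, fit_window=100e-12, radius=27e-10)
    return spec, traj, result
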