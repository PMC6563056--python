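import numpy as np
import pytest

from glycoleus.leus import BiasPotential, LEUSSchedule, le_build, us_sample
from glycoleus.systems import two_basin_surface
from glycoleus.toy_system import (
    AnalyticSurface,
    GaussianWell,
    SamplerConfig,
    sample_dihedrals,
)


@pytest.fixture(scope="session")
def flat_surface():
    return AnalyticSurface(angle_names=("phi", "psi"))


@pytest.fixture(scope="session")
def two_basin():
    """Two-basin surface with quadrature basin ΔG calibrated to 3.0 kJ/mol."""
    return two_basin_surface(3.0)


@pytest.fixture(scope="session")
def two_basin_leus(two_basin):
    """One LE build + US run on the two-basin surface, shared across tests."""
    sched = LEUSSchedule(t_le=40000, t_us=120000, seed=11)
    bias = le_build(two_basin, BiasPotential(two_basin.angle_names), sched)
    traj = us_sample(two_basin, bias, sched)
    return bias, traj


@pytest.fixture(scope="session")
def unbiased_two_basin(two_basin):
    return sample_dihedrals(two_basin, SamplerConfig(n_steps=120000, seed=7, record_every=10))
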