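import numpy as np
import pytest

import dissectsim as ds
from dissectsim.fem import P1Operators


@pytest.fixture(scope="session")
def channel_mesh():
    """20 x 4 mm channel, h = 0.2 mm (shared by transport tests)."""
    return ds.benchmark_channel(20.0, 4.0, 0.2)


@pytest.fixture(scope="session")
def channel_ops(channel_mesh):
    return P1Operators(channel_mesh)


@pytest.fixture(scope="session")
def blood():
    return ds.FluidProperties(density=1060.0)


@pytest.fixture(scope="session")
def newtonian():
    """Constant-viscosity blood analog used by the flow-solver oracles."""
    return ds.FluidProperties(density=1060.0, constant_viscosity=3.5e-3)


@pytest.fixture(scope="session")
def tparams():
    return ds.ThrombosisParams()


def l2_error(ops, f, f_exact):
    num = np.sum(ops.lumped_mass * (f - f_exact) ** 2)
    den = np.sum(ops.lumped_mass * f_exact**2)
    return float(np.sqrt(num / den))
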