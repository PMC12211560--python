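import numpy as np
import pytest
from hypothesis import settings

from corset.solver import EnergyModel, SolverOptions, shape_family

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: mid-surface area of the reference system: a 500 nm diameter sphere
SPHERE_AREA_500 = 4.0 * np.pi * 250.0**2
#: intermembrane distance of the reference system, nm
D_REF = 10.0
#: area-difference targets tracing the sphere -> elongated -> peanut family
FAMILY_TARGETS = [0.08, 0.10, 0.12, 0.16, 0.20]


@pytest.fixture(scope="session")
def reference_family():
    """Continuation family of the 500 nm / d = 10 nm system (computed once)."""
    return shape_family(
        SPHERE_AREA_500, D_REF, FAMILY_TARGETS,
        EnergyModel(d=D_REF), SolverOptions(seed=0),
    )
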