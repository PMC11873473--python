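import numpy as np
import pytest

import trochleamap as tm


@pytest.fixture(scope="session")
def cylinder():
    """Cylinder r=10 mm, h=50 mm with analytic curvature oracle."""
    return tm.make_primitive("cylinder", radius=10.0, height=50.0, spacing=0.6)


@pytest.fixture(scope="session")
def sphere():
    return tm.make_primitive("sphere", radius=5.0, spacing=0.5)


@pytest.fixture(scope="session")
def saddle():
    return tm.make_primitive("saddle", size=40.0, c=10.0, spacing=0.8)


@pytest.fixture(scope="session")
def lateralized_phantom():
    """Grooved phantom with a lateralized groove and its ground truth."""
    spec = tm.PhantomSpec(groove_lateral_offset=8.0, mesh_resolution=1.0)
    mesh, truth = tm.make_trochlea_phantom(spec)
    return spec, mesh, truth


@pytest.fixture(scope="session")
def symmetric_phantom():
    spec = tm.PhantomSpec(groove_lateral_offset=0.0, mesh_resolution=1.0)
    mesh, truth = tm.make_trochlea_phantom(spec)
    return spec, mesh, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
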