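import numpy as np
import pytest

from vesseltrace.core import Centerline, ImageVolume, ProbabilityMask
from vesseltrace.phantom import PhantomSpec, generate_curve, make_phantom


@pytest.fixture(scope="session")
def straight_spec():
    """Axis-aligned straight tube, 120 mm long, on a roomy grid."""
    return PhantomSpec(
        curve_kind="straight",
        radius_mm=10.0,
        grid_shape=(40, 40, 80),
        spacing_mm=(2.0, 2.0, 2.0),
        edge_softness_mm=0.0,
        seed=11,
        curve_params={"length_mm": 120.0, "direction": (0.0, 0.0, 1.0)},
    )


@pytest.fixture(scope="session")
def straight_case(straight_spec):
    return make_phantom(straight_spec)


@pytest.fixture(scope="session")
def default_case():
    """One default aorta-like phantom (48^3 grid, 2 mm spacing)."""
    return make_phantom(PhantomSpec(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
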