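import hypothesis
import numpy as np
import pytest

import tg43seed as t

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def ir06():
    return t.ir06()


@pytest.fixture
def line_model():
    return t.GeometryModel.line(0.3)


@pytest.fixture
def noiseless_config():
    return t.SimulatorConfig(noise_relative_sigma=0.0, random_seed=7)


@pytest.fixture
def noiseless_grid(noiseless_config, line_model):
    grid, truth = t.simulate_dose_grid(noiseless_config)
    return grid, truth


def make_grid(radii, angles, values, medium="water"):
    return t.DoseRateGrid(
        radii=np.asarray(radii, float),
        angles=np.asarray(angles, float),
        values=np.asarray(values, float),
        medium=medium,
    )


@pytest.fixture
def geometry_grid(line_model):
    """Pure-geometry grid D = C * G(r, theta): attenuation-free limit."""
    radii = np.array([0.25, 0.5, 1.0, 2.0, 5.0])
    angles = np.array([0.0, 30.0, 60.0, 90.0])
    G = t.geometry_function(radii[:, None], angles[None, :], line_model)
    return make_grid(radii, angles, 7.5 * G)
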