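import numpy as np
import pytest
from hypothesis import settings

from paitwin.forward import SensorArray
from paitwin.phantoms import (GeometryConfig, NodeGroundTruth, build_phantom,
                              generate_label_map)
from paitwin.spectra import default_spectra

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spectra():
    return default_spectra()


@pytest.fixture(scope="session")
def small_geometry():
    """Desk-scale imaging grid used throughout the pipeline tests."""
    return GeometryConfig(shape=(128, 64), spacing=0.2)


@pytest.fixture(scope="session")
def small_array():
    return SensorArray(n_elements=128)


@pytest.fixture(scope="session")
def node_phantom(small_geometry):
    """One seeded phantom with an intermediate-state node."""
    truth = NodeGroundTruth(bvf=0.09, so2=0.58, state_name="intermediate")
    label = generate_label_map(small_geometry, 12)
    return build_phantom(label, None, truth,
                         wavelengths=(700, 730, 760, 800, 850))
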