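import numpy as np
import pytest

from lair.geometry import ScanGeometry
from lair.phantom import generate_dataset, shepp_logan
from lair.pipeline import desk_ce_geometry


@pytest.fixture(scope="session")
def small_fan_geometry() -> ScanGeometry:
    return ScanGeometry(sod=60.0, sid=80.0, det_pitch_um=800.0, det_count=48)


@pytest.fixture(scope="session")
def parallel_geometry() -> ScanGeometry:
    return ScanGeometry(
        sod=100.0, sid=100.0, det_pitch_um=500.0, det_count=64, beam="parallel"
    )


@pytest.fixture(scope="session")
def shepp_logan_128() -> np.ndarray:
    # scaled to a soft-tissue attenuation range (mm^-1)
    return shepp_logan(128) * 0.025


@pytest.fixture(scope="session")
def tiny_dataset():
    """Ten cylinder-phantom sinogram triples at the network desk profile."""
    return generate_dataset(10, desk_ce_geometry(), seed=7)
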