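import numpy as np
import pytest

from dbtpre import AcquisitionGeometry
from dbtpre.geometry import ProjectionSet
from dbtpre.phantom import DigitalPhantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geometry():
    return AcquisitionGeometry(n_projections=15, arc_deg=15.0,
                               detector_shape=(32, 64), pixel_pitch=0.5)


def attenuation_phantom(volume: np.ndarray, voxel_size: float = 1.0) -> DigitalPhantom:
    """Wrap a raw non-negative attenuation array as a phantom (label: mass
    wherever attenuation is nonzero, so the air invariant holds)."""
    volume = np.asarray(volume, dtype=np.float64)
    label = np.where(volume > 0, 3, 0).astype(np.int8)
    return DigitalPhantom(volume=volume, voxel_size=voxel_size,
                          label_map=label, breast_type="dense")


def projection_set(images: np.ndarray, geometry: AcquisitionGeometry) -> ProjectionSet:
    return ProjectionSet(images=images, angles_deg=geometry.angles_deg,
                         geometry=geometry)
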