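import numpy as np
import pytest

from cacskit.core_io import CtVolume, VesselLabelMask
from cacskit.phantom import LesionSpec, PhantomSpec, generate_phantom, standard_cohort


@pytest.fixture(scope="session")
def single_lesion_case():
    """One uniform 450 HU LAD lesion, 5 voxels in one slice at 0.5 mm pixels.

    Pixel-aligned centre so the footprint is the 5-voxel cross: area
    1.25 mm^2, Agatston 1.25 * 4 = 5.0.
    """
    spec = PhantomSpec(
        shape=(10, 64, 64),
        lesions=[LesionSpec(vessel=2, center=(21.0, 16.0, 16.0),
                            radius_mm=0.6, axial_extent=1, peak_hu=450.0)],
        seed=0,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def cohort10():
    return standard_cohort(10, seed=11)


@pytest.fixture(scope="session")
def cohort46():
    return standard_cohort(46, seed=1234)


@pytest.fixture
def flat_volume():
    """A 3-slice, all-zero-HU volume with a paired empty mask."""
    shape = (3, 16, 16)
    vol = CtVolume(voxels=np.zeros(shape), spacing=(3.0, 0.5, 0.5))
    mask = VesselLabelMask(labels=np.zeros(shape, dtype=np.int64),
                           spacing=(3.0, 0.5, 0.5))
    return vol, mask
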