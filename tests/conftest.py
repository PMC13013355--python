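import numpy as np
import pytest

from lesioneval import LabelVolume, default_phantom_spec, load_stage_rules
from lesioneval.phantom import Compartment, PhantomSpec


@pytest.fixture(scope="session")
def rules():
    return load_stage_rules("ninth_edition")


@pytest.fixture(scope="session")
def spec():
    return default_phantom_spec()


@pytest.fixture
def tiny_spec():
    """A compact three-compartment layout for fast generation tests."""
    comps = [
        Compartment(1, "T", "right_lung_primary", ((2, 14), (2, 14), (2, 14)),
                    radius_range_mm=(5.0, 12.0)),
        Compartment(2, "N", "ipsilateral_hilar", ((14, 22), (2, 14), (2, 14))),
        Compartment(3, "M", "liver", ((2, 14), (14, 22), (2, 14))),
    ]
    return PhantomSpec(
        grid_shape=(24, 24, 24),
        voxel_spacing=(4.0, 4.0, 4.0),
        compartments=comps,
        lesions_per_compartment={1: 1, 2: 1, 3: 1},
        radius_range_mm=(4.0, 8.0),
    ).validate()


def volume_from(arr, spacing=(1.0, 1.0, 1.0)):
    return LabelVolume(np.asarray(arr, dtype=np.int32), spacing)


@pytest.fixture
def make_volume():
    return volume_from
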