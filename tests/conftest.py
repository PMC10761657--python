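import numpy as np
import pytest

from petrestore import (AcquisitionModel, Ellipsoid, PhantomSpec, Sphere,
                        generate_phantom)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """A small phantom with one organ and one hot lesion."""
    organ = Ellipsoid(center=(15.5, 15.5, 5.5), semi_axes_mm=(25.0, 25.0, 12.0),
                      activity=2.0, ct_level=50.0)
    lesion = Sphere(center=(15.5, 15.5, 5.5), radius_mm=6.0,
                    activity=8.0, ct_level=40.0)
    return PhantomSpec(grid_shape=(32, 32, 12), organs=(organ,),
                       lesions=(lesion,), background_activity=0.5, seed=7)


@pytest.fixture
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture
def fast_acq():
    return AcquisitionModel(durations_s=(6.0, 60.0, 600.0))
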