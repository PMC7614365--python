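import numpy as np
import pytest

from spheromap import simdata
from spheromap.mesh import make_embryo_mesh
from spheromap.simdata import SimConfig


@pytest.fixture(scope="session")
def mesh():
    return make_embryo_mesh(200, 100.0, seed=3)


@pytest.fixture(scope="session")
def fields(mesh):
    # reduced gene load keeps unit tests fast; defaults are exercised in the
    # acceptance suite
    return simdata.make_expression_fields(
        mesh, n_background=300, n_smooth=60, seed=3
    )


@pytest.fixture(scope="session")
def reference(mesh, fields):
    return simdata.sample_reference_profiles(
        fields, mesh, samples_per_region=4, cfg=SimConfig(seed=4)
    )


@pytest.fixture(scope="session")
def epi_stack():
    return simdata.make_spheroid_stack("epi", seed=11)


@pytest.fixture(scope="session")
def am_stack():
    return simdata.make_spheroid_stack("am", seed=12)
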