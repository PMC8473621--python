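import numpy as np
import pytest

from osteoseed import (DefectSpec, MarrowRheology, ScaffoldSpec,
                       build_section_domain, build_titanium_lattice)


@pytest.fixture(scope="session")
def default_lattice():
    return build_titanium_lattice(ScaffoldSpec())


@pytest.fixture(scope="session")
def coarse_section():
    """Small section domain for quick flow/transport tests."""
    return build_section_domain(nx=32, nz=48)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
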