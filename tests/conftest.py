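import numpy as np
import pytest

from hgofit.constitutive import (
    ElasticConstants,
    FiberParams,
    GroundParams,
    MaterialRegion,
    elastic_to_ground,
)
from hgofit.synthetic import reference_fixtures


@pytest.fixture(scope="session")
def reference():
    return reference_fixtures()


@pytest.fixture(scope="session")
def regions(reference):
    """The three calibrated annulus regions of the reference table."""
    return reference.regions


@pytest.fixture(scope="session")
def posterior(regions):
    return regions["posterior"]


@pytest.fixture(scope="session")
def anterior(regions):
    return regions["anterior"]


@pytest.fixture(scope="session")
def posterior_ground():
    """Ground substance converted from the posterior fit (E=0.46, nu=0.49)."""
    return elastic_to_ground(ElasticConstants(0.46, 0.49))
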