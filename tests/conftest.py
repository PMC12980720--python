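import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def templates():
    from csacg.topology import load_templates
    return load_templates()


@pytest.fixture(scope="session")
def chain21(templates):
    from csacg.topology import build_chain
    return build_chain(21, templates)


@pytest.fixture(scope="session")
def chain21_coords(chain21):
    from csacg.topology_io import extended_coordinates
    return extended_coordinates(chain21)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
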