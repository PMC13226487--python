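import pytest

from vesselbench.phantom import make_fixture_suite


@pytest.fixture(scope="session")
def suite():
    """The five deterministic named phantom fixtures (in memory)."""
    return make_fixture_suite()


@pytest.fixture(scope="session")
def straight_tube(suite):
    return suite["straight_tube"]


@pytest.fixture(scope="session")
def y_junction(suite):
    return suite["y_junction"]


@pytest.fixture(scope="session")
def hollow_trunk(suite):
    return suite["hollow_trunk"]


@pytest.fixture(scope="session")
def capillary_mesh(suite):
    return suite["capillary_mesh"]


@pytest.fixture(scope="session")
def weak_signal(suite):
    return suite["weak_signal"]


@pytest.fixture(scope="session")
def hollow_segmentation(hollow_trunk):
    """Annular (hollow) segmentation of the trunk fixture, from its image."""
    spec = hollow_trunk.spec
    thr = spec.background_level + spec.foreground_intensity / 2
    return hollow_trunk.image.data > thr
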