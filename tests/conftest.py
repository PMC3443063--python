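import pytest

from gemproject import fixtures as fx
from gemproject.orthology import build_consensus
from gemproject.projection import project


@pytest.fixture(scope="session")
def spec():
    return fx.FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def scaffold(spec):
    return fx.make_scaffold(spec)


@pytest.fixture(scope="session")
def media_cfg(spec):
    return fx.make_media_config(spec)


@pytest.fixture(scope="session")
def maps_and_truth(scaffold, spec):
    return fx.make_ortholog_maps(scaffold, spec)


@pytest.fixture(scope="session")
def consensus(maps_and_truth):
    maps, _truth = maps_and_truth
    return build_consensus(maps)


@pytest.fixture(scope="session")
def projected(scaffold, consensus):
    """(target model, projection report) for the zero-noise fixture study."""
    return project(scaffold, consensus)
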