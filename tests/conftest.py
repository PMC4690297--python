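import pytest

from coolernudge import PlacementLocation, default_params


@pytest.fixture
def params():
    """Published default parameter bundle."""
    return default_params()


@pytest.fixture
def worst():
    return PlacementLocation(6, 6)


@pytest.fixture
def optimal():
    return PlacementLocation(1, 2)


def all_locations(params):
    return [
        PlacementLocation(c, s)
        for c in range(1, params.n_coolers + 1)
        for s in range(1, params.n_shelves + 1)
    ]
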