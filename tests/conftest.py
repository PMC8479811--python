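import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracle helper

from pertbuild import fixtures as fx


@pytest.fixture(scope="session")
def named():
    """All named fixture topologies (+ coordinates where provided)."""
    return {name: fx.make_fixture(name) for name in fx.fixture_names()}


@pytest.fixture
def lysine_pair(named):
    return named["lysine_side"][0], named["trimethyllysine_side"][0]


@pytest.fixture
def acetyl_pair(named):
    return named["lysine_side"][0], named["acetyllysine_side"][0]


@pytest.fixture
def toy_pair(named):
    return named["methanol_ua"][0], named["ethane_ua"][0]
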