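import numpy as np
import pytest

from ventplume.community import ModelParams
from ventplume.guilds import default_guilds
from ventplume.species import default_registry
from ventplume.synthetic_sites import seawater_background


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def guilds():
    return default_guilds()


@pytest.fixture()
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def background():
    return seawater_background()
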