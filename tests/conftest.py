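import pytest

from starlocus import build_custom_track
from starlocus.align import Prober
from starlocus.fixtures import default_model


@pytest.fixture(scope="session")
def model_defs():
    return default_model()


@pytest.fixture(scope="session")
def model(model_defs):
    return model_defs[0]


@pytest.fixture(scope="session")
def defs(model_defs):
    return model_defs[1]


@pytest.fixture(scope="session")
def tracks(model):
    return {tid: build_custom_track(model, tid) for tid in ("REF", "A", "B")}


@pytest.fixture(scope="session")
def prober(model, defs):
    return Prober(model, defs)
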