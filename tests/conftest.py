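import pytest

from loopdist import coords


@pytest.fixture(scope="session")
def panel():
    return coords.default_probe_panel()


@pytest.fixture(scope="session")
def loops():
    return coords.default_loop_annotation()
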