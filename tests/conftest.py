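import pytest

from helpers import log_from_symbols


@pytest.fixture
def make_log():
    return log_from_symbols
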