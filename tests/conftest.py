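import pytest

from mviscore import load_reference_set


@pytest.fixture(scope="session")
def refset():
    return load_reference_set()
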