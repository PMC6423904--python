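import pytest

from etherlipids import enumerate_library


@pytest.fixture(scope="session")
def library():
    """The default combinatorial library, shared across tests."""
    return enumerate_library()
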