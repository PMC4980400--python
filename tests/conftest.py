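import pytest

from ecea import land_fixture


@pytest.fixture
def land():
    """The country-'Land' TB scenario (five quintiles, UPF of TB treatment)."""
    return land_fixture()
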