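import pytest
from hypothesis import settings

from cdgmine.references import load_reference_panel

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    """The packaged (synthetic stand-in) reference panel."""
    return load_reference_panel()
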