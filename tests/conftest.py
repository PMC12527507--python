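import pytest
from hypothesis import settings

from esconvert.schema import StudyRow

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def make_row():
    """Factory for StudyRows with only the named fields set."""

    def _make(**kwargs):
        return StudyRow(**kwargs)

    return _make
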