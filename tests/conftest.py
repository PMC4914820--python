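import pytest
from hypothesis import HealthCheck, settings

from tests.helpers import build_song

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def quarter_song_table():
    """One song, one phrase, four quarter notes."""
    from tests.helpers import make_table

    rows = [f"tune,English,children,4/4,C,,0,{i},60,1,1,0,0" for i in range(4)]
    return make_table(rows)


@pytest.fixture
def two_phrase_song():
    """Phrases [1,2] and [2,1]: the junction pair (2,2) must be excluded."""
    return build_song([[1, 2], [2, 1]])
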