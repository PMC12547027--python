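import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from blindindex.table import GuessTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(rows, **kw) -> GuessTable:
    """Shorthand fixture builder from a list of count rows."""
    return GuessTable.build(np.asarray(rows), **kw)


@pytest.fixture
def acupuncture():
    return make_table([[42, 0], [19, 2]])


@pytest.fixture
def balanced_random():
    return make_table([[50, 50, 0], [50, 50, 0]])


@pytest.fixture
def unbalanced_idk():
    return make_table([[36, 12, 19], [18, 6, 9]])
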