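import numpy as np
import pytest

from rewardpace.ethogram import (
    DEFAULT_VOCABULARY,
    BehaviorEvent,
    CopulationTestLog,
)


@pytest.fixture
def vocab():
    return DEFAULT_VOCABULARY


@pytest.fixture
def make_log():
    """Factory: build a validated-looking log from (behavior, start, end) triples."""

    def _make(*triples, subject="r1", test_duration=1800.0):
        events = tuple(
            sorted(BehaviorEvent(start=s, end=e, behavior=b) for b, s, e in triples)
        )
        return CopulationTestLog(
            subject=subject, events=events, test_duration=test_duration
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240224)
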