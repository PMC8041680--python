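import numpy as np
import pytest

from visearch import TaskLayout, default_profiles, simulate_participant


@pytest.fixture(scope="session")
def layout():
    return TaskLayout()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def td_participant(layout, profiles):
    """One rendered TD participant shared by detection/segmentation tests."""
    return simulate_participant(profiles["TD"], layout, seed=42,
                                participant_id="td_42")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
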