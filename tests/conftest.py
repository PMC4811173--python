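import hypothesis
import numpy as np
import pytest
from hypothesis import strategies as st

from dramatyping import AlgorithmParameters, LabValueEpisode, validate_episode
from dramatyping.signal_ops import WeightedSeries

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


def make_episode(days, values, admin_days, episode_id="ep") -> LabValueEpisode:
    return validate_episode((episode_id, list(zip(days, values)), admin_days))


@pytest.fixture
def episode_factory():
    return make_episode


@pytest.fixture
def params() -> AlgorithmParameters:
    return AlgorithmParameters()


@pytest.fixture
def simple_series():
    """Contiguous 5-day series, all observed."""
    return WeightedSeries(np.arange(1, 6), np.array([0.1, 0.2, 0.3, 0.4, 0.5]), np.ones(5))


@st.composite
def episode_strategy(draw, min_obs=3, max_obs=30):
    """Random valid episodes: unique increasing days, finite values, admin
    window inside the observation span."""
    days = sorted(
        draw(
            st.lists(
                st.integers(1, 60), min_size=min_obs, max_size=max_obs, unique=True
            )
        )
    )
    values = draw(
        st.lists(
            st.floats(-5, 5, allow_nan=False, allow_infinity=False),
            min_size=len(days),
            max_size=len(days),
        )
    )
    first_admin = draw(st.integers(days[0], days[-1]))
    last_admin = draw(st.integers(first_admin, days[-1]))
    return make_episode(days, values, list(range(first_admin, last_admin + 1)))
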