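import numpy as np
import pytest

from audiencesync import ChannelSeries, SusyParams


@pytest.fixture
def params():
    """Default synchrony parameters with a small surrogate count for speed."""
    return SusyParams(n_surrogates=30, rng_seed=123)


@pytest.fixture
def make_series():
    """Factory for feature series on the 1-Hz grid."""

    def _make(values, pid="p1", channel="HR", rate_hz=1.0, concert="c1"):
        return ChannelSeries(
            concert_id=concert, participant_id=pid, channel=channel,
            rate_hz=rate_hz, values=np.asarray(values, dtype=float),
        )

    return _make


@pytest.fixture
def white_noise(make_series):
    """Factory for seeded white-noise series."""

    def _make(n, pid="p1", seed=0, channel="HR"):
        rng = np.random.default_rng(seed)
        return make_series(rng.normal(size=n), pid=pid, channel=channel)

    return _make
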