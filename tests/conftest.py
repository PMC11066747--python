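import numpy as np
import pytest

from rhythmlink import RhythmProfile, simulate_feature_stream


@pytest.fixture
def rng():
    return np.random.default_rng(20240418)


@pytest.fixture
def noiseless_profile():
    """Pure 24-h cosine: 10 + 2*cos(2*pi*(t - 14)/24)."""
    return RhythmProfile(mesor=10.0, amp_by_period={24: 2.0}, acro_by_period={24: 14.0})


@pytest.fixture
def three_component_profile():
    return RhythmProfile(
        mesor=10.0,
        amp_by_period={8: 1.0, 12: 1.5, 24: 2.0},
        acro_by_period={8: 3.0, 12: 5.0, 24: 14.0},
    )


@pytest.fixture
def noiseless_stream(noiseless_profile):
    return simulate_feature_stream(noiseless_profile, 72, seed=0)
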