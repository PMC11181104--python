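import matplotlib

matplotlib.use("Agg")

import pytest

from alphalock.echt import FilterSpec
from alphalock.synthgen import make_background
from alphalock.targeting import SubjectProfile

FS = 501.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def spec10():
    """IAF +/- 25% causal bandpass around 10 Hz."""
    return FilterSpec(center=10.0, fs=FS)


@pytest.fixture(scope="session")
def clean_alpha():
    """Noise-free 10 Hz alpha recording with ground-truth phase."""
    return make_background(30.0, FS, iaf=10.0, alpha_amp=5.0, noise_amp=0.0,
                           seed=11)


@pytest.fixture(scope="session")
def noisy_alpha():
    """10 Hz alpha plus 1/f background at a realistic amplitude ratio."""
    return make_background(60.0, FS, iaf=10.0, alpha_amp=8.0, noise_amp=3.0,
                           seed=12)


@pytest.fixture(scope="session")
def profile10():
    """The worked-example subject: IAF 10 Hz, P1 latency 50 ms."""
    return SubjectProfile(iaf=10.0, p1_latency=0.050)
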