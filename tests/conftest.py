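import pytest

from equigait import (
    GaitParams,
    LamenessSpec,
    NOISELESS,
    NoiseSpec,
    simulate_trial,
)


@pytest.fixture(scope="session")
def sound_trial_cl():
    """Noiseless sound trot trial on the left circle (1800 frames, 30 fps)."""
    return simulate_trial(GaitParams(), LamenessSpec(), "CL", NOISELESS)


@pytest.fixture(scope="session")
def sound_trial_cr():
    return simulate_trial(GaitParams(), LamenessSpec(), "CR", NOISELESS)


@pytest.fixture(scope="session")
def noisy_sound_trial():
    """Sound trial with default pose-estimation noise, fixed seed."""
    return simulate_trial(GaitParams(), LamenessSpec(), "CL", NoiseSpec(seed=42))
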