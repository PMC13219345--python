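import numpy as np
import pytest
from hypothesis import settings

from hearsim import default_battery

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def battery():
    return default_battery()


def step_listener(location, correct_above=True, guess=0.0, lapse=0.0):
    """A near-deterministic listener: (in)correct depending on which side of
    ``location`` the stimulus falls, up to guess/lapse asymptotes."""
    from hearsim import HIGHER_EASIER, HIGHER_HARDER, PsychometricSpec

    return PsychometricSpec(
        location=location,
        slope=1e-6,
        guess_rate=guess,
        lapse_rate=lapse,
        direction=HIGHER_EASIER if correct_above else HIGHER_HARDER,
    )
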