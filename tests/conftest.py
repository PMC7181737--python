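import numpy as np
import pytest

import strokekin as sk
from strokekin.preprocess import differentiate, lowpass_two_way, resample_uniform


@pytest.fixture(scope="session")
def clean_trial():
    """A noise-free default drawing trial (full stops, no overlap)."""
    return sk.generate_target_trial(sk.TargetTrialPlan(), trial_id="clean")


@pytest.fixture(scope="session")
def clean_series(clean_trial):
    raw, _ = clean_trial
    return sk.smooth_with_splines(raw)


@pytest.fixture(scope="session")
def clean_segment(clean_series):
    return sk.detect_bounds(clean_series)


@pytest.fixture(scope="session")
def slow_program():
    """A low-frequency two-block stimulus program (about 40 s)."""
    return sk.StimulusProgram(blocks=((0.25, 10), (0.375, 15)), amplitude=100.0)


def analyze_follower(raw, stimulus, resample_hz=100.0):
    """The tracking preprocessing recipe: filter, differentiate, resample."""
    follower = resample_uniform(differentiate(lowpass_two_way(raw)), resample_hz)
    stim = resample_uniform(stimulus, resample_hz)
    return follower, stim


@pytest.fixture(scope="session")
def tracking_recipe():
    return analyze_follower
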