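import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cardiogate as cg

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def heart_video():
    """Noiseless default heart video (400 ms period, 30 fps, EF 20%)."""
    return cg.generate_heart_video(cg.HeartSimParams())


@pytest.fixture(scope="session")
def noisy_heart_video():
    return cg.generate_heart_video(cg.HeartSimParams(noise_sigma=0.05, seed=7))


@pytest.fixture(scope="session")
def reference_set(heart_video):
    video, _ = heart_video
    period = cg.estimate_period(video)
    return cg.build_reference(video, period, anchor_frame=0,
                              target_phase="end-diastole")


@pytest.fixture(scope="session")
def default_stack():
    """Noiseless default z-stack: 238 in-mask nuclei, 8 mitotic, 5 puncta."""
    return cg.generate_heart_stack(
        cg.StackSimParams(phh3_fraction=0.033, n_tunel_puncta=5, seed=1))
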