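import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_topographies():
    from eegstates.synthetic_data import make_state_topographies

    return make_state_topographies(16, 3, seed=1)


@pytest.fixture(scope="session")
def small_ground_truth():
    from eegstates.synthetic_data import make_ground_truth

    return make_ground_truth(3, 0.4, seed=2)


def make_recording(
    n_channels=16,
    K=3,
    duration=20.0,
    fs=500.0,
    noise_sd=0.3,
    n_bad=0,
    seed=7,
    dwell_mean=300.0,
    dwell_range=(200.0, 500.0),
):
    """Small synthetic recording with resolvable (>= filter-width) dwells."""
    from eegstates.recording import SubjectSpec
    from eegstates.synthetic_data import (
        make_ground_truth,
        make_state_topographies,
        sample_path_for_duration,
        synthesize_recording,
    )

    topos = make_state_topographies(n_channels, K, seed=seed)
    gt = make_ground_truth(K, 0.4, seed=seed + 1)
    spec = SubjectSpec(
        subject_id=f"T{seed:03d}",
        CA=12.5,
        BA=12.5,
        n_bad_channels=n_bad,
        seed=seed + 2,
        duration=duration,
        fs=fs,
    )
    path = sample_path_for_duration(
        gt, duration, fs, dwell_mean=dwell_mean, dwell_range=dwell_range, seed=seed + 3
    )
    rec = synthesize_recording(topos, path, fs=fs, noise_sd=noise_sd, spec=spec)
    return rec, topos, gt
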