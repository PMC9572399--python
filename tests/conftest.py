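import numpy as np
import pytest

from gescon.data import DEFAULT_VOCAB, GESTURES, GestureRecording
from gescon.synth import SubjectProfile, make_profile, simulate_subject

#: deterministic base for per-subject seeds used across the suite
SEED_BASE = 20220


@pytest.fixture(scope="session")
def vocab():
    return DEFAULT_VOCAB


@pytest.fixture(scope="session")
def separable_profile():
    return make_profile("separable", SEED_BASE)


@pytest.fixture(scope="session")
def separable_sessions(separable_profile):
    """One separable subject's (Data1, Data2) under the default protocol."""
    return simulate_subject(
        separable_profile, seed_pair=(SEED_BASE * 2 + 1, SEED_BASE * 2 + 2), subject_id="S0"
    )


@pytest.fixture(scope="session")
def planted_sessions():
    profile = make_profile("planted_confusion", SEED_BASE)
    d1, d2 = simulate_subject(
        profile, seed_pair=(SEED_BASE * 2 + 1, SEED_BASE * 2 + 2), subject_id="P0"
    )
    return profile, d1, d2


def grid_recording(labels, channels=None, subject_id="T", session_id="Data1", true_labels=None):
    """Hand-built recording on the 20 Hz grid for unit tests."""
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if channels is None:
        channels = np.full((n, 8), 100.0)
    return GestureRecording(
        subject_id=subject_id,
        session_id=session_id,
        times=np.arange(n) * 0.05,
        channels=np.asarray(channels, dtype=float),
        prompt_labels=labels,
        true_labels=None if true_labels is None else np.asarray(true_labels, dtype=object),
    )


def noise_free_profile(seed=0, n_gestures=10, relax_max=0.0, **overrides):
    """A zero-noise, deterministic-transition profile for exact-value tests."""
    rng = np.random.default_rng(seed)
    from gescon.synth import GestureSignature

    gestures = GESTURES[:n_gestures]
    means = rng.uniform(300.0, 900.0, size=(len(gestures) + 1, 8))
    sigs = {
        g: GestureSignature(mean=means[i], within_session_drift=np.zeros(8))
        for i, g in enumerate(gestures)
    }
    kwargs = dict(
        signatures=sigs,
        rest=means[-1],
        noise_sd=0.0,
        lag_range=(0.5, 0.5),
        ramp=0.4,
        relax_max=relax_max,
        artifact_rate=0.0,
        artifact_amplitude=0.0,
    )
    kwargs.update(overrides)
    return SubjectProfile(**kwargs)
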