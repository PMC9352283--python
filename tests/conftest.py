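"""Shared fixtures.

The full-scale identification experiment is expensive (minutes), so it runs
once per session and is shared by every test that inspects its reports.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from speckleheart.heartsound import generate_heart_sound, make_cohort
from speckleheart.identify import ExperimentProtocol, run_experiment
from speckleheart.pcg import bandpass, rescale_unit, segment

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cohort10():
    return make_cohort(10, seed=11)


@pytest.fixture(scope="session")
def pcg_segment(cohort10):
    """One band-passed, unit-rescaled 2.5 s phonocardiogram segment."""
    wave = generate_heart_sound(cohort10[0], 10.0, 1500.0, seed=2)
    return segment(rescale_unit(bandpass(wave)))[0]


@pytest.fixture(scope="session")
def full_experiment(cohort10):
    """The complete synthetic identification study at protocol scale:
    10 subjects, 4.5 min sessions (108 segments each, first 12 training),
    0.05 session perturbation with fresh speckle realizations, and a
    shuffled-label control."""
    protocol = ExperimentProtocol()
    return run_experiment(cohort10, protocol, seed=0)
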