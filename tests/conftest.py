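"""Shared fixtures: deterministic circuits, profiles and sessions.

Heavy simulations are session-scoped; tests must not mutate them.
"""

from __future__ import annotations

from dataclasses import replace

import pytest

from drivecog.synthetic import (
    CircuitConfig,
    CohortConfig,
    SubjectProfile,
    build_circuit,
    default_styles,
    generate_cohort,
    simulate_session,
)
from drivecog.synthetic.profiles import ZERO_NOISE


@pytest.fixture(scope="session")
def circuit():
    return build_circuit(CircuitConfig())


@pytest.fixture(scope="session")
def quiet_styles():
    """Default styles with lap-to-lap jitter disabled."""
    return {k: replace(v, jitter_cv=0.0) for k, v in default_styles().items()}


@pytest.fixture(scope="session")
def quiet_profile(quiet_styles):
    """Zero-noise, zero-jitter healthy subject."""
    return SubjectProfile(
        "S01", 72, "Male", "Healthy", styles=quiet_styles, noise=ZERO_NOISE
    )


@pytest.fixture(scope="session")
def quiet_session(quiet_profile, circuit):
    """One noiseless normal-condition recording of the full protocol."""
    return simulate_session(quiet_profile, circuit, "normal", seed=11)


@pytest.fixture(scope="session")
def noisy_subject_sessions(circuit):
    """Both conditions for one healthy subject at default noise."""
    profile = SubjectProfile("S01", 72, "Male", "Healthy")
    return [
        simulate_session(profile, circuit, cond, seed=100 + i)
        for i, cond in enumerate(("normal", "aggressive"))
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (4 healthy, 4 MCI, 3 laps) for fast end-to-end tests."""
    cfg = CohortConfig(
        n_healthy=4,
        n_mci=4,
        circuit=CircuitConfig(laps=3),
    )
    roster, sessions = generate_cohort(cfg, seed=5)
    return cfg, roster, sessions
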