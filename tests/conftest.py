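"""Shared fixtures: protocols, priors and session-cached trained rosters."""

import numpy as np
import pytest
from hypothesis import settings

from cbench.changes import default_roster, train_roster

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from cbench.protocol import two_shell_protocol
from cbench.tissue import PriorSet


@pytest.fixture(scope="session")
def protocol():
    """The full two-shell protocol (b = 7, 10; 90 directions; 18 b0)."""
    return two_shell_protocol()


@pytest.fixture(scope="session")
def small_protocol():
    """A cut-down protocol for walk tests (signal cost is per volume)."""
    return two_shell_protocol(n_directions=12, n_b0=2)


@pytest.fixture(scope="session")
def priors_exvivo():
    return PriorSet(with_ball=False)


@pytest.fixture(scope="session")
def priors_sim():
    return PriorSet(with_ball=True)


@pytest.fixture(scope="session")
def models_exvivo(protocol, priors_exvivo):
    """Trained roster for the ex-vivo variant (no ball); cached per session."""
    return train_roster(
        default_roster(priors_exvivo), priors_exvivo, protocol,
        n_samples=20_000, rng_seed=1234,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
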