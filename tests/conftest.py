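import numpy as np
import pytest

from opheno import SessionConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def fr5_config():
    """Long-protocol FR5 session: 25 min / 10 min / 25 min."""
    return SessionConfig(session_kind="fr", fixed_ratio=5)


@pytest.fixture
def short_fr_config():
    """Single 60-s pellet period, FR5 — compact worked-example geometry."""
    return SessionConfig(
        session_kind="fr",
        fixed_ratio=5,
        pellet_period_1_s=60.0,
        pellet_free_s=0.0,
        pellet_period_2_s=0.0,
    )


@pytest.fixture
def shock_config():
    return SessionConfig(session_kind="shock", fixed_ratio=5)
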