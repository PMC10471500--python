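import warnings

import numpy as np
import pandas as pd
import pytest

from econphys import synth

warnings.filterwarnings("ignore", message=".*Liblinear failed to converge.*")


@pytest.fixture(scope="session")
def small_session():
    """One modest two-region session reused across read-only tests."""
    cfg = synth.SimConfig(n_trials=120, n_units_per_region=12, rng_seed=42)
    return synth.gen_session(cfg)


@pytest.fixture
def hand_trials():
    """10-trial hand fixture: two filter violations, one wrong choice."""
    from econphys.recovery import hand_fixture_trials
    return hand_fixture_trials()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
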