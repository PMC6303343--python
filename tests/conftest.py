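import warnings

import numpy as np
import pytest

from dmnstab import make_coupled_study, simulate_bart_behavior
from dmnstab.config import TruthConfig

# empty-condition and low-pair warnings are expected in small fixtures
warnings.filterwarnings("ignore", message="condition .* has no events")
warnings.filterwarnings("ignore", message=".*usable pairs.*")


@pytest.fixture(scope="session")
def default_truth() -> TruthConfig:
    return TruthConfig()


@pytest.fixture(scope="session")
def small_sessions(default_truth):
    """Forty BART sessions at the study defaults (shared across tests)."""
    return simulate_bart_behavior(default_truth, 40, seed=7)


@pytest.fixture(scope="session")
def small_study(default_truth):
    """A compact coupled study (20 subjects) for pipeline-level tests."""
    return make_coupled_study(default_truth, 20, (180, 300), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
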