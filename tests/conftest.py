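import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

from reifold.fold_engine import default_model
from reifold.synthetic_data import gcn4_like_leader

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def gcn4_fixture():
    """The synthetic GCN4-uORF1-like study fixture (shared across tests)."""
    return gcn4_like_leader(seed=1)
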