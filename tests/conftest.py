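import numpy as np
import pytest

from lickdistract import SyntheticConfig, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def short_session():
    """One deterministic closed-loop session with ground truth."""
    cfg = SyntheticConfig(seed=11, session_length=600.0)
    train, events, manifest = generate_session(cfg)
    return cfg, train, events, manifest
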