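import numpy as np
import pytest

from wimotion import protocol_sim as ps


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_lossless_session():
    """5-slave, 5-second ideal session shared by several tests."""
    cfg = ps.SimConfig(
        n_slaves=5, session_duration_s=5.0,
        master_jitter_sigma_us=0.0, slave_jitter_sigma_us=0.0,
        csma_enabled=False, seed=1,
    )
    return ps.run_session(cfg)
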