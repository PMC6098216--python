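import numpy as np
import pytest

import fstseg


@pytest.fixture(scope="session")
def small_study():
    """A compact phantom study with a severe scanner gap (shared, read-only)."""
    cfg = fstseg.StudyConfig(n_train=2, n_test=2, n_pairs=2)
    return fstseg.generate_study(cfg, master_seed=11)


@pytest.fixture(scope="session")
def same_scanner_study():
    """A study whose two scanner models are identical."""
    cfg = fstseg.StudyConfig(
        n_train=2, n_test=1, n_pairs=2, scanner_b=fstseg.scanner_preset("reference")
    )
    return fstseg.generate_study(cfg, master_seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
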