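import numpy as np
import pytest

import capsmi as cm


@pytest.fixture(scope="session")
def strong_cfg() -> cm.SynthConfig:
    """Strong-effect fixture: deep contralateral ERD on moderate noise."""
    return cm.SynthConfig(erd_depth=0.8, noise_sd=0.3)


@pytest.fixture(scope="session")
def small_trialset(strong_cfg) -> cm.TrialSet:
    return cm.synthesize_dataset(strong_cfg, n_per_class=10, seed=42)


@pytest.fixture(scope="session")
def small_epochset(small_trialset) -> cm.EpochSet:
    return cm.build_epochset(small_trialset)


@pytest.fixture(scope="session")
def small_images(small_epochset) -> tuple[np.ndarray, np.ndarray]:
    return cm.epochs_to_images(small_epochset.data), small_epochset.labels
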