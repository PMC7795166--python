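import numpy as np
import pytest

import calfmotion as cm
from calfmotion import ethogram


@pytest.fixture(scope="session")
def small_dataset():
    """Six animals x 20 min at default regimes: quick but non-trivial."""
    cfg = cm.SimulationConfig(n_animals=6, duration_s=1200.0, seed=7)
    return cm.generate_dataset(cfg), cfg


@pytest.fixture(scope="session")
def small_features(small_dataset):
    dataset, _ = small_dataset
    frame = cm.build_feature_frame(dataset, window_s=3.0)
    return frame


@pytest.fixture(scope="session")
def catalogue():
    return cm.default_catalogue()


def single_state_config(behaviour: str, duration_s: float = 120.0, seed: int = 0,
                        **regime_kwargs) -> cm.SimulationConfig:
    """Config with one active state, for controlled signal checks."""
    regime = cm.BehaviourRegime(behaviour=behaviour, **regime_kwargs)
    prevalences = {b: 0.0 for b in ethogram.BEHAVIOURS}
    prevalences[behaviour] = 1.0
    return cm.SimulationConfig(
        n_animals=1,
        duration_s=duration_s,
        regimes={behaviour: regime},
        prevalences=prevalences,
        seed=seed,
    )
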