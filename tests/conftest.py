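import numpy as np
import pytest

from trimanus.config import SceneSpec, SessionConfig, periodic_schedule


@pytest.fixture
def short_config() -> SessionConfig:
    """A 12-s artifact-free session with two attention episodes."""
    return SessionConfig(
        seed=7,
        trial_duration=12.0,
        n_trials=2,
        attention_schedule=[(3.0, 2.5, 1.0), (8.0, 2.5, 1.0)],
        blink_rate_per_min=0.0,
        muscle_rate_per_min=0.0,
    )


@pytest.fixture
def default_config() -> SessionConfig:
    cfg = SessionConfig(seed=11)
    cfg.attention_schedule = periodic_schedule(duration=cfg.trial_duration)
    return cfg


@pytest.fixture
def scene() -> SceneSpec:
    return SceneSpec.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
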