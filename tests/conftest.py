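import numpy as np
import pytest

from artidelta.synthetic_data import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Desk-scale generator: small images, short questions, fast to render."""
    return GeneratorConfig(
        n_participants=2,
        n_trials_per_condition=3,
        image_height_px=32,
        image_width_px=64,
        seed=7,
    )


@pytest.fixture
def tiny_events(small_config, rng):
    from artidelta.synthetic_data import EARLY, sample_trial_timeline

    return sample_trial_timeline(small_config, EARLY, rng, participant_id=1, item_id=1)
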