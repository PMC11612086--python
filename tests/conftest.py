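import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_pipeline_config(seed=0):
    """A miniature end-to-end configuration for fast pipeline tests."""
    from sectorvit.pipeline import default_config

    cfg = default_config(seed=seed)
    cfg["sim"].update(n_patients=20, slices_per_patient=(4, 4), image_size=48, seed=seed)
    cfg["crop_size"] = 32
    cfg["test_fraction"] = 0.3
    cfg["bootstrap_B"] = 50
    cfg["model"].update(embed_dim=16, depth=1, head_dim=8, mlp_dim=16,
                        head_hidden_layers=2, patch_dim=128)
    cfg["train"].update(epochs=2, batch_size=16)
    cfg["importance"] = {"n_repeats": 5}
    return cfg
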