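import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import g2npan as g

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

# desk-scale protocol used by training-based tests: network widths small
# enough for CPU training but wide enough to learn the synthetic quality
# signal, and the lr-decay interval rescaled to desk batch counts (~10 epochs
# per decay step; the full-scale interval presumes far more batches per epoch)
DESK = dict(image_size=32, batch_size=16, gen_base_channels=8,
            disc_channels=(8, 16, 32, 32), aqa_base_width=8,
            aqa_stem_channels=8, aqa_hidden=32, decay_every_batches=150)


def desk_config(**overrides) -> g.TrainConfig:
    kw = {**DESK, **overrides}
    return g.TrainConfig(**kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_groups():
    """Six 5-variant groups at 32x32: the smallest dataset exercising color
    and grayscale scenes, tie-free references, and severity maps."""
    cfg = g.DatasetConfig(n_groups=6, n_variants=5, size=32, n_grayscale=2,
                          seed=3)
    return g.make_image_groups(cfg)
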