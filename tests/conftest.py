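import numpy as np
import pytest

import toothseg as ts


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 64x128 scene with every tooth present."""
    spec = ts.SyntheticSceneSpec(image_height=64, image_width=128, seed=1)
    return ts.generate_scene(spec)


@pytest.fixture(scope="session")
def tiny_net():
    return ts.SEIBEDNetwork(ts.NetworkConfig.tiny(), seed=0)


@pytest.fixture(scope="session")
def trained_tiny():
    """A quick 40-epoch fit on 4 small scenes, reused across tests."""
    samples = ts.sample_dataset(4, seed=3, image_height=64, image_width=128)
    model = ts.ToothSegmentation(
        samples,
        ts.NetworkConfig.tiny(),
        ts.TrainConfig(epochs=40, batch_size=2, learning_rate=3e-3, seed=0),
    )
    return model.fit(holdout=False)
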