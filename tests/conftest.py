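import numpy as np
import pytest

import adaptaug as aa
from adaptaug.data import GeneratorConfig, ImageVector


@pytest.fixture(scope="session")
def default_dataset() -> ImageVector:
    """25 synthetic 64×64 scenes under the package's default conditions."""
    return aa.generate_dataset(GeneratorConfig(image_size=64, n_images=25, seed=2))


@pytest.fixture(scope="session")
def default_split(default_dataset):
    return aa.split_dataset(default_dataset, 0.2, seed=0)


@pytest.fixture(scope="session")
def pretrained(default_split):
    """Converged surrogate on the default scenes, plus its snapshot blob."""
    pre, test = default_split
    model, _ = aa.pretrain("surrogate", pre, test, aa.TrainConfig(seed=0))
    return model, aa.snapshot(model)


@pytest.fixture(scope="session")
def easy_dataset() -> ImageVector:
    """Low-noise scenes on which the surrogate segments perfectly."""
    cfg = GeneratorConfig(image_size=64, n_images=16, seed=3,
                          hue_jitter=8, hue_shift=0)
    return aa.generate_dataset(cfg)


@pytest.fixture(scope="session")
def easy_split(easy_dataset):
    return aa.split_dataset(easy_dataset, 0.25, seed=0)


@pytest.fixture(scope="session")
def perfect_rust_model(easy_split):
    """A surrogate whose rust predictions exactly reproduce the labels."""
    pre, test = easy_split
    model, _ = aa.pretrain("surrogate", pre, test,
                           aa.TrainConfig(epochs=400, seed=0, target="rust"))
    for item in test:
        assert (aa.segbackend.predict(model, item.image) == item.rust_label).all()
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
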