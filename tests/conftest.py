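import numpy as np
import pytest

from echoflow.ode import OdeSolveConfig
from echoflow.phantom import PhantomConfig, generate_phantom, sample_clip
from echoflow.training import TrainConfig, train


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless 32×32 phantom, two regular cycles."""
    config = PhantomConfig(image_size=(32, 32), n_frames=24, base_period=12,
                           pulsation_amplitude=0.2, speckle_strength=0.0,
                           seed=7)
    return generate_phantom(config)


@pytest.fixture(scope="session")
def speckled_phantom():
    config = PhantomConfig(image_size=(32, 32), n_frames=24, base_period=12,
                           pulsation_amplitude=0.2, speckle_strength=0.3,
                           seed=11)
    return generate_phantom(config)


def _make_dataset(n_videos, seed0, policy, rng, image=32, n_frames=24,
                  period=12, speckle=0.3):
    ds, videos = [], []
    for k in range(n_videos):
        cfg = PhantomConfig(image_size=(image, image), n_frames=n_frames,
                            base_period=period, pulsation_amplitude=0.2,
                            speckle_strength=speckle, seed=seed0 + k)
        clip, ann = generate_phantom(cfg)
        labeled = int(rng.integers(7, clip.n_frames))
        ds.append(sample_clip(clip, ann, labeled, policy=policy, rng=rng))
        videos.append((clip, ann))
    return ds, videos


@pytest.fixture(scope="session")
def smoke_trained():
    """A briefly-trained small model shared by 'trained model' tests."""
    rng = np.random.default_rng(3)
    dataset, _ = _make_dataset(12, 500, "train", rng)
    config = TrainConfig(epochs=6, batch_size=4, width_scale=8,
                         solver=OdeSolveConfig(rtol=1e-3, atol=1e-3),
                         use_augmentation=False, seed=3)
    model, log = train(dataset, config)
    return model, log, config
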