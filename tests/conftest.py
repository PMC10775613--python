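import numpy as np
import pytest

from corneaseg.config import SlicConfig, SyntheticConfig, TrainConfig
from corneaseg.synthetic import generate_video


def small_video_config(**overrides) -> SyntheticConfig:
    """A scaled-down deformation video for fast end-to-end tests."""
    kwargs = dict(
        height=48,
        width=192,
        n_frames=4,
        band_thickness=8,
        apex_depression_max=5.0,
        noise_sigma=0.03,
        n_blob_artifacts=2,
        seed=0,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def small_clean_video():
    """Noise-free scaled-down video: band region == ground-truth mask."""
    cfg = small_video_config(noise_sigma=0.0, n_blob_artifacts=0, seed=1)
    video, gt = generate_video(cfg)
    return cfg, video, gt


@pytest.fixture(scope="session")
def small_noisy_video():
    cfg = small_video_config(seed=2)
    video, gt = generate_video(cfg)
    return cfg, video, gt


@pytest.fixture
def small_slic_cfg():
    # grid spacing ~6 px on 192x48 frames
    return SlicConfig(n_superpixels=256, compactness=10.0, n_iter=10)


@pytest.fixture
def fast_train_cfg():
    return TrainConfig(seed=0, max_epochs_first_frame=60, max_epochs_warm=20)


def random_blob_mask(rng: np.random.Generator, shape=(24, 24)) -> np.ndarray:
    """A random single-component, hole-free blob mask for boundary oracles."""
    from scipy import ndimage

    while True:
        seeds = np.zeros(shape, dtype=bool)
        n_seed = rng.integers(1, 4)
        seeds[
            rng.integers(4, shape[0] - 4, n_seed),
            rng.integers(4, shape[1] - 4, n_seed),
        ] = True
        blob = ndimage.binary_dilation(seeds, iterations=int(rng.integers(2, 6)))
        blob = ndimage.binary_fill_holes(blob)
        comp, n = ndimage.label(blob, structure=np.ones((3, 3), bool))
        if n >= 1:
            sizes = np.bincount(comp.ravel())[1:]
            blob = comp == (int(np.argmax(sizes)) + 1)
            return blob
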