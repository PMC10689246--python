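import numpy as np
import pytest

from speechenc import synthetic
from speechenc.datatypes import Segmentation


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_segmentation():
    """Hand-built segmentation: 4 phonemes grouped into 2 syllables."""
    return Segmentation(
        phoneme_bounds=[0, 5, 9, 14],
        syllable_bounds=[0, 9],
        labels=["s", "iy", "b", "aa"],
        n_frames=20,
    )


@pytest.fixture(scope="session")
def random_segmentations():
    """A batch of generated segmentations for property checks."""
    return synthetic.gen_segmentation(
        12, seed=7, phonemes_per_sentence=(4, 12),
        duration_params=synthetic.DurationSpec(median_ms=60, sigma=0.5))


@pytest.fixture(scope="session")
def small_features():
    return synthetic.gen_feature_stream(
        600, {"spectrogram": 8, "phonetic": 5}, seed=11)
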