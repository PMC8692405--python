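import numpy as np
import pytest

from wsus.phantom import GenerationConfig, LesionRanges, generate_images


@pytest.fixture(scope="session")
def easy64():
    """A small, strongly-contrasted 64x64 phantom set that is easy to learn.

    Benign and malignant lesions differ sharply in echogenicity as well as
    morphology, so a tiny classifier separates them within a few epochs.
    """
    cfg = GenerationConfig(
        height=64, width=64,
        counts={"train": (50, 50), "internal_val": (20, 20),
                "external_val": (5, 5)},
        tune_per_class=10,
        ranges=LesionRanges(size_range=(0.25, 0.45),
                            benign_offset=(-0.2, -0.1),
                            malignant_offset=(-0.9, -0.75),
                            malignant_posterior=(-0.6, -0.4),
                            malignant_posterior_prob=1.0),
    )
    images = list(generate_images(cfg, 123))
    return cfg, images


def split_arrays(images, split):
    X = np.stack([im.pixels for im in images if im.split == split]).astype(
        np.float32)
    y = np.array([im.label == "malignant" for im in images
                  if im.split == split], dtype=np.int64)
    return X, y
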