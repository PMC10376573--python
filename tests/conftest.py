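import numpy as np
import pytest

from octpyramid import (AEConfig, ScaleAdaptationAE, SyntheticSpec,
                        TINY_BACKBONE, build_backbone, generate_dataset)

# Small scales keep the training-path tests cheap; the arithmetic is
# identical to the default 224/112/56 configuration.
SMALL_SCALES = ((56, 56, 3), (28, 28, 3), (14, 14, 3))


@pytest.fixture(scope="session")
def small_dataset():
    """12 tiny synthetic B-scans (3 per class, 64x80)."""
    return generate_dataset(SyntheticSpec(n_per_class=3, image_height=64,
                                          image_width=80, seed=7))


@pytest.fixture(scope="session")
def tiny_backbone():
    return build_backbone(TINY_BACKBONE)


@pytest.fixture(scope="session")
def small_ae_config():
    return AEConfig(target_scales=SMALL_SCALES, base_channels=4, epochs=4,
                    batch_size=4, seed=11)


@pytest.fixture(scope="session")
def trained_small_ae(small_dataset, small_ae_config):
    return ScaleAdaptationAE(small_ae_config).fit(small_dataset.images)


@pytest.fixture(scope="session")
def blob_features():
    """Well-separated 4-class Gaussian blobs in 6 dimensions."""
    rng = np.random.default_rng(42)
    centers = np.eye(4, 6) * 12.0
    X, y = [], []
    for i, label in enumerate(("NORMAL", "CNV", "DME", "DRUSEN")):
        X.append(centers[i] + rng.normal(0, 0.3, size=(15, 6)))
        y += [label] * 15
    return np.vstack(X), np.asarray(y)
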