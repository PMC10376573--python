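"""Three-path feature pyramid and concatenation fusion.

One dense backbone per pyramid scale (independent weights by default — each
path is its own transfer-learned model; optionally shared) turns the
scale-adapted images into fixed-length global-pooled vectors, which are then
concatenated largest-scale-first into the fused predictor. With the
DenseNet201 reference topology each path yields 1920 features and the fused
vector has length 5760.

No per-scale standardisation is applied at fusion time: the fused vector is
the raw concatenation, and classifiers that are scale-sensitive standardise
on their own side (see :mod:`octpyramid.cascade`).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .backbone import (BackboneConfig, DenseFeatureExtractor, FeatureVector)
from .scale_adaptation import MultiScaleImage

__all__ = ["PyramidConfig", "FusedFeature", "PyramidFeatureExtractor",
           "extract_pyramid", "fuse"]


@dataclasses.dataclass(frozen=True)
class PyramidConfig:
    """Pyramid layout: which scales feed which backbone."""

    backbone_config: BackboneConfig = dataclasses.field(default_factory=BackboneConfig)
    scale_list: tuple[tuple[int, int, int], ...] = ((224, 224, 3), (112, 112, 3),
                                                    (56, 56, 3))
    share_weights: bool = False

    def __post_init__(self):
        if not self.scale_list:
            raise ValueError("scale_list must be non-empty")


@dataclasses.dataclass
class FusedFeature:
    """Concatenation of the per-scale feature vectors, fixed order."""

    values: np.ndarray
    component_lengths: list[int]
    source_scales: list[str]

    def __post_init__(self):
        if len(self.values) != sum(self.component_lengths):
            raise ValueError("fused length must equal the sum of components")


def fuse(vectors: list[FeatureVector]) -> FusedFeature:
    """Concatenate per-scale feature vectors in their given (scale) order."""
    if not vectors:
        raise ValueError("cannot fuse an empty list of feature vectors")
    return FusedFeature(
        values=np.concatenate([np.asarray(v.values) for v in vectors]),
        component_lengths=[v.length for v in vectors],
        source_scales=[v.scale_tag for v in vectors])


class PyramidFeatureExtractor(BaseEstimator, TransformerMixin):
    """Multi-scale feature pyramid as a scikit-learn transformer.

    ``fit`` builds one frozen backbone per scale (seeded ``random_state``,
    ``random_state + 1``, ... — or a single shared backbone);
    ``transform`` maps :class:`MultiScaleImage` inputs to an
    ``(n, sum of path widths)`` fused feature matrix.
    """

    def __init__(self, backbone_config: BackboneConfig | None = None,
                 n_scales: int = 3, share_weights: bool = False,
                 random_state: int = 0):
        self.backbone_config = backbone_config
        self.n_scales = n_scales
        self.share_weights = share_weights
        self.random_state = random_state

    def fit(self, X=None, y=None) -> "PyramidFeatureExtractor":
        cfg = self.backbone_config or BackboneConfig()
        if self.share_weights:
            shared = DenseFeatureExtractor.from_config(
                dataclasses.replace(cfg, seed=self.random_state))
            self.backbones_ = [shared] * self.n_scales
        else:
            self.backbones_ = [
                DenseFeatureExtractor.from_config(
                    dataclasses.replace(cfg, seed=self.random_state + i))
                for i in range(self.n_scales)]
        self.n_features_ = sum(b.terminal_channels_ for b in self.backbones_)
        return self

    def _check_built(self):
        if not hasattr(self, "backbones_"):
            self.fit()

    def extract_pyramid(self, multiscale: MultiScaleImage) -> list[FeatureVector]:
        """One tagged feature vector per configured scale."""
        self._check_built()
        if len(multiscale) != self.n_scales:
            have = set(multiscale.tags)
            missing = [f"scale {i}" for i in range(self.n_scales)
                       if i >= len(multiscale)]
            raise ValueError(
                f"expected {self.n_scales} scales, got {len(multiscale)} "
                f"(tags {sorted(have)}; missing {missing})")
        return [bb.extract(img, tag) for bb, img, tag in
                zip(self.backbones_, multiscale.scales, multiscale.tags)]

    def transform(self, X) -> np.ndarray:
        """List of :class:`MultiScaleImage` -> fused feature matrix."""
        self._check_built()
        rows = [fuse(self.extract_pyramid(ms)).values for ms in X]
        return np.stack(rows)


def extract_pyramid(multiscale: MultiScaleImage,
                    config: PyramidConfig, random_state: int = 0
                    ) -> list[FeatureVector]:
    """Functional wrapper: build a pyramid per ``config`` and extract once."""
    ext = PyramidFeatureExtractor(config.backbone_config,
                                  n_scales=len(config.scale_list),
                                  share_weights=config.share_weights,
                                  random_state=random_state).fit()
    return ext.extract_pyramid(multiscale)
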