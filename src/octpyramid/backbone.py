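"""DenseNet-style feature extractor with explicit channel bookkeeping.

A dense block stacks layers that each receive the concatenation of every
previous layer's output; layer ``l`` therefore sees

    FM(l) = k0 + k * (l - 1)

input channels, where ``k0`` is the block's input width and ``k`` the growth
rate. Each dense layer is BN -> ReLU -> 1x1 conv (bottleneck, width
``bottleneck_factor * k``) -> BN -> ReLU -> 3x3 conv (``k`` channels).
Transition layers (BN -> ReLU -> 1x1 conv -> 2x2 average pool) compress
channels by ``compression`` and halve the spatial size. A 7x7/stride-2 stem
convolution plus 3x3/stride-2 max pool precedes the first block; global
average pooling of the terminal map yields a fixed-length feature vector
whose length depends only on the topology, never on the input size.

The reference configuration is the DenseNet201 topology (growth rate 32, stem
64, blocks 6/12/48/32, compression 0.5), whose terminal width is 1920. The
extractor is frozen: weights are seeded random by default (sufficient for
desk-scale experiments — random convolutional features are still
discriminative) and pretrained weights can be loaded from a checkpoint.

The channel arithmetic is audited at run time: every dense layer asserts that
the tensor it receives has exactly the width the growth-rate formula
predicts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import DTYPE, BatchNorm2d, Conv2d, ReLU, AvgPool, max_pool

__all__ = ["BackboneConfig", "FeatureVector", "DenseFeatureExtractor",
           "feature_map_count", "build_backbone", "load_pretrained",
           "DENSENET201_CONFIG"]


def feature_map_count(k0: int, k: int, l: int) -> int:
    """Input feature maps of the l-th layer in a dense block: ``k0 + k(l-1)``.

    ``k0`` is the number of channels entering the block and ``k`` the growth
    rate; layer indices start at 1 (the first layer sees only the block
    input).
    """
    if l < 1:
        raise ValueError(f"layer index must be >= 1, got {l}")
    if k < 0 or k0 < 1:
        raise ValueError("require k >= 0 and k0 >= 1")
    return k0 + k * (l - 1)


@dataclasses.dataclass(frozen=True)
class BackboneConfig:
    """Topology of a dense backbone.

    Defaults give the DenseNet201 reference topology; tests use tiny
    configurations (e.g. growth 8, blocks (2, 2)) with identical arithmetic.
    """

    growth_rate: int = 32
    stem_channels: int = 64
    block_layers: tuple[int, ...] = (6, 12, 48, 32)
    compression: float = 0.5
    bottleneck_factor: int = 4
    input_shape: tuple[int, int, int] = (224, 224, 3)
    seed: int = 0

    def __post_init__(self):
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be >= 1")
        if not self.block_layers:
            raise ValueError("block_layers must be non-empty")
        if not (0.0 < self.compression <= 1.0):
            raise ValueError("compression must be in (0, 1]")
        if self.bottleneck_factor < 1:
            raise ValueError("bottleneck_factor must be >= 1")


DENSENET201_CONFIG = BackboneConfig()


@dataclasses.dataclass
class FeatureVector:
    """Global-pooled descriptor from one pyramid path."""

    values: np.ndarray
    scale_tag: str = ""

    @property
    def length(self) -> int:
        return int(self.values.shape[-1])


class _DenseLayer:
    def __init__(self, c_in: int, k: int, bf: int, rng, name: str):
        self.expected_in = c_in
        self.name = name
        width = bf * k
        self.bn1 = BatchNorm2d(c_in, name + ".bn1")
        self.conv1 = Conv2d(c_in, width, 1, rng, name=name + ".conv1")
        self.bn2 = BatchNorm2d(width, name + ".bn2")
        self.conv2 = Conv2d(width, k, 3, rng, name=name + ".conv2")
        self.relu = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.expected_in:
            raise RuntimeError(
                f"{self.name}: got {x.shape[1]} input channels, "
                f"growth-rate formula predicts {self.expected_in}")
        y = self.conv1(self.relu(self.bn1(x)))
        return self.conv2(self.relu(self.bn2(y)))

    def modules(self):
        return [self.bn1, self.conv1, self.bn2, self.conv2]


class _Transition:
    def __init__(self, c_in: int, c_out: int, rng, name: str):
        self.name = name
        self.bn = BatchNorm2d(c_in, name + ".bn")
        self.conv = Conv2d(c_in, c_out, 1, rng, name=name + ".conv")
        self.pool = AvgPool(2)
        self.relu = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] < 2 or x.shape[3] < 2:
            raise ValueError(f"{self.name}: spatial size {x.shape[2:]} too small to pool")
        return self.pool(self.conv(self.relu(self.bn(x))))

    def modules(self):
        return [self.bn, self.conv]


class DenseFeatureExtractor(BaseEstimator, TransformerMixin):
    """Frozen dense-connectivity feature extractor (scikit-learn transformer).

    ``fit`` builds the network with seeded random weights (it ignores ``X``
    and ``y`` — the extractor is not trained); ``transform`` maps a batch of
    images of any spatial size to an ``(n, terminal_channels_)`` matrix via
    global average pooling.
    """

    def __init__(self, growth_rate: int = 32, stem_channels: int = 64,
                 block_layers: tuple[int, ...] = (6, 12, 48, 32),
                 compression: float = 0.5, bottleneck_factor: int = 4,
                 random_state: int = 0):
        self.growth_rate = growth_rate
        self.stem_channels = stem_channels
        self.block_layers = block_layers
        self.compression = compression
        self.bottleneck_factor = bottleneck_factor
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    @classmethod
    def from_config(cls, config: BackboneConfig) -> "DenseFeatureExtractor":
        return cls(growth_rate=config.growth_rate,
                   stem_channels=config.stem_channels,
                   block_layers=tuple(config.block_layers),
                   compression=config.compression,
                   bottleneck_factor=config.bottleneck_factor,
                   random_state=config.seed).fit()

    def fit(self, X=None, y=None) -> "DenseFeatureExtractor":
        cfg = BackboneConfig(self.growth_rate, self.stem_channels,
                             tuple(self.block_layers), self.compression,
                             self.bottleneck_factor, seed=self.random_state)
        rng = np.random.default_rng(self.random_state)
        k, bf = cfg.growth_rate, cfg.bottleneck_factor
        self.stem_conv_ = Conv2d(3, cfg.stem_channels, 7, rng, stride=2, pad=3,
                                 name="stem.conv")
        self.stem_bn_ = BatchNorm2d(cfg.stem_channels, "stem.bn")
        self._relu = ReLU()
        self.blocks_: list[list[_DenseLayer]] = []
        self.transitions_: list[_Transition] = []
        ledger = []
        c = cfg.stem_channels
        for bi, n_layers in enumerate(cfg.block_layers):
            block, k0 = [], c
            for li in range(1, n_layers + 1):
                c_in = feature_map_count(k0, k, li)
                block.append(_DenseLayer(c_in, k, bf, rng,
                                         f"block{bi + 1}.layer{li}"))
                ledger.append((bi + 1, li, c_in))
            self.blocks_.append(block)
            c = k0 + k * n_layers
            if bi < len(cfg.block_layers) - 1:
                c_out = max(1, int(np.floor(c * cfg.compression)))
                self.transitions_.append(
                    _Transition(c, c_out, rng, f"transition{bi + 1}"))
                c = c_out
        self.final_bn_ = BatchNorm2d(c, "final.bn")
        self.terminal_channels_ = c
        self.n_features_ = c
        self.channel_ledger_ = ledger
        return self

    def _check_built(self):
        if not hasattr(self, "blocks_"):
            raise RuntimeError("backbone not built; call fit() first")

    # -- forward -----------------------------------------------------------

    def _forward_map(self, x: np.ndarray) -> np.ndarray:
        """NCHW input -> terminal NCHW feature map."""
        if x.shape[2] < 7 or x.shape[3] < 7:
            raise ValueError(f"input {x.shape[2:]} too small for the 7x7 stem")
        y = self._relu(self.stem_bn_(self.stem_conv_(x)))
        y = max_pool(y, 3, 2, 1)
        for bi, block in enumerate(self.blocks_):
            for layer in block:
                y = np.concatenate([y, layer.forward(y)], axis=1)
            if bi < len(self.transitions_):
                y = self.transitions_[bi].forward(y)
        return self._relu(self.final_bn_(y))

    def transform(self, X) -> np.ndarray:
        """Images (iterable of HxWx3 arrays in [0,1]) -> (n, L) features."""
        self._check_built()
        out = []
        for img in X:
            x = _to_nchw(img)
            fmap = self._forward_map(x)
            out.append(fmap.mean(axis=(2, 3))[0])
        return np.stack(out).astype(DTYPE)

    def extract(self, image: np.ndarray, scale_tag: str = "") -> FeatureVector:
        """Single-image convenience wrapper around :meth:`transform`."""
        return FeatureVector(self.transform([image])[0], scale_tag)

    # -- persistence -------------------------------------------------------

    def _modules(self):
        self._check_built()
        mods = [self.stem_conv_, self.stem_bn_]
        for block in self.blocks_:
            for layer in block:
                mods.extend(layer.modules())
        mods.extend(t_mod for t in self.transitions_ for t_mod in t.modules())
        mods.append(self.final_bn_)
        return mods

    def named_parameters(self) -> dict[str, np.ndarray]:
        named = {}
        for m in self._modules():
            for p in m.params():
                named[p.name] = p.value
            if isinstance(m, BatchNorm2d):
                named[m.gamma.name.rsplit(".", 1)[0] + ".running_mean"] = m.running_mean
                named[m.gamma.name.rsplit(".", 1)[0] + ".running_var"] = m.running_var
        return named

    def parameter_checksums(self) -> dict[str, float]:
        """Per-array sums; cheap fingerprint for determinism checks."""
        return {k: float(v.sum()) for k, v in self.named_parameters().items()}

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        cfg = dict(growth_rate=self.growth_rate, stem_channels=self.stem_channels,
                   block_layers=list(self.block_layers), compression=self.compression,
                   bottleneck_factor=self.bottleneck_factor,
                   random_state=self.random_state)
        with open(path, "wb") as fh:
            np.savez(fh, __config__=json.dumps(cfg), **self.named_parameters())
        return path


def _to_nchw(image: np.ndarray) -> np.ndarray:
    """HxW / HxWx1 / HxWx3 -> 1x3xHxW float32 (grayscale replicated)."""
    a = np.asarray(image, dtype=DTYPE)
    if a.ndim == 2:
        a = a[:, :, None]
    if a.ndim != 3:
        raise ValueError(f"expected HxW or HxWxC image, got shape {a.shape}")
    if a.shape[2] == 1:
        a = np.repeat(a, 3, axis=2)
    if a.shape[2] != 3:
        raise ValueError(f"expected 1 or 3 channels, got {a.shape[2]}")
    return a.transpose(2, 0, 1)[None]


def build_backbone(config: BackboneConfig) -> DenseFeatureExtractor:
    """Build a seeded, frozen backbone from a :class:`BackboneConfig`."""
    return DenseFeatureExtractor.from_config(config)


def load_pretrained(backbone: DenseFeatureExtractor, weights: str | Path
                    ) -> DenseFeatureExtractor:
    """Replace a built backbone's parameters from a saved ``.npz`` checkpoint.

    The checkpoint must match the topology exactly; the first mismatched or
    missing array is reported by name.
    """
    weights = Path(weights)
    if not weights.exists():
        raise FileNotFoundError(f"weights file not found: {weights}")
    current = backbone.named_parameters()
    with np.load(weights, allow_pickle=False) as archive:
        stored = {k: archive[k] for k in archive.files if k != "__config__"}
    for name in sorted(current):
        if name not in stored:
            raise ValueError(f"topology mismatch: checkpoint lacks array '{name}'")
        if stored[name].shape != current[name].shape:
            raise ValueError(
                f"topology mismatch at '{name}': checkpoint shape "
                f"{stored[name].shape}, model shape {current[name].shape}")
    for name, arr in current.items():
        arr[...] = stored[name].astype(arr.dtype)
    return backbone
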