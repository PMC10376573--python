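"""Autoencoder-based scale adaptation.

Pretrained backbones expect fixed input sizes, but OCT B-scans come in
whatever size the device produces, and naive interpolation discards detail.
This module trains a small convolutional autoencoder that maps an image of
*any* size to the three pyramid scales (by default 224x224x3, 112x112x3 and
56x56x3) while learning to keep reconstruction-relevant content.

Architecture (channels for ``base_channels = b``):

* encoder — ``encoder_stages`` repetitions of 3x3 conv + ReLU + 2x2 max pool
  (widths b, 2b, 4b, ...), then a 3x3 projection conv to 3 channels and a
  bilinear resize to the first target scale, producing the latent map
  ``F_AE`` (224x224x3 by default);
* processed branch — 3x3 conv -> ReLU -> stride-1 transposed 3x3 conv ->
  ReLU -> channel-expanding 3x3 conv to 12 channels (224x224x12);
* output heads — ``F_AE`` and the processed map are concatenated (15
  channels); a 3x3 conv yields the high-resolution output fed to the
  pyramid, and a parallel 3x3 conv followed by a bilinear resize back to the
  original input size yields the low-resolution reconstruction used only
  during training.

Training is unsupervised (labels are never consulted) with the combined
objective of :mod:`octpyramid.losses`: two pseudo-Huber terms on the
high-resolution side (output branch and ``F_AE``, both against an
antialiased downsample of the input) and one log-cosh term on the
reconstruction at the original size. Optimisation is Adam; every source of
randomness (weight init, shuffling) flows from the config seed, so runs are
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import (DTYPE, Adam, AvgPool, BilinearResize, Conv2d,
                  ConvTranspose2d, MaxPool2x2, ReLU)
from .losses import (combined_ae_loss, log_cosh_grad, pseudo_huber_grad)

__all__ = ["AEConfig", "AEOutputs", "MultiScaleImage", "ScaleAdaptationAE",
           "build_ae", "train_ae", "emit_pyramid", "ae_loss"]

_DEFAULT_SCALES = ((224, 224, 3), (112, 112, 3), (56, 56, 3))


@dataclasses.dataclass(frozen=True)
class AEConfig:
    """Hyperparameters of the scale-adaptation module."""

    target_scales: tuple[tuple[int, int, int], ...] = _DEFAULT_SCALES
    encoder_stages: int = 3
    base_channels: int = 8
    delta: float = 1.0              # pseudo-Huber transition scale
    loss_weights: tuple[float, float] = (1.0, 1.0)  # (w_hi, w_lo)
    epochs: int = 5
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not self.target_scales:
            raise ValueError("target_scales must be non-empty")
        sizes = [(h, w) for h, w, _ in self.target_scales]
        if any(a <= b for a, b in zip(sizes, sizes[1:])):
            raise ValueError("target_scales must be strictly decreasing")
        if any(h > 2048 or w > 2048 or h < 1 or w < 1
               for h, w in sizes):
            raise ValueError("target scales outside practical bounds")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        w_hi, w_lo = self.loss_weights
        if w_hi < 0 or w_lo < 0 or (w_hi == 0 and w_lo == 0):
            raise ValueError("loss_weights must be nonnegative, not both zero")
        if self.encoder_stages < 1 or self.base_channels < 1:
            raise ValueError("encoder_stages and base_channels must be >= 1")


@dataclasses.dataclass
class AEOutputs:
    """All four branch outputs of one forward pass (HWC arrays)."""

    f_ae: np.ndarray                  # (s0_h, s0_w, 3) latent feature map
    processed: np.ndarray             # (s0_h, s0_w, 12)
    high_res: np.ndarray              # (s0_h, s0_w, 3), fed to the pyramid
    low_res_reconstruction: np.ndarray  # (H, W, 3) at the original input size


@dataclasses.dataclass
class MultiScaleImage:
    """The calibrated pyramid inputs, largest scale first."""

    scales: list[np.ndarray]          # HWC arrays
    tags: list[str]

    def __iter__(self):
        return iter(self.scales)

    def __len__(self):
        return len(self.scales)


def _to_nchw3(image: np.ndarray) -> np.ndarray:
    a = np.asarray(image, dtype=DTYPE)
    if a.ndim == 2:
        a = a[:, :, None]
    if a.ndim != 3 or a.shape[2] not in (1, 3):
        raise ValueError(f"expected HxW or HxWx{{1,3}} image, got {a.shape}")
    if a.shape[2] == 1:
        a = np.repeat(a, 3, axis=2)
    return np.ascontiguousarray(a.transpose(2, 0, 1))[None]


def _target_hi(image_nchw: np.ndarray, s0: tuple[int, int]) -> np.ndarray:
    """Antialiased bilinear downsample of the input to the first scale."""
    img = image_nchw[0].transpose(1, 2, 0)
    t = _sk_resize(img, s0, order=1, anti_aliasing=img.shape[0] > s0[0],
                   preserve_range=True)
    return np.ascontiguousarray(t.transpose(2, 0, 1), dtype=DTYPE)[None]


class _AENet:
    """The parameterised graph; forward caches activations for backward."""

    def __init__(self, cfg: AEConfig):
        rng = np.random.default_rng(cfg.seed)
        b = cfg.base_channels
        s0h, s0w, _ = cfg.target_scales[0]
        self.cfg = cfg
        self.enc = []
        c = 3
        for i in range(cfg.encoder_stages):
            width = b * (2 ** i)
            self.enc.append((Conv2d(c, width, 3, rng, name=f"enc{i + 1}.conv"),
                             ReLU(), MaxPool2x2()))
            c = width
        self.proj = Conv2d(c, 3, 3, rng, name="proj.conv")
        self.resize_hi = BilinearResize(s0h, s0w)
        self.p1 = Conv2d(3, b, 3, rng, name="proc.conv1")
        self.r1 = ReLU()
        self.p2 = ConvTranspose2d(b, b, 3, rng, name="proc.tconv")
        self.r2 = ReLU()
        self.p3 = Conv2d(b, 12, 3, rng, name="proc.conv2")
        self.hi = Conv2d(15, 3, 3, rng, name="head.hi")
        self.lo = Conv2d(15, 3, 3, rng, name="head.lo")

    def params(self):
        ps = []
        for conv, _, _ in self.enc:
            ps.extend(conv.params())
        for m in (self.proj, self.p1, self.p2, self.p3, self.hi, self.lo):
            ps.extend(m.params())
        return ps

    def forward(self, x: np.ndarray):
        min_side = 2 ** self.cfg.encoder_stages
        if x.shape[2] < min_side or x.shape[3] < min_side:
            raise ValueError(
                f"input {x.shape[2:]} smaller than the encoder's minimum {min_side}")
        h = x
        for conv, relu, pool in self.enc:
            h = pool(relu(conv(h)))
        f_ae = self.resize_hi(self.proj(h))
        p = self.r1(self.p1(f_ae))
        p = self.r2(self.p2(p))
        processed = self.p3(p)
        cat = np.concatenate([f_ae, processed], axis=1)
        high = self.hi(cat)
        self._resize_lo = BilinearResize(x.shape[2], x.shape[3])
        low = self._resize_lo(self.lo(cat))
        return f_ae, processed, high, low

    def backward(self, g_high, g_fae_direct, g_low):
        g_cat = self.hi.backward(g_high)
        g_cat = g_cat + self.lo.backward(self._resize_lo.backward(g_low))
        g_fae = g_cat[:, :3] + g_fae_direct
        g = self.p3.backward(g_cat[:, 3:])
        g = self.p2.backward(self.r2.backward(g))
        g_fae = g_fae + self.p1.backward(self.r1.backward(g))
        g = self.proj.backward(self.resize_hi.backward(g_fae))
        for conv, relu, pool in reversed(self.enc):
            g = conv.backward(relu.backward(pool.backward(g)))
        return g


class ScaleAdaptationAE(BaseEstimator, TransformerMixin):
    """Scale-adaptation autoencoder as a scikit-learn transformer.

    ``fit(X)`` trains on a list of images (or a
    :class:`~octpyramid.synthetic.LabeledImageSet`, whose labels are
    ignored); ``transform(X)`` emits one :class:`MultiScaleImage` per input.
    ``build()`` initialises weights without training, which is all the shape
    contract requires.
    """

    def __init__(self, config: AEConfig | None = None):
        self.config = config

    @property
    def _cfg(self) -> AEConfig:
        return self.config if self.config is not None else AEConfig()

    def build(self) -> "ScaleAdaptationAE":
        self.net_ = _AENet(self._cfg)
        self.loss_history_ = []
        return self

    def _ensure_built(self):
        if not hasattr(self, "net_"):
            self.build()

    # -- forward / emission ------------------------------------------------

    def forward(self, image: np.ndarray) -> AEOutputs:
        """Run one image of any size through all four branches."""
        self._ensure_built()
        x = _to_nchw3(image)
        f_ae, processed, high, low = self.net_.forward(x)
        return AEOutputs(
            f_ae=f_ae[0].transpose(1, 2, 0),
            processed=processed[0].transpose(1, 2, 0),
            high_res=high[0].transpose(1, 2, 0),
            low_res_reconstruction=low[0].transpose(1, 2, 0))

    def emit_pyramid(self, image: np.ndarray) -> MultiScaleImage:
        """Emit the configured pyramid scales for one image.

        The largest scale is the high-resolution branch output (clipped to
        [0, 1]); smaller scales are derived from it by average pooling when
        the ratio is integral, otherwise by bilinear resizing.
        """
        self._ensure_built()
        cfg = self._cfg
        x = _to_nchw3(image)
        _, _, high, _ = self.net_.forward(x)
        high = np.clip(high, 0.0, 1.0)
        s0h, s0w, _ = cfg.target_scales[0]
        scales, tags = [], []
        for (h, w, _c) in cfg.target_scales:
            if (h, w) == (s0h, s0w):
                out = high
            elif s0h % h == 0 and s0w % w == 0 and s0h // h == s0w // w:
                out = AvgPool(s0h // h)(high)
            else:
                out = BilinearResize(h, w)(high)
            scales.append(out[0].transpose(1, 2, 0))
            tags.append(f"{h}x{w}")
        return MultiScaleImage(scales=scales, tags=tags)

    def transform(self, X) -> list[MultiScaleImage]:
        return [self.emit_pyramid(img) for img in _image_list(X)]

    # -- training ----------------------------------------------------------

    def fit(self, X, y=None) -> "ScaleAdaptationAE":
        """Train on images (labels, if any, are ignored — unsupervised)."""
        images = _image_list(X)
        if len(images) < 2:
            raise ValueError("training requires at least 2 images")
        self.build()
        cfg = self._cfg
        s0 = cfg.target_scales[0][:2]
        w_hi, w_lo = cfg.loss_weights

        xs = [_to_nchw3(img) for img in images]
        targets = [_target_hi(x, s0) for x in xs]
        opt = Adam(self.net_.params(), lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)

        # group by size so each batch is one array
        by_size: dict[tuple[int, int], list[int]] = {}
        for i, x in enumerate(xs):
            by_size.setdefault(x.shape[2:], []).append(i)

        for _epoch in range(cfg.epochs):
            losses, counts = [], []
            order = []
            for idxs in by_size.values():
                idxs = list(idxs)
                rng.shuffle(idxs)
                order.extend(idxs[i:i + cfg.batch_size]
                             for i in range(0, len(idxs), cfg.batch_size))
            for batch in order:
                x = np.concatenate([xs[i] for i in batch])
                t = np.concatenate([targets[i] for i in batch])
                f_ae, _proc, high, low = self.net_.forward(x)
                r_hi, r_fae, r_lo = high - t, f_ae - t, low - x
                loss = combined_ae_loss(high, f_ae, low, t, x,
                                        w_hi=w_hi, w_lo=w_lo, delta=cfg.delta)
                opt.zero_grad()
                g_hi = (w_hi / r_hi.size) * pseudo_huber_grad(r_hi, cfg.delta)
                g_fae = (w_hi / r_fae.size) * pseudo_huber_grad(r_fae, cfg.delta)
                g_lo = (w_lo / r_lo.size) * log_cosh_grad(r_lo)
                self.net_.backward(g_hi.astype(DTYPE), g_fae.astype(DTYPE),
                                   g_lo.astype(DTYPE))
                opt.step()
                losses.append(loss * len(batch))
                counts.append(len(batch))
            self.loss_history_.append(float(np.sum(losses) / np.sum(counts)))
        return self

    def training_loss(self, X) -> float:
        """Mean combined loss over images, without updating parameters."""
        self._ensure_built()
        cfg = self._cfg
        w_hi, w_lo = cfg.loss_weights
        s0 = cfg.target_scales[0][:2]
        vals = []
        for img in _image_list(X):
            x = _to_nchw3(img)
            t = _target_hi(x, s0)
            f_ae, _p, high, low = self.net_.forward(x)
            vals.append(combined_ae_loss(high, f_ae, low, t, x,
                                         w_hi=w_hi, w_lo=w_lo, delta=cfg.delta))
        return float(np.mean(vals))

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        self._ensure_built()
        path = Path(path)
        named = {p.name: p.value for p in self.net_.params()}
        cfg = dataclasses.asdict(self._cfg)
        cfg["target_scales"] = [list(s) for s in self._cfg.target_scales]
        with open(path, "wb") as fh:
            np.savez(fh, __config__=json.dumps(cfg),
                     __history__=np.asarray(self.loss_history_, dtype=float),
                     **named)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ScaleAdaptationAE":
        with np.load(Path(path), allow_pickle=False) as archive:
            cfg_d = json.loads(str(archive["__config__"]))
            cfg_d["target_scales"] = tuple(tuple(s) for s in cfg_d["target_scales"])
            cfg_d["loss_weights"] = tuple(cfg_d["loss_weights"])
            cfg = AEConfig(**cfg_d)
            ae = cls(cfg).build()
            ae.loss_history_ = list(archive["__history__"])
            named = {p.name: p for p in ae.net_.params()}
            for name, param in named.items():
                param.value[...] = archive[name].astype(param.value.dtype)
        return ae


def _image_list(X) -> list[np.ndarray]:
    if hasattr(X, "images"):  # LabeledImageSet
        return list(X.images)
    return list(X)


# -- thin functional surface -------------------------------------------------

def build_ae(config: AEConfig | None = None) -> ScaleAdaptationAE:
    """Build a seeded, untrained scale-adaptation module."""
    return ScaleAdaptationAE(config).build()


def train_ae(ae: ScaleAdaptationAE, images, config: AEConfig | None = None):
    """Train ``ae`` on images; returns ``(ae, loss_history)``."""
    if config is not None:
        ae.config = config
    ae.fit(images)
    return ae, list(ae.loss_history_)


def emit_pyramid(ae: ScaleAdaptationAE, image: np.ndarray) -> MultiScaleImage:
    return ae.emit_pyramid(image)


def ae_loss(outputs: AEOutputs, original: np.ndarray, target_hi: np.ndarray,
            config: AEConfig | None = None) -> float:
    """Combined loss of a forward pass against its targets (see module doc)."""
    cfg = config if config is not None else AEConfig()
    w_hi, w_lo = cfg.loss_weights
    orig = _to_nchw3(original)[0].transpose(1, 2, 0)
    tgt = np.asarray(target_hi, dtype=float)
    if tgt.ndim == 2:
        tgt = np.repeat(tgt[:, :, None], 3, axis=2)
    return combined_ae_loss(outputs.high_res, outputs.f_ae,
                            outputs.low_res_reconstruction, tgt, orig,
                            w_hi=w_hi, w_lo=w_lo, delta=cfg.delta)
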