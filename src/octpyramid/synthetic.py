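"""Synthetic retinal OCT B-scan generator.

Real B-scans show a stack of roughly horizontal reflective bands (the retinal
layers) over a dark vitreous, corrupted by multiplicative speckle. The four
UCSD-style classes differ in morphology, and the generator reproduces the
discriminative cue of each:

* ``NORMAL`` — smooth stacked bands only.
* ``CNV`` — a dome-shaped elevation of the deep bands (the RPE lifted by
  neovascular material), with moderately reflective tissue under the dome.
* ``DME`` — one or two dark intraretinal ellipses (fluid cysts).
* ``DRUSEN`` — small periodic bumps on the RPE band.

Geometry (band position, tilt, undulation, lesion size/location) is drawn per
image from a seeded RNG, so a :class:`SyntheticSpec` is a pure description:
the same spec always yields bit-identical images. Images are grayscale floats
in [0, 1]; channel replication for 3-channel backbones happens downstream.

This is a test-bed fixture generator, not a physical OCT simulator: speckle is
modelled as clipped multiplicative uniform noise and no device-specific
artifacts (shadowing, mirror images, motion) are emulated.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["SyntheticSpec", "LabeledImageSet", "generate_dataset",
           "write_folder_layout", "read_folder_layout", "DEFAULT_CLASSES"]

DEFAULT_CLASSES = ("NORMAL", "CNV", "DME", "DRUSEN")

# (start fraction within the retina, intensity) per sub-band, top to bottom.
_BANDS = ((0.00, 0.78), (0.12, 0.38), (0.26, 0.55), (0.48, 0.42),
          (0.64, 0.60), (0.80, 0.88))
_RPE = len(_BANDS) - 1  # index of the deep bright band the lesions deform


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Description of a synthetic dataset; a pure function input.

    The default canvas is 256x320 — deliberately different from every pyramid
    scale so the size-adaptation path is always exercised.
    """

    n_per_class: int = 50
    image_height: int = 256
    image_width: int = 320
    classes: tuple[str, ...] = DEFAULT_CLASSES
    noise_level: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("image dimensions must be positive")
        if not self.classes:
            raise ValueError("classes must be non-empty")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("classes must be unique")
        unknown = set(self.classes) - set(DEFAULT_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes (no generator): {sorted(unknown)}")
        if self.noise_level < 0:
            raise ValueError("noise_level must be nonnegative")


@dataclasses.dataclass
class LabeledImageSet:
    """Aligned images (HxW float arrays in [0,1]) and class labels."""

    images: list[np.ndarray]
    labels: list[str]
    layout_path: Path | None = None

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must be aligned")

    def __len__(self) -> int:
        return len(self.images)


def _bscan(h: int, w: int, rng: np.random.Generator, label: str,
           noise: float) -> np.ndarray:
    u = np.linspace(0.0, 1.0, w)
    rows = np.arange(h, dtype=float)[:, None]

    tilt = rng.uniform(-0.06, 0.06)
    top = h * (0.28 + tilt * (u - 0.5)
               + 0.03 * np.sin(2 * np.pi * (rng.uniform(0.5, 1.5) * u + rng.uniform(0, 1))))
    thick = h * rng.uniform(0.30, 0.40)

    # per-column row positions of band starts, plus the retina floor
    fracs = np.array([f for f, _ in _BANDS] + [1.0])
    bounds = top[None, :] + fracs[:, None] * thick  # (n_bands+1, w)

    if label == "CNV":
        c, s = rng.uniform(0.3, 0.7), rng.uniform(0.06, 0.12)
        dome = h * rng.uniform(0.08, 0.14) * np.exp(-0.5 * ((u - c) / s) ** 2)
        bounds[_RPE:, :] -= dome  # lift the RPE and the floor together
    elif label == "DRUSEN":
        n_bumps = rng.integers(6, 13)
        phase = rng.uniform(0, 2 * np.pi)
        bumps = h * rng.uniform(0.025, 0.045) * \
            np.maximum(0.0, np.sin(2 * np.pi * n_bumps * u + phase)) ** 2
        bounds[_RPE, :] -= bumps

    img = np.full((h, w), 0.06)
    for j, (_, val) in enumerate(_BANDS):
        mask = (rows >= bounds[j][None, :]) & (rows < bounds[j + 1][None, :])
        img[mask] = val
    if label == "CNV":
        # moderately reflective material filling the space under the dome
        floor0 = top + thick
        mask = (rows >= bounds[-1][None, :]) & (rows < floor0[None, :])
        img[mask] = 0.48
    # faint choroid decaying below the retina floor
    below = rows - np.maximum(bounds[-1], top + thick)[None, :]
    ch = (below > 0) & (below < 0.12 * h)
    img[ch] = np.maximum(img[ch], 0.22 * (1 - below[ch] / (0.12 * h)))

    if label == "DME":
        for _ in range(int(rng.integers(1, 3))):
            cy = top[w // 2] + thick * rng.uniform(0.35, 0.65)
            cx = w * rng.uniform(0.25, 0.75)
            ry = h * rng.uniform(0.05, 0.09)
            rx = w * rng.uniform(0.06, 0.12)
            cols = np.arange(w)[None, :]
            cyst = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0
            img[cyst] = 0.10

    img *= rng.uniform(0.9, 1.1)  # per-acquisition gain jitter
    if noise > 0:
        img = img * rng.uniform(1.0 - noise, 1.0 + noise, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(spec: SyntheticSpec) -> LabeledImageSet:
    """Generate a balanced labeled set: ``n_per_class`` images per class.

    Deterministic: the output is a pure function of ``spec`` (including the
    seed). Images are generated class by class in ``spec.classes`` order.
    """
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for label in spec.classes:
        for _ in range(spec.n_per_class):
            images.append(_bscan(spec.image_height, spec.image_width, rng,
                                 label, spec.noise_level))
            labels.append(label)
    return LabeledImageSet(images=images, labels=labels)


def write_folder_layout(dataset: LabeledImageSet, root: str | Path) -> Path:
    """Write ``root/<CLASS>/<index>.png`` (lossless 8-bit grayscale PNG).

    An empty dataset creates ``root`` with no files. Returns ``root``.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    counters: dict[str, int] = {}
    for img, label in zip(dataset.images, dataset.labels):
        d = root / label
        d.mkdir(exist_ok=True)
        i = counters.get(label, 0)
        counters[label] = i + 1
        arr = np.clip(np.asarray(img, dtype=float), 0, 1)
        Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(
            d / f"{i:04d}.png")
    dataset.layout_path = root
    return root


_IMAGE_EXT = {".png", ".jpg", ".jpeg"}


def read_folder_layout(root: str | Path) -> LabeledImageSet:
    """Read a folder-per-class layout back into a :class:`LabeledImageSet`.

    Labels are the subfolder names; traversal is sorted (deterministic). RGB
    files are converted to grayscale luminance; pixel values are scaled to
    [0, 1]. Raises if ``root`` contains no class subfolders; an unreadable
    image raises an error naming the file.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root not found: {root}")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subfolders under {root}")
    images, labels = [], []
    for d in class_dirs:
        for f in sorted(d.iterdir()):
            if f.suffix.lower() not in _IMAGE_EXT:
                continue
            try:
                with Image.open(f) as im:
                    arr = np.asarray(im.convert("L"), dtype=float) / 255.0
            except Exception as exc:  # noqa: BLE001 - re-raise with file name
                raise OSError(f"cannot read image {f}: {exc}") from exc
            images.append(arr)
            labels.append(d.name)
    return LabeledImageSet(images=images, labels=labels, layout_path=root)
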