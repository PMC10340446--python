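"""Seed-deterministic pseudo-radiograph generator.

Emulates the statistical structure the one-class framing relies on: a
"normal" class of smooth, reconstructible 64x64 grayscale images (two
bright elliptical lung fields over a darker torso gradient, plus pixel
noise), and an "anomalous" class that is identical except for a few
localized bright opacity blobs composited inside the lung fields —
pneumonia consolidations appear as bright opacities on a radiograph.

Determinism contract: generation is a pure function of the config,
including its seed. The seed is fanned into named substreams
(background, noise, blobs), so a zero-blob anomalous image is
pixel-identical to the normal image generated under the same seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

LABEL_POSITIVE = "PNEUMONIA"
LABEL_NEGATIVE = "NORMAL"


class SynthConfigError(ValueError):
    """A SynthConfig field violates its constraint."""


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters; defaults define the simulated study conditions.

    ``blob_contrast`` is the peak added intensity of an opacity blob;
    ``blob_radius_range`` / ``blob_count_range`` are inclusive intervals;
    ``noise_sd`` is the additive Gaussian pixel-noise standard deviation.
    """

    image_side: int = 64
    n_normal: int = 100
    n_anomalous: int = 100
    blob_count_range: tuple[int, int] = (1, 3)
    blob_radius_range: tuple[float, float] = (4.0, 9.0)
    blob_contrast: float = 0.4
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_side != 64:
            raise SynthConfigError(
                f"image_side is fixed at 64, got {self.image_side}")
        if self.n_normal < 0 or self.n_anomalous < 0:
            raise SynthConfigError("n_normal and n_anomalous must be >= 0")
        lo, hi = self.blob_count_range
        if not (0 <= lo <= hi):
            raise SynthConfigError(
                f"blob_count_range must be 0 <= lo <= hi, got {self.blob_count_range}")
        rlo, rhi = self.blob_radius_range
        if not (0 < rlo <= rhi):
            raise SynthConfigError(
                f"blob_radius_range must be 0 < lo <= hi, got {self.blob_radius_range}")
        if rhi > self.image_side / 2:
            raise SynthConfigError(
                f"blob radius {rhi} exceeds image_side/2 = {self.image_side / 2}")
        if not 0.0 < self.blob_contrast <= 1.0:
            raise SynthConfigError(
                f"blob_contrast must be in (0,1], got {self.blob_contrast}")
        if self.noise_sd < 0:
            raise SynthConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")


# Lung-field geometry in unit coordinates (x-center, y-center, x-semiaxis,
# y-semiaxis); two ellipses, the left one slightly larger (the heart
# shadow narrows the anatomical left lung, which sits on the image right).
_LUNGS = ((0.30, 0.48, 0.16, 0.28), (0.70, 0.48, 0.14, 0.28))


def lung_field_mask(side: int = 64) -> np.ndarray:
    """Boolean mask of the two elliptical lung fields (nominal geometry)."""
    yy, xx = np.mgrid[0:side, 0:side] / (side - 1)
    mask = np.zeros((side, side), dtype=bool)
    for cx, cy, ax, ay in _LUNGS:
        mask |= ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    return mask


def _streams(cfg: SynthConfig) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(cfg.seed)
    bg, noise, blobs = root.spawn(3)
    return {"background": np.random.default_rng(bg),
            "noise": np.random.default_rng(noise),
            "blobs": np.random.default_rng(blobs)}


def _background(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    side = cfg.image_side
    yy, xx = np.mgrid[0:side, 0:side] / (side - 1)
    base = 0.22 + 0.18 * yy  # torso gradient, brighter toward the abdomen
    img = base + rng.uniform(-0.02, 0.02)
    for cx, cy, ax, ay in _LUNGS:
        cx += rng.uniform(-0.015, 0.015)
        cy += rng.uniform(-0.015, 0.015)
        ax *= 1.0 + rng.uniform(-0.06, 0.06)
        ay *= 1.0 + rng.uniform(-0.06, 0.06)
        r2 = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
        amp = 0.32 + rng.uniform(-0.03, 0.03)
        img += amp * np.clip(1.0 - r2, 0.0, None) ** 0.5
    # mediastinum: a dim bright column between the lungs
    img += 0.10 * np.exp(-((xx - 0.5) / 0.07) ** 2) * np.exp(-((yy - 0.4) / 0.35) ** 2)
    return gaussian_filter(img, sigma=1.0)


def _blobs(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Additive opacity field for one anomalous image (may be all-zero)."""
    side = cfg.image_side
    lo, hi = cfg.blob_count_range
    count = int(rng.integers(lo, hi + 1))
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    overlay = np.zeros((side, side))
    for _ in range(count):
        cx, cy, ax, ay = _LUNGS[int(rng.integers(0, len(_LUNGS)))]
        # uniform point in the ellipse via rejection-free polar sampling
        t = rng.uniform(0, 2 * np.pi)
        r = np.sqrt(rng.uniform(0, 1)) * 0.8
        px = (cx + r * np.cos(t) * ax) * (side - 1)
        py = (cy + r * np.sin(t) * ay) * (side - 1)
        radius = rng.uniform(*cfg.blob_radius_range)
        d2 = (xx - px) ** 2 + (yy - py) ** 2
        profile = np.clip(1.0 - d2 / radius ** 2, 0.0, None)
        overlay = np.maximum(overlay, cfg.blob_contrast * profile)
    return overlay


def _generate(cfg: SynthConfig, n: int, with_blobs: bool) -> np.ndarray:
    streams = _streams(cfg)
    images = np.empty((n, cfg.image_side, cfg.image_side), dtype=np.float32)
    for i in range(n):
        img = _background(cfg, streams["background"])
        if with_blobs:
            img = img + _blobs(cfg, streams["blobs"])
        if cfg.noise_sd > 0:
            img = img + streams["noise"].normal(
                0.0, cfg.noise_sd, size=img.shape)
        images[i] = np.clip(img, 0.0, 1.0)
    return images


def generate_normal(cfg: SynthConfig) -> np.ndarray:
    """n_normal blob-free images, shape (n, 64, 64), values in [0,1]."""
    return _generate(cfg, cfg.n_normal, with_blobs=False)


def generate_anomalous(cfg: SynthConfig) -> np.ndarray:
    """n_anomalous images with opacity blobs inside the lung fields.

    Background and noise draws consume the same substreams as
    generate_normal, so with blob_count_range=(0,0) the output is
    pixel-identical to the normal images of the same config.
    """
    return _generate(cfg, cfg.n_anomalous, with_blobs=True)


def write_fixture_dataset(cfg: SynthConfig, destination) -> list[dict]:
    """Write the dataset as 8-bit grayscale PNGs under class directories.

    Layout is ``<destination>/<NORMAL|PNEUMONIA>/<name>.png`` plus a
    ``manifest.csv`` with columns path,label. Returns the manifest rows.
    """
    destination = Path(destination)
    try:
        destination.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create destination {destination}: {exc}") from exc
    manifest: list[dict] = []
    for label, images in ((LABEL_NEGATIVE, generate_normal(cfg)),
                          (LABEL_POSITIVE, generate_anomalous(cfg))):
        if len(images) == 0:
            continue
        subdir = destination / label
        subdir.mkdir(exist_ok=True)
        for i, img in enumerate(images):
            q = np.round(img * 255.0).astype(np.uint8)
            path = subdir / f"{label.lower()}_{i:05d}.png"
            Image.fromarray(q, mode="L").save(path)
            manifest.append({"path": str(path), "label": label})
    with open(destination / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["path", "label"])
        writer.writeheader()
        writer.writerows(manifest)
    return manifest
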