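"""Image loading, preprocessing and one-class split construction.

Radiographs are decoded to grayscale, resized to 64x64 (antialiased
bilinear resampling) and scaled to [0,1]. The one-class scenarios train
and validate on a single class, split 60/20/20, and use the entire
opposite class as additional test data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image, UnidentifiedImageError

from .synthetic import LABEL_NEGATIVE, LABEL_POSITIVE

logger = logging.getLogger(__name__)

IMAGE_SIDE = 64
IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}

Label = Literal["positive", "negative", "unknown"]

#: directory-name -> label mapping for the public chest X-ray layout
DEFAULT_LABEL_MAP = {LABEL_POSITIVE.lower(): "positive",
                     LABEL_NEGATIVE.lower(): "negative"}


class LoadError(RuntimeError):
    pass


class SplitError(ValueError):
    pass


@dataclass
class Radiograph:
    """One preprocessed 64x64 grayscale image with intensities in [0,1]."""

    pixels: np.ndarray
    source_id: str
    label: Label = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.shape != (IMAGE_SIDE, IMAGE_SIDE):
            raise ValueError(
                f"{self.source_id}: expected {IMAGE_SIDE}x{IMAGE_SIDE} pixels, "
                f"got {self.pixels.shape}")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError(f"{self.source_id}: intensities outside [0,1]")


@dataclass
class DatasetSplit:
    """One-class partitions: train/validation/test of the trained-on class
    plus the entire opposite class as test_other."""

    train: list[Radiograph]
    validation: list[Radiograph]
    test_same: list[Radiograph]
    test_other: list[Radiograph]
    scenario: Literal["train_pos", "train_neg"]

    @property
    def trained_label(self) -> Label:
        return "positive" if self.scenario == "train_pos" else "negative"


def preprocess_array(arr: np.ndarray, source_id: str = "",
                     label: Label = "unknown") -> Radiograph:
    """Resize an arbitrary grayscale array (any float in [0,1]) to 64x64."""
    arr = np.asarray(arr, dtype=np.float32)
    if arr.shape != (IMAGE_SIDE, IMAGE_SIDE):
        im = Image.fromarray(np.clip(arr, 0.0, 1.0), mode="F")
        im = im.resize((IMAGE_SIDE, IMAGE_SIDE), Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float32)
    return Radiograph(np.clip(arr, 0.0, 1.0), source_id, label)


def load_image(path, label: Label = "unknown") -> Radiograph:
    """Decode one PNG/JPEG to a preprocessed Radiograph.

    Multi-channel files are converted with the standard luminance
    weights; intensities are divided by the maximum representable value
    of the source bit depth.
    """
    path = Path(path)
    with Image.open(path) as im:
        if im.mode == "I;16":
            arr = np.asarray(im, dtype=np.float32) / 65535.0
            im = Image.fromarray(arr, mode="F")
        elif im.mode != "L":
            im = im.convert("L")
        if im.size != (IMAGE_SIDE, IMAGE_SIDE):
            im = im.resize((IMAGE_SIDE, IMAGE_SIDE), Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float32)
    if arr.max() > 1.0:  # 8-bit path
        arr = arr / 255.0
    return Radiograph(np.clip(arr, 0.0, 1.0), source_id=str(path), label=label)


def load_directory(root, label_map: dict[str, str] | None = None
                   ) -> list[Radiograph]:
    """Load every readable image under class-named subdirectories of root.

    Unreadable files are skipped with a logged warning; an empty or
    missing root raises LoadError.
    """
    root = Path(root)
    if not root.is_dir():
        raise LoadError(f"data root {root} is not a directory")
    label_map = {k.lower(): v for k, v in
                 (label_map or DEFAULT_LABEL_MAP).items()}
    images: list[Radiograph] = []
    skipped = 0
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        label = label_map.get(sub.name.lower(), "unknown")
        for path in sorted(sub.rglob("*")):
            if path.suffix.lower() not in IMAGE_SUFFIXES:
                continue
            try:
                images.append(load_image(path, label=label))
            except (OSError, UnidentifiedImageError) as exc:
                skipped += 1
                logger.warning("skipping unreadable image %s: %s", path, exc)
    if skipped:
        logger.warning("skipped %d unreadable image(s) under %s", skipped, root)
    if not images:
        raise LoadError(f"no images found under {root}")
    return images


def split_counts(n: int) -> tuple[int, int, int]:
    """60/20/20 partition counts with round-half-up, remainder to test."""
    if n < 5:
        raise ValueError(f"need at least 5 samples to split, got {n}")
    train_n = int(np.floor(0.6 * n + 0.5))
    val_n = int(np.floor(0.2 * n + 0.5))
    test_n = n - train_n - val_n
    if min(train_n, val_n, test_n) < 1:
        raise ValueError(f"degenerate split for n={n}")
    return train_n, val_n, test_n


def make_split(images: list[Radiograph],
               scenario: Literal["train_pos", "train_neg"],
               seed: int) -> DatasetSplit:
    """Shuffle the trained-on class and partition it 60/20/20.

    The entire opposite class becomes test_other. Deterministic in
    (images, seed).
    """
    if scenario not in ("train_pos", "train_neg"):
        raise SplitError(f"unknown scenario {scenario!r}")
    target: Label = "positive" if scenario == "train_pos" else "negative"
    other: Label = "negative" if scenario == "train_pos" else "positive"
    same = [im for im in images if im.label == target]
    rest = [im for im in images if im.label == other]
    if not same:
        raise SplitError(f"no {target} images to train on")
    if not rest:
        raise SplitError(f"no {other} images for the opposite-class test set")
    if len(same) < 5:
        raise SplitError(
            f"trained-on class needs >= 5 samples, got {len(same)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(same))
    shuffled = [same[i] for i in order]
    train_n, val_n, _ = split_counts(len(same))
    return DatasetSplit(
        train=shuffled[:train_n],
        validation=shuffled[train_n:train_n + val_n],
        test_same=shuffled[train_n + val_n:],
        test_other=list(rest),
        scenario=scenario,
    )


def stack_pixels(images: list[Radiograph]) -> np.ndarray:
    """(n, 64, 64) float32 array of a Radiograph collection."""
    return np.stack([im.pixels for im in images]).astype(np.float32)
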