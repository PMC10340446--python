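"""One-class training, reconstruction-error scoring and thresholding.

A model is trained on a single class with momentum SGD (initial learning
rate 0.1, momentum 0.9, decayed by 0.2 every 3 epochs, batch size 32,
10 epochs). The anomaly score of an image is its eval-mode mean squared
pixel error; the decision threshold is the maximum score over the
validation set, so every validation image is, by construction,
classified as belonging to the trained-on class (ties break
non-anomalous).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .data import DatasetSplit, Radiograph, stack_pixels
from . import layers as _L
from .models import (EPS, AnyAutoencoder, VariationalConvAutoencoder,
                     corrupt_zero_mask)


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer schedule; defaults are the reference training settings."""

    initial_lr: float = 0.1
    momentum: float = 0.9
    decay_every: int = 3
    decay_factor: float = 0.2
    batch_size: int = 32
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_lr <= 0 or self.decay_factor <= 0:
            raise ValueError("learning rates must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError(f"momentum must be in [0,1), got {self.momentum}")
        if self.decay_every < 1 or self.batch_size < 1:
            raise ValueError("decay_every and batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for 0-based epoch index e: lr0 * f^(e // every)."""
        return self.initial_lr * self.decay_factor ** (epoch // self.decay_every)


@dataclass
class AnomalyDecision:
    source_id: str
    error: float
    threshold: float
    is_anomaly: bool
    predicted_label: Literal["positive", "negative"]


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss: float
    val_loss: float


# -- batch objective and gradients ---------------------------------------

def _batch_step(model: AnyAutoencoder, xb: np.ndarray,
                rng_corrupt: np.random.Generator,
                rng_reparam: np.random.Generator) -> dict[str, float]:
    """Forward + backward for one batch; leaves gradients on the layers.

    The objective is the variant cost divided by B*u (per-sample,
    per-pixel mean), which keeps the step size of the 0.1 learning rate
    well-scaled; the beta/gamma weightings relative to the
    reconstruction term are unchanged.
    """
    spec = model.spec
    B, H, W, _ = xb.shape
    u = H * W
    scale = 1.0 / (B * u)
    if isinstance(model, VariationalConvAutoencoder):
        y = model.forward(xb, train=True, rng=rng_reparam)
        mu, lv = model.mu, model.logvar
        recon = float(np.sum((xb - y) ** 2))
        kl = float(0.5 * np.sum(mu.astype(np.float64) ** 2
                                + np.exp(lv, dtype=np.float64) - 1.0 - lv))
        loss = (recon + spec.beta * kl) * scale
        dy = (2.0 * (y - xb) * scale).astype(_L.DTYPE)
        dmu = (spec.beta * scale * mu).astype(_L.DTYPE)
        dlv = (spec.beta * scale * 0.5 * (np.exp(lv) - 1.0)).astype(_L.DTYPE)
        model.backward(dy, dmu_extra=dmu, dlogvar_extra=dlv)
        return {"loss": loss, "reconstruction": recon * scale,
                "kl": spec.beta * kl * scale}

    x_in = xb
    if spec.variant == "dcae":
        x_in = corrupt_zero_mask(xb, spec.sigma, rng_corrupt)
    y = model.forward(x_in, train=True)
    recon = float(np.sum((xb - y) ** 2))
    dy = (2.0 * (y - xb) * scale).astype(_L.DTYPE)
    dlatent = None
    sparsity = 0.0
    if spec.variant == "scae":
        latent = model.latent
        m = latent.mean(axis=(0, 1, 2), dtype=np.float64)
        zbar = np.clip(1.0 / (1.0 + np.exp(-m)), EPS, 1.0 - EPS)
        z = spec.z
        kl = z * np.log(z / zbar) + (1 - z) * np.log((1 - z) / (1 - zbar))
        sparsity = spec.gamma * float(np.sum(kl)) / u
        dkl_dzbar = -z / zbar + (1 - z) / (1 - zbar)
        per_map = (spec.gamma / u) * dkl_dzbar * zbar * (1 - zbar) \
            / (latent.shape[0] * latent.shape[1] * latent.shape[2])
        dlatent = np.broadcast_to(
            per_map.astype(_L.DTYPE)[None, None, None, :], latent.shape)
    model.backward(dy, dlatent=dlatent)
    return {"loss": recon * scale + sparsity,
            "reconstruction": recon * scale, "sparsity": sparsity}


def _sgd_update(params: list[tuple[np.ndarray, np.ndarray]],
                velocity: list[np.ndarray], lr: float, momentum: float) -> None:
    for (p, g), v in zip(params, velocity):
        v *= momentum
        v -= lr * g
        p += v


def train(model: AnyAutoencoder, split: DatasetSplit, cfg: TrainingConfig
          ) -> tuple[AnyAutoencoder, list[EpochRecord]]:
    """Momentum-SGD training on the split's single-class training set.

    Returns the trained model (updated in place) and the per-epoch log of
    learning rate, mean training loss and validation loss. No early
    stopping is applied.
    """
    if not split.train:
        raise ValueError("training partition is empty")
    labels = {im.label for im in split.train}
    if len(labels) != 1:
        raise ValueError(f"training partition mixes labels: {sorted(labels)}")
    x_train = stack_pixels(split.train)[..., None]
    x_val = stack_pixels(split.validation) if split.validation else None

    ss = np.random.SeedSequence(cfg.seed)
    s_shuffle, s_corrupt, s_reparam = (np.random.default_rng(c)
                                       for c in ss.spawn(3))
    params = model.parameters()
    velocity = [np.zeros_like(p) for p, _ in params]
    n = x_train.shape[0]
    log: list[EpochRecord] = []
    for epoch in range(cfg.epochs):
        lr = cfg.lr_at(epoch)
        order = s_shuffle.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            terms = _batch_step(model, x_train[idx], s_corrupt, s_reparam)
            if not np.isfinite(terms["loss"]):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}")
            _sgd_update(params, velocity, lr, cfg.momentum)
            losses.append(terms["loss"])
        val = (float(np.mean(reconstruction_errors(model, x_val)))
               if x_val is not None else float("nan"))
        log.append(EpochRecord(epoch=epoch, lr=lr,
                               train_loss=float(np.mean(losses)), val_loss=val))
    return model, log


# -- scoring and classification ------------------------------------------

def reconstruction_errors(model: AnyAutoencoder, images: np.ndarray,
                          batch_size: int = 64) -> np.ndarray:
    """Eval-mode mean squared pixel error per image; deterministic."""
    images = np.asarray(images, dtype=_L.DTYPE)
    if images.ndim == 2:
        images = images[None]
    if images.ndim == 3:
        images = images[..., None]
    out = np.empty(images.shape[0], dtype=np.float64)
    for start in range(0, images.shape[0], batch_size):
        xb = images[start:start + batch_size]
        if isinstance(model, VariationalConvAutoencoder):
            y = model.forward(xb, train=False)
        else:
            y = model.forward(xb, train=False)
        out[start:start + xb.shape[0]] = \
            np.mean((xb.astype(np.float64) - y) ** 2, axis=(1, 2, 3))
    return out


def reconstruction_error(model: AnyAutoencoder, x: Radiograph | np.ndarray
                         ) -> float:
    """Anomaly score of one image: eval-mode mean squared pixel error."""
    pixels = x.pixels if isinstance(x, Radiograph) else np.asarray(x)
    return float(reconstruction_errors(model, pixels[None])[0])


def fit_threshold(model: AnyAutoencoder,
                  validation: list[Radiograph] | np.ndarray) -> float:
    """Decision threshold: the maximum validation reconstruction error."""
    if isinstance(validation, list):
        if not validation:
            raise ValueError("validation set is empty")
        validation = stack_pixels(validation)
    validation = np.asarray(validation)
    if validation.size == 0:
        raise ValueError("validation set is empty")
    return float(np.max(reconstruction_errors(model, validation)))


def classify(model: AnyAutoencoder, threshold: float,
             images: list[Radiograph],
             scenario: Literal["train_pos", "train_neg"]
             ) -> list[AnomalyDecision]:
    """Binary calls: an image is anomalous iff its error exceeds the
    threshold (ties are non-anomalous); the predicted label is the
    trained-on class unless the image is anomalous."""
    trained = "positive" if scenario == "train_pos" else "negative"
    other = "negative" if scenario == "train_pos" else "positive"
    if not images:
        return []
    errors = reconstruction_errors(model, stack_pixels(images))
    decisions = []
    for im, err in zip(images, errors):
        is_anom = bool(err > threshold)
        decisions.append(AnomalyDecision(
            source_id=im.source_id, error=float(err), threshold=threshold,
            is_anomaly=is_anom,
            predicted_label=other if is_anom else trained))
    return decisions
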