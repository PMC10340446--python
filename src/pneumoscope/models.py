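"""Convolutional autoencoder variants for one-class radiograph scoring.

Four variants share one convolutional backbone and differ only in their
training objective:

``pcae``
    plain reconstruction (squared error, or Bernoulli cross-entropy).
``dcae``
    denoising: training inputs are corrupted by zero-masking (each pixel
    independently set to 0 with probability ``sigma``) while the clean
    image remains the target.
``scae``
    sparse: a Bernoulli KL penalty pulls the mean activation of each
    latent feature map toward a small target ``z``, weighted by ``gamma``.
``bvcae``
    beta-variational: the encoder maps to a Gaussian posterior
    ``(mu, log sigma^2)`` over a ``latent_dim``-dimensional code; the KL
    to the isotropic unit-Gaussian prior is weighted by ``beta``
    (``beta=1`` recovers the conventional VAE).

The backbone has two or four hidden 3x3 conv layers (16,16 or
32,16,16,32 filters), ReLU activations, and a single-filter sigmoid
output layer reconstructing the input, so hidden feature maps keep the
full 64x64 extent. The variational variant inserts a dense head at the
midpoint of the stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import layers as _L
from .layers import Conv3x3, Dense, Layer, ReLU, Sigmoid, parameters_of

EPS = 1e-7

VARIANTS = ("pcae", "dcae", "scae", "bvcae")
HIDDEN_FILTERS = {2: (16, 16), 4: (32, 16, 16, 32)}
CHECKPOINT_FORMAT = "pneumoscope-ckpt-1"


class SpecError(ValueError):
    """Invalid model specification."""


@dataclass(frozen=True)
class ModelSpec:
    """Which autoencoder variant to build, and its hyperparameters.

    Only the hyperparameters of the chosen variant are meaningful:
    ``sigma`` (corruption probability) for dcae, ``z``/``gamma``
    (sparsity target and weight) for scae, ``beta``/``latent_dim`` for
    bvcae.
    """

    variant: Literal["pcae", "dcae", "scae", "bvcae"] = "pcae"
    n_hidden_layers: int = 2
    reconstruction_loss: Literal["mse", "bernoulli_ce"] = "mse"
    sigma: float = 0.1
    z: float = 0.3
    gamma: float = 0.1
    beta: float = 1.0
    latent_dim: int = 32

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise SpecError(f"unknown variant {self.variant!r}")
        if self.n_hidden_layers not in HIDDEN_FILTERS:
            raise SpecError(
                f"n_hidden_layers must be 2 or 4, got {self.n_hidden_layers}")
        if self.reconstruction_loss not in ("mse", "bernoulli_ce"):
            raise SpecError(
                f"unknown reconstruction loss {self.reconstruction_loss!r}")
        if not 0.0 <= self.sigma <= 1.0:
            raise SpecError(f"sigma must be in [0,1], got {self.sigma}")
        if not 0.0 < self.z < 1.0:
            raise SpecError(f"sparsity target z must be in (0,1), got {self.z}")
        if self.gamma < 0:
            raise SpecError(f"gamma must be >= 0, got {self.gamma}")
        if self.beta < 0:
            raise SpecError(f"beta must be >= 0, got {self.beta}")
        if self.variant == "bvcae" and self.latent_dim < 1:
            raise SpecError(
                f"latent_dim must be a positive integer, got {self.latent_dim}")

    @property
    def hidden_filters(self) -> tuple[int, ...]:
        return HIDDEN_FILTERS[self.n_hidden_layers]

    @property
    def kernel_side(self) -> int:
        return 3

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "n_hidden_layers": self.n_hidden_layers,
            "reconstruction_loss": self.reconstruction_loss,
            "sigma": self.sigma, "z": self.z, "gamma": self.gamma,
            "beta": self.beta, "latent_dim": self.latent_dim,
        }


@dataclass
class Reconstruction:
    """Output of a single forward pass through an autoencoder."""

    output: np.ndarray
    latent_summary: dict = field(default_factory=dict)
    per_sample_loss_terms: dict = field(default_factory=dict)


def _as_batch(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=_L.DTYPE)
    if x.ndim == 2:
        x = x[None, :, :, None]
    elif x.ndim == 3:
        x = x[..., None]
    elif x.ndim != 4:
        raise ValueError(f"expected HxW, NxHxW or NxHxWxC input, got {x.shape}")
    return x


def corrupt_zero_mask(x: np.ndarray, sigma: float,
                      rng: np.random.Generator | int) -> np.ndarray:
    """Zero-masking corruption: each pixel is zeroed with probability sigma."""
    if not 0.0 <= sigma <= 1.0:
        raise ValueError(f"sigma must be in [0,1], got {sigma}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=_L.DTYPE)
    mask = (rng.random(x.shape) >= sigma).astype(_L.DTYPE)
    return x * mask


class ConvAutoencoder:
    """Backbone for the pcae / dcae / scae variants.

    The "latent" used by the sparsity penalty is the ReLU output of the
    middle hidden layer (the encoder's last feature maps).
    """

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        self.spec = spec
        filters = spec.hidden_filters
        chans = [1, *filters, 1]
        self.layers: list[Layer] = []
        for i in range(len(chans) - 1):
            self.layers.append(Conv3x3(chans[i], chans[i + 1], rng))
            self.layers.append(
                Sigmoid() if i == len(chans) - 2 else ReLU())
        # layer index (exclusive) up to which the encoder runs
        self._latent_after = 2 * (spec.n_hidden_layers // 2)
        self._latent: np.ndarray | None = None

    # -- introspection ----------------------------------------------------
    def n_params(self) -> int:
        return sum(p.size for p, _ in parameters_of(self.layers))

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return parameters_of(self.layers)

    # -- passes -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        for i, layer in enumerate(self.layers):
            h = layer.forward(h, train)
            if i == self._latent_after - 1:
                self._latent = h
        return h

    @property
    def latent(self) -> np.ndarray:
        """Middle-layer activations of the most recent forward pass."""
        assert self._latent is not None
        return self._latent

    def backward(self, dy: np.ndarray,
                 dlatent: np.ndarray | None = None) -> np.ndarray:
        g = dy
        for i in range(len(self.layers) - 1, -1, -1):
            if dlatent is not None and i == self._latent_after - 1:
                g = g + dlatent
            g = self.layers[i].backward(g)
        return g


class VariationalConvAutoencoder:
    """bvcae backbone: conv encoder, dense Gaussian head, conv decoder.

    The encoder's flattened feature maps feed two dense layers producing
    mu and log-variance; the decoder starts from a dense layer mapping
    the latent sample back to the midpoint feature-map shape.
    """

    def __init__(self, spec: ModelSpec, rng: np.random.Generator,
                 image_side: int = 64):
        self.spec = spec
        filters = spec.hidden_filters
        half = len(filters) // 2
        self.enc_layers: list[Layer] = []
        chans = [1, *filters[:half]]
        for i in range(len(chans) - 1):
            self.enc_layers.append(Conv3x3(chans[i], chans[i + 1], rng))
            self.enc_layers.append(ReLU())
        self.mid_shape = (image_side, image_side, filters[half - 1])
        flat = int(np.prod(self.mid_shape))
        self.fc_mu = Dense(flat, spec.latent_dim, rng)
        self.fc_logvar = Dense(flat, spec.latent_dim, rng)
        self.fc_dec = Dense(spec.latent_dim, flat, rng)
        self.dec_relu = ReLU()
        self.dec_layers: list[Layer] = []
        chans = [filters[half - 1], *filters[half:], 1]
        for i in range(len(chans) - 1):
            self.dec_layers.append(Conv3x3(chans[i], chans[i + 1], rng))
            self.dec_layers.append(
                Sigmoid() if i == len(chans) - 2 else ReLU())
        self._cache: dict | None = None
        self.mu: np.ndarray | None = None
        self.logvar: np.ndarray | None = None

    def _all_layers(self) -> list[Layer]:
        return [*self.enc_layers, self.fc_mu, self.fc_logvar,
                self.fc_dec, self.dec_relu, *self.dec_layers]

    def n_params(self) -> int:
        return sum(p.size for p, _ in parameters_of(self._all_layers()))

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return parameters_of(self._all_layers())

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        B = x.shape[0]
        h = x
        for layer in self.enc_layers:
            h = layer.forward(h, train)
        flat = h.reshape(B, -1)
        mu = self.fc_mu.forward(flat, train)
        logvar = self.fc_logvar.forward(flat, train)
        if train:
            if rng is None:
                raise ValueError("train-mode forward needs an rng for the "
                                 "reparameterization sample")
            eps = rng.standard_normal(mu.shape).astype(_L.DTYPE)
            std = np.exp(0.5 * logvar, dtype=_L.DTYPE)
            zlat = mu + eps * std
        else:
            eps = std = None
            zlat = mu
        d = self.fc_dec.forward(zlat, train)
        d = self.dec_relu.forward(d, train)
        h = d.reshape(B, *self.mid_shape)
        for layer in self.dec_layers:
            h = layer.forward(h, train)
        self.mu, self.logvar = mu, logvar
        if train:
            self._cache = {"eps": eps, "std": std, "B": B}
        return h

    def backward(self, dy: np.ndarray,
                 dmu_extra: np.ndarray | None = None,
                 dlogvar_extra: np.ndarray | None = None) -> np.ndarray:
        assert self._cache is not None
        B = self._cache["B"]
        g = dy
        for layer in reversed(self.dec_layers):
            g = layer.backward(g)
        g = g.reshape(B, -1)
        g = self.dec_relu.backward(g)
        dz = self.fc_dec.backward(g)
        dmu = dz if dmu_extra is None else dz + dmu_extra
        dlv = dz * self._cache["eps"] * 0.5 * self._cache["std"]
        if dlogvar_extra is not None:
            dlv = dlv + dlogvar_extra
        dflat = self.fc_mu.backward(dmu) + self.fc_logvar.backward(dlv)
        g = dflat.reshape(B, *self.mid_shape)
        for layer in reversed(self.enc_layers):
            g = layer.backward(g)
        self._cache = None
        return g


AnyAutoencoder = ConvAutoencoder | VariationalConvAutoencoder


def build_model(spec: ModelSpec, seed: int) -> AnyAutoencoder:
    """Construct a variant with deterministic Glorot initialisation."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if spec.variant == "bvcae":
        return VariationalConvAutoencoder(spec, rng)
    return ConvAutoencoder(spec, rng)


def reconstruct(model: AnyAutoencoder, x: np.ndarray,
                mode: Literal["train", "eval"] = "eval",
                seed: int | np.random.Generator | None = None) -> Reconstruction:
    """Single forward pass; applies the variant's train-time stochasticity.

    In train mode a dcae input is corrupted by zero-masking and a bvcae
    latent is sampled via the reparameterization trick; in eval mode both
    are deterministic (no corruption, latent fixed at mu).
    """
    spec = model.spec
    xb = _as_batch(x)
    train = mode == "train"
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(0 if seed is None else seed)
    if isinstance(model, VariationalConvAutoencoder):
        y = model.forward(xb, train=train, rng=rng if train else None)
        latent = {"mu": model.mu.copy(), "logvar": model.logvar.copy()}
        terms = {
            "reconstruction": float(
                loss_reconstruction(xb, y, spec.reconstruction_loss)),
            "kl": float(loss_beta_kl(model.mu, model.logvar, spec.beta)),
        }
    else:
        x_in = xb
        if train and spec.variant == "dcae":
            x_in = corrupt_zero_mask(xb, spec.sigma, rng)
        y = model.forward(x_in, train=False)
        latent = {"mean_activation": model.latent.mean(axis=(0, 1, 2))}
        terms = {"reconstruction": float(
            loss_reconstruction(xb, y, spec.reconstruction_loss))}
        if spec.variant == "scae":
            zbar = squash_mean_activation(model.latent)
            terms["sparsity"] = float(
                loss_sparsity(zbar, spec.z, spec.gamma))
    if x.ndim == 2:
        y = y[0, :, :, 0]
    return Reconstruction(output=y, latent_summary=latent,
                          per_sample_loss_terms=terms)


# -- losses ---------------------------------------------------------------

def loss_reconstruction(x: np.ndarray, y: np.ndarray,
                        kind: Literal["mse", "bernoulli_ce"] = "mse") -> float:
    """Per-sample reconstruction cost, summed over pixels.

    ``mse``: sum_i (x_i - y_i)^2. ``bernoulli_ce``:
    -sum_i [x_i log y_i + (1-x_i) log(1-y_i)], with y clamped away from
    {0,1} by eps.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if kind == "mse":
        return float(np.sum((x - y) ** 2))
    if kind == "bernoulli_ce":
        yc = np.clip(y, EPS, 1.0 - EPS)
        return float(-np.sum(x * np.log(yc) + (1.0 - x) * np.log(1.0 - yc)))
    raise ValueError(f"unknown reconstruction loss {kind!r}")


def squash_mean_activation(latent: np.ndarray) -> np.ndarray:
    """Per-feature-map mean activation squashed into (0,1).

    ReLU activations are unbounded, so the batch/spatial mean of each
    feature map is passed through the logistic function before entering
    the Bernoulli KL.
    """
    m = latent.mean(axis=(0, 1, 2), dtype=np.float64)
    return 1.0 / (1.0 + np.exp(-m))


def loss_sparsity(zbar: np.ndarray, z: float, gamma: float) -> float:
    """gamma-weighted Bernoulli KL between target z and mean activations."""
    if not 0.0 < z < 1.0:
        raise ValueError(f"sparsity target z must be in (0,1), got {z}")
    zb = np.clip(np.asarray(zbar, dtype=np.float64), EPS, 1.0 - EPS)
    kl = z * np.log(z / zb) + (1.0 - z) * np.log((1.0 - z) / (1.0 - zb))
    return float(gamma * np.sum(kl))


def loss_beta_kl(mu: np.ndarray, log_variance: np.ndarray,
                 beta: float) -> float:
    """beta-weighted KL of N(mu, diag exp(lv)) to the unit Gaussian."""
    mu = np.asarray(mu, dtype=np.float64)
    lv = np.asarray(log_variance, dtype=np.float64)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(lv))):
        raise FloatingPointError("non-finite posterior parameters")
    return float(beta * 0.5 * np.sum(mu ** 2 + np.exp(lv) - 1.0 - lv))


def total_loss(spec: ModelSpec, x: np.ndarray,
               recon: Reconstruction) -> dict[str, float]:
    """Variant objective assembled from a Reconstruction's components."""
    terms = dict(recon.per_sample_loss_terms)
    if "reconstruction" not in terms:
        raise RuntimeError("reconstruction component missing")
    if spec.variant in ("pcae", "dcae"):
        extras = set(terms) - {"reconstruction"}
    elif spec.variant == "scae":
        extras = set(terms) - {"reconstruction", "sparsity"}
    else:
        extras = set(terms) - {"reconstruction", "kl"}
    if extras:
        raise RuntimeError(
            f"loss components {sorted(extras)} do not belong to {spec.variant}")
    terms["total"] = sum(v for k, v in terms.items())
    return terms


# -- checkpointing --------------------------------------------------------

def save_checkpoint(model: AnyAutoencoder, seed: int, path) -> None:
    arrays = {f"p{i}": p for i, (p, _) in enumerate(model.parameters())}
    meta = json.dumps({"format": CHECKPOINT_FORMAT, "seed": seed,
                       "spec": model.spec.to_dict()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[AnyAutoencoder, int]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unrecognised checkpoint format in {path}")
        spec = ModelSpec(**meta["spec"])
        model = build_model(spec, meta["seed"])
        for i, (p, _) in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
    return model, meta["seed"]
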