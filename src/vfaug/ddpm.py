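"""Denoising diffusion probabilistic model: schedule, training, sampling.

The forward process corrupts a sample x0 (scaled to [-1, 1]) as

    x_t = sqrt(abar_t) * x0 + sqrt(1 - abar_t) * eps,    eps ~ N(0, I),

where the cumulative signal-retention coefficients abar_t follow the cosine
schedule abar_t = f(t)/f(0), f(t) = cos^2(((t/T + s)/(1 + s)) * pi/2) with a
small offset s. A denoiser eps_theta(x_t, t) is trained to predict the added
noise by minimizing the mean squared error E||eps - eps_theta(x_t, t)||^2,
and ancestral sampling inverts the corruption step by step: each reverse
transition is Gaussian with mean

    mu_theta = (x_t - beta_t / sqrt(1 - abar_t) * eps_theta) / sqrt(alpha_t)

and standard deviation sigma_t = sqrt(beta_t) (zero at the final step). The
per-step alpha_t and beta_t = 1 - alpha_t are derived from consecutive abar
ratios, with beta clipped at 0.999 to keep the last steps non-singular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import DatasetError, ImageDataset, LabeledImage
from .nn import (
    Adam,
    Conv2d,
    Dense,
    GroupNorm,
    Param,
    SiLU,
    Upsample2x,
    sinusoidal_embedding,
)


class ScheduleError(ValueError):
    """Raised for invalid schedule arguments or degenerate timesteps."""


# ---------------------------------------------------------------------------
# Noise schedule
# ---------------------------------------------------------------------------

def cosine_alpha_bar(t: int | np.ndarray, T: int, s: float = 0.008) -> float | np.ndarray:
    """Cosine-schedule cumulative coefficient abar_t = f(t)/f(0)."""
    t = np.asarray(t)
    if s <= 0:
        raise ScheduleError("offset s must be positive")
    if np.any(t < 0) or np.any(t > T):
        raise ScheduleError(f"timestep out of range [0, {T}]")
    f = lambda u: np.cos(((u / T + s) / (1 + s)) * np.pi / 2.0) ** 2
    out = f(t) / f(0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class NoiseSchedule:
    """Cosine variance schedule and derived per-step quantities.

    ``alpha_bar[t]`` for t = 0..T is the cumulative product of ``alpha[t]``;
    ``beta[t] = 1 - alpha[t]`` (clipped at 0.999); ``sigma[t] = sqrt(beta[t])``
    except at the final denoising step t=1 where sigma is 0. Index 0 of the
    per-step arrays is unused padding.
    """

    T: int
    s: float
    alpha_bar: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray


def build_schedule(T: int, s: float = 0.008, beta_max: float = 0.999) -> NoiseSchedule:
    """Build the cosine schedule with all derived per-step quantities."""
    if T < 1:
        raise ScheduleError("T must be >= 1")
    raw = cosine_alpha_bar(np.arange(T + 1), T, s)
    beta = 1.0 - raw[1:] / raw[:-1]
    beta = np.clip(beta, 1e-12, beta_max)
    alpha = 1.0 - beta
    alpha_bar = np.concatenate([[1.0], np.cumprod(alpha)])
    alpha = np.concatenate([[1.0], alpha])
    beta = np.concatenate([[0.0], beta])
    sigma = np.sqrt(beta)
    if T >= 1:
        sigma = sigma.copy()
        sigma[1] = 0.0  # final denoising step is deterministic
    return NoiseSchedule(T=T, s=s, alpha_bar=alpha_bar, alpha=alpha,
                         beta=beta, sigma=sigma)


# ---------------------------------------------------------------------------
# Forward process and loss
# ---------------------------------------------------------------------------

def _abar(schedule: NoiseSchedule, t: int | np.ndarray) -> np.ndarray:
    t = np.asarray(t)
    if np.any(t < 0) or np.any(t > schedule.T):
        raise ScheduleError(f"timestep out of range [0, {schedule.T}]")
    return schedule.alpha_bar[t]


def forward_diffuse(x0: np.ndarray, t: int | np.ndarray, noise: np.ndarray,
                    schedule: NoiseSchedule) -> np.ndarray:
    """x_t = sqrt(abar_t) x0 + sqrt(1 - abar_t) eps (shape-preserving).

    ``t`` may be a scalar or a per-sample array matching the batch axis.
    """
    x0 = np.asarray(x0, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if x0.shape != noise.shape:
        raise DatasetError(f"shape mismatch: {x0.shape} vs {noise.shape}")
    ab = _abar(schedule, t)
    ab = np.reshape(ab, np.shape(ab) + (1,) * (x0.ndim - np.ndim(ab)))
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * noise


def invert_forward(xt: np.ndarray, noise: np.ndarray, t: int | np.ndarray,
                   schedule: NoiseSchedule) -> np.ndarray:
    """Algebraic inverse of the forward step: recovers x0 given the noise."""
    xt = np.asarray(xt, dtype=float)
    noise = np.asarray(noise, dtype=float)
    ab = _abar(schedule, t)
    if np.any(ab <= 0):
        raise ScheduleError("degenerate timestep: alpha_bar is zero")
    ab = np.reshape(ab, np.shape(ab) + (1,) * (xt.ndim - np.ndim(ab)))
    return (xt - np.sqrt(1.0 - ab) * noise) / np.sqrt(ab)


def diffusion_loss(model: "Denoiser", x0: np.ndarray, t: np.ndarray,
                   noise: np.ndarray, schedule: NoiseSchedule) -> float:
    """Mean squared noise-prediction error, averaged over batch and elements."""
    xt = forward_diffuse(x0, t, noise, schedule)
    eps_hat = model.predict_noise(xt, np.broadcast_to(np.asarray(t), (xt.shape[0],)))
    return float(np.mean((noise - eps_hat) ** 2))


def reverse_step(model: "Denoiser", xt: np.ndarray, t: int,
                 schedule: NoiseSchedule, rng: np.random.Generator) -> np.ndarray:
    """One ancestral sampling step from x_t to x_{t-1}."""
    if not 1 <= t <= schedule.T:
        raise ScheduleError("t must be in [1, T] (nothing to denoise at t=0)")
    tb = np.full(xt.shape[0], t, dtype=int)
    eps_hat = model.predict_noise(xt, tb)
    ab = schedule.alpha_bar[t]
    mu = (xt - schedule.beta[t] / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(schedule.alpha[t])
    if schedule.sigma[t] > 0:
        mu = mu + schedule.sigma[t] * rng.standard_normal(xt.shape)
    return mu


# ---------------------------------------------------------------------------
# Denoiser models
# ---------------------------------------------------------------------------

class Denoiser:
    """Contract: ``predict_noise(x_t, t) -> eps_hat`` of identical shape."""

    architecture: dict
    train_log: list

    def predict_noise(self, xt: np.ndarray, t: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Param]:
        raise NotImplementedError

    def loss_and_grad(self, xt: np.ndarray, t: np.ndarray, eps: np.ndarray) -> float:
        """MSE loss plus parameter-gradient accumulation (for training)."""
        eps_hat = self._forward(xt, t)
        diff = eps_hat - eps
        loss = float(np.mean(diff**2))
        self._backward(2.0 * diff / diff.size)
        return loss


class _TimeMLP:
    """Sinusoidal embedding followed by a two-layer MLP."""

    def __init__(self, dim: int, out: int, rng: np.random.Generator):
        self.dim = dim
        self.fc1 = Dense(dim, out, rng)
        self.act = SiLU()
        self.fc2 = Dense(out, out, rng)

    def forward(self, t: np.ndarray) -> np.ndarray:
        return self.fc2.forward(self.act.forward(self.fc1.forward(
            sinusoidal_embedding(t, self.dim))))

    def backward(self, g: np.ndarray) -> None:
        self.fc1.backward(self.act.backward(self.fc2.backward(g)))

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params()


class _ConvResBlock:
    """Wide-ResNet-style block: GN -> SiLU -> conv -> (+temb) -> GN -> SiLU -> conv,
    with an identity or 1x1-conv shortcut."""

    def __init__(self, cin: int, cout: int, temb_dim: int, rng: np.random.Generator):
        self.n1 = GroupNorm(cin)
        self.a1 = SiLU()
        self.c1 = Conv2d(cin, cout, rng)
        self.tproj = Dense(temb_dim, cout, rng)
        self.n2 = GroupNorm(cout)
        self.a2 = SiLU()
        self.c2 = Conv2d(cout, cout, rng)
        self.shortcut = Conv2d(cin, cout, rng, k=1) if cin != cout else None

    def forward(self, x: np.ndarray, temb: np.ndarray) -> np.ndarray:
        h = self.c1.forward(self.a1.forward(self.n1.forward(x)))
        h = h + self.tproj.forward(temb)[:, :, None, None]
        h = self.c2.forward(self.a2.forward(self.n2.forward(h)))
        sc = self.shortcut.forward(x) if self.shortcut else x
        return h + sc

    def backward(self, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        gh = self.n2.backward(self.a2.backward(self.c2.backward(g)))
        gtemb = self.tproj.backward(gh.sum(axis=(2, 3)))
        gx = self.n1.backward(self.a1.backward(self.c1.backward(gh)))
        if self.shortcut:
            gx = gx + self.shortcut.backward(g)
        else:
            gx = gx + g
        return gx, gtemb

    def params(self) -> list[Param]:
        out = (self.n1.params() + self.c1.params() + self.tproj.params()
               + self.n2.params() + self.c2.params())
        if self.shortcut:
            out += self.shortcut.params()
        return out


class UNetDenoiser(Denoiser):
    """Small two-level U-Net with timestep conditioning and skip connection.

    Encoder: conv-in, residual block, stride-2 downsample; bottleneck residual
    block; decoder: nearest upsample + conv, concatenation with the encoder
    feature map, residual block, conv-out. Channels default to (16, 32) for
    the desk profile.
    """

    def __init__(self, in_channels: int = 3, base: int = 16, temb_dim: int = 64,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        c1, c2 = base, base * 2
        self.time = _TimeMLP(32, temb_dim, rng)
        self.conv_in = Conv2d(in_channels, c1, rng)
        self.enc = _ConvResBlock(c1, c1, temb_dim, rng)
        self.down = Conv2d(c1, c2, rng, stride=2)
        self.mid = _ConvResBlock(c2, c2, temb_dim, rng)
        self.up = Upsample2x()
        self.up_conv = Conv2d(c2, c1, rng)
        self.dec = _ConvResBlock(2 * c1, c1, temb_dim, rng)
        self.norm_out = GroupNorm(c1)
        self.act_out = SiLU()
        self.conv_out = Conv2d(c1, in_channels, rng)
        # start near the identity-zero map for stable early training
        self.conv_out.W.data *= 0.01
        self.architecture = {
            "type": "unet2", "base": base, "in_channels": in_channels,
            "temb_dim": temb_dim,
        }
        self.train_log = []
        self._c1 = c1

    def parameters(self) -> list[Param]:
        return (self.time.params() + self.conv_in.params() + self.enc.params()
                + self.down.params() + self.mid.params() + self.up_conv.params()
                + self.dec.params() + self.norm_out.params() + self.conv_out.params())

    def _forward(self, xt: np.ndarray, t: np.ndarray) -> np.ndarray:
        temb = self.time.forward(np.asarray(t))
        h0 = self.conv_in.forward(xt)
        h1 = self.enc.forward(h0, temb)
        h2 = self.down.forward(h1)
        h3 = self.mid.forward(h2, temb)
        h4 = self.up_conv.forward(self.up.forward(h3))
        cat = np.concatenate([h4, h1], axis=1)
        h5 = self.dec.forward(cat, temb)
        return self.conv_out.forward(self.act_out.forward(self.norm_out.forward(h5)))

    def _backward(self, g: np.ndarray) -> None:
        g5 = self.norm_out.backward(self.act_out.backward(self.conv_out.backward(g)))
        gcat, gt_dec = self.dec.backward(g5)
        g4, g1b = gcat[:, : self._c1], gcat[:, self._c1 :]
        g3 = self.up.backward(self.up_conv.backward(g4))
        g2, gt_mid = self.mid.backward(g3)
        g1 = self.down.backward(g2) + g1b
        g0, gt_enc = self.enc.backward(g1)
        self.conv_in.backward(g0)
        self.time.backward(gt_dec + gt_mid + gt_enc)

    def predict_noise(self, xt: np.ndarray, t: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(xt, dtype=float), np.asarray(t))


class MLPDenoiser(Denoiser):
    """Residual MLP denoiser for low-dimensional (vector) data.

    Used for distribution-level checks (e.g. 2-D Gaussian mixtures) where a
    convolutional encoder is meaningless. Timestep conditioning and residual
    blocks follow the same pattern as the U-Net.
    """

    def __init__(self, dim: int = 2, hidden: int = 96, blocks: int = 3,
                 temb_dim: int = 48, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.time = _TimeMLP(32, temb_dim, rng)
        self.fc_in = Dense(dim, hidden, rng)
        self.blocks = []
        for _ in range(blocks):
            self.blocks.append({
                "a1": SiLU(), "fc1": Dense(hidden, hidden, rng),
                "tproj": Dense(temb_dim, hidden, rng),
                "a2": SiLU(), "fc2": Dense(hidden, hidden, rng),
            })
        self.act_out = SiLU()
        self.fc_out = Dense(hidden, dim, rng)
        self.fc_out.W.data *= 0.01
        self.architecture = {"type": "resmlp", "dim": dim, "hidden": hidden,
                             "blocks": blocks}
        self.train_log = []

    def parameters(self) -> list[Param]:
        ps = self.time.params() + self.fc_in.params() + self.fc_out.params()
        for b in self.blocks:
            ps += b["fc1"].params() + b["tproj"].params() + b["fc2"].params()
        return ps

    def _forward(self, xt: np.ndarray, t: np.ndarray) -> np.ndarray:
        self._in_shape = xt.shape
        x = xt.reshape(xt.shape[0], -1)
        temb = self.time.forward(np.asarray(t))
        h = self.fc_in.forward(x)
        for b in self.blocks:
            a = b["fc1"].forward(b["a1"].forward(h))
            a = a + b["tproj"].forward(temb)
            a = b["fc2"].forward(b["a2"].forward(a))
            h = h + a
        out = self.fc_out.forward(self.act_out.forward(h))
        return out.reshape(self._in_shape)

    def _backward(self, g: np.ndarray) -> None:
        g = g.reshape(g.shape[0], -1)
        gh = self.act_out.backward(self.fc_out.backward(g))
        gt_total = None
        for b in reversed(self.blocks):
            ga = b["a2"].backward(b["fc2"].backward(gh))
            gtp = b["tproj"].backward(ga)
            gt_total = gtp if gt_total is None else gt_total + gtp
            gh = gh + b["a1"].backward(b["fc1"].backward(ga))
        self.fc_in.backward(gh)
        if gt_total is not None:
            self.time.backward(gt_total)

    def predict_noise(self, xt: np.ndarray, t: np.ndarray) -> np.ndarray:
        xt = np.asarray(xt, dtype=float)
        return self._forward(xt, np.asarray(t))


# ---------------------------------------------------------------------------
# Training and sampling
# ---------------------------------------------------------------------------

@dataclass
class DiffusionTrainConfig:
    """Training hyperparameters for one per-class diffusion model.

    ``steps`` caps the total number of optimizer updates (None = no cap);
    timesteps are drawn uniformly from {1..T} at every update.
    """

    epochs: int = 10
    steps: int | None = None
    learning_rate: float = 1e-4
    batch_size: int = 16
    input_size: int = 32
    T: int = 200
    s: float = 0.008
    seed: int = 0
    base_channels: int = 16

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.input_size, self.T) < 1:
            raise DatasetError("all config sizes must be positive")
        if self.learning_rate <= 0 or self.s <= 0:
            raise DatasetError("learning rate and s must be positive")


def desk_profile(**overrides) -> DiffusionTrainConfig:
    """Small CPU-friendly configuration used throughout the test suite."""
    cfg = dict(epochs=10, steps=None, learning_rate=1e-4, batch_size=16,
               input_size=32, T=200, s=0.008, base_channels=16)
    cfg.update(overrides)
    return DiffusionTrainConfig(**cfg)


def paper_profile(**overrides) -> DiffusionTrainConfig:
    """The study's published hyperparameter listing (GPU scale)."""
    cfg = dict(epochs=1024, steps=10_000, learning_rate=1e-4, batch_size=32,
               input_size=256, T=10_000, s=0.008, base_channels=64)
    cfg.update(overrides)
    return DiffusionTrainConfig(**cfg)


def to_unit_range(pixels: np.ndarray) -> np.ndarray:
    """uint8 [0,255] -> float [-1,1]."""
    return pixels.astype(float) / 127.5 - 1.0


def from_unit_range(x: np.ndarray) -> np.ndarray:
    """float, clamped to [-1,1] -> uint8 [0,255]."""
    x = np.clip(x, -1.0, 1.0)
    return np.rint((x + 1.0) * 127.5).astype(np.uint8)


def _as_training_array(dataset, input_size: int) -> np.ndarray:
    """ImageDataset -> (n, 3, S, S) in [-1, 1]; arrays pass through."""
    if isinstance(dataset, ImageDataset):
        if len(dataset) == 0:
            raise DatasetError("cannot train on an empty dataset")
        if dataset.image_size != input_size:
            raise DatasetError(
                f"dataset images are {dataset.image_size} px, config expects {input_size}")
        arr = to_unit_range(dataset.pixel_array())
        return np.moveaxis(arr, -1, 1)
    arr = np.asarray(dataset, dtype=float)
    if arr.ndim < 2 or arr.shape[0] == 0:
        raise DatasetError("cannot train on an empty dataset")
    return arr


def train_ddpm(dataset, config: DiffusionTrainConfig,
               model: Denoiser | None = None) -> Denoiser:
    """Train a denoiser on one class of images (or raw arrays in [-1, 1]).

    Timesteps are drawn uniformly from {1..T} for every sample of every
    update; the per-epoch mean loss is recorded in ``model.train_log``.
    Deterministic for a fixed config (all randomness from ``config.seed``).
    """
    x = _as_training_array(dataset, config.input_size)
    n = x.shape[0]
    schedule = build_schedule(config.T, config.s)
    rng = np.random.default_rng(config.seed)
    if model is None:
        if x.ndim == 4 and x.shape[2] >= 8:
            model = UNetDenoiser(in_channels=x.shape[1], base=config.base_channels,
                                 seed=config.seed)
        else:
            model = MLPDenoiser(dim=int(np.prod(x.shape[1:])), seed=config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    updates_per_epoch = max(1, int(np.ceil(n / config.batch_size)))
    total = 0
    for epoch in range(config.epochs):
        losses = []
        for _ in range(updates_per_epoch):
            if config.steps is not None and total >= config.steps:
                break
            idx = rng.integers(0, n, size=min(config.batch_size, n))
            x0 = x[idx]
            t = rng.integers(1, config.T + 1, size=x0.shape[0])
            eps = rng.standard_normal(x0.shape)
            xt = forward_diffuse(x0, t, eps, schedule)
            opt.zero_grad()
            losses.append(model.loss_and_grad(xt, t, eps))
            opt.step()
            total += 1
        if losses:
            model.train_log.append({"epoch": epoch, "loss": float(np.mean(losses))})
        if config.steps is not None and total >= config.steps:
            break
    model.schedule = schedule
    model.config = config
    return model


def sample(model: Denoiser, schedule: NoiseSchedule, shape: tuple, n: int,
           seed: int = 0) -> np.ndarray:
    """Draw n samples by running all T reverse steps from pure noise."""
    if n < 1:
        raise DatasetError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n,) + tuple(shape))
    for t in range(schedule.T, 0, -1):
        x = reverse_step(model, x, t, schedule, rng)
    return x


def sample_images(model: Denoiser, schedule: NoiseSchedule, n: int, seed: int = 0,
                  label: str = "without_pathology", image_size: int | None = None,
                  id_prefix: str = "") -> ImageDataset:
    """Generate n synthetic images for one class (provenance ``synthetic``).

    Outputs are clamped to [-1, 1] and mapped to 8-bit regardless of model
    quality, so even an untrained model yields valid images.
    """
    size = image_size or getattr(model, "config", None).input_size
    x = sample(model, schedule, (model.architecture.get("in_channels", 3), size, size),
               n, seed)
    images = []
    for i in range(n):
        px = from_unit_range(np.moveaxis(x[i], 0, -1))
        images.append(LabeledImage(
            pixels=px, label=label, provenance="synthetic",
            id=f"{id_prefix}synt-{label}-{seed}-{i:05d}",
            meta={"seed": seed, "sampler": "ancestral", "T": schedule.T},
        ))
    return ImageDataset(images)
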