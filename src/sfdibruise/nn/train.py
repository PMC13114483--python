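"""Adversarial training of the coefficient-prediction generator.

Alternates discriminator and generator Adam updates over the paired
simulation dataset.  Inputs (calibrated diffuse reflectance) are normalized
to [-1, 1]; labels (RGB-encoded coefficient maps) to [0, 1], matching the
sigmoid output head.  Per-epoch training loss and validation L1/MSE are
logged and the best-validation-L1 generator weights are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..synth import DatasetManifest, OpticalPropertyMap, decode_rgb_label
from .autograd import Tensor, no_grad
from .layers import (
    DiscriminatorConfig,
    GeneratorConfig,
    build_discriminator,
    build_generator,
)
from .losses import EPS, LAMBDA_L1, l1_loss

__all__ = [
    "TrainConfig",
    "Adam",
    "load_pairs",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Optimization schedule of the adversarial training loop.

    The discriminator loss is halved (the usual conditional-GAN convention)
    and its learning rate additionally scaled by ``disc_lr_factor``: with the
    pixel term weighted at lambda = 60 the objective is L1-dominated, and a
    deliberately slow discriminator supplies adversarial sharpening without
    destabilizing short schedules.
    """

    lambda_l1: float = LAMBDA_L1
    learning_rate: float = 1e-3
    betas: tuple[float, float] = (0.5, 0.999)
    epochs: int = 20
    batch_size: int = 4
    seed: int = 0
    disc_lr_factor: float = 0.05
    disc_loss_scale: float = 0.5
    lr_decay: bool = True  # linear decay of both rates to ~0 over the run

    def __post_init__(self) -> None:
        if self.lambda_l1 <= 0:
            raise ValueError("lambda_l1 must be > 0")


class Adam:
    """Adam over a flat parameter list."""

    def __init__(self, params, lr=2e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def load_pairs(manifest: DatasetManifest, root, split: str | None = None):
    """Load (x, y) arrays from a dataset directory.

    Returns ``x`` of shape (N, 1, H, W) in [-1, 1] and ``y`` of shape
    (N, 3, H, W) in [0, 1].
    """
    import tifffile
    from PIL import Image

    root = Path(root)
    xs, ys = [], []
    for entry in manifest.paths(split):
        rd = tifffile.imread(root / entry["input"]).astype(np.float64)
        label = np.asarray(Image.open(root / entry["label"])).astype(np.float64)
        xs.append(2.0 * rd - 1.0)
        ys.append(label.transpose(2, 0, 1) / 255.0)
    if not xs:
        raise ValueError(f"empty split {split!r}")
    return np.stack(xs)[:, None], np.stack(ys)


@dataclass
class History:
    train_total: list = field(default_factory=list)
    train_l1: list = field(default_factory=list)
    val_l1: list = field(default_factory=list)
    val_mse: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.val_l1) + 1),
                "train_total": self.train_total,
                "train_l1": self.train_l1,
                "val_l1": self.val_l1,
                "val_mse": self.val_mse,
            }
        )


def _validation_scores(gen, x_val, y_val, batch=8):
    l1s, mses = [], []
    with no_grad():
        for i in range(0, len(x_val), batch):
            pred = gen(Tensor(x_val[i : i + batch])).data
            diff = pred - y_val[i : i + batch]
            l1s.append(np.abs(diff).mean(axis=(1, 2, 3)))
            mses.append((diff**2).mean(axis=(1, 2, 3)))
    return float(np.concatenate(l1s).mean()), float(np.concatenate(mses).mean())


def train(
    manifest: DatasetManifest,
    root,
    cfg: TrainConfig = TrainConfig(),
    gen_cfg: GeneratorConfig | None = None,
    disc_cfg: DiscriminatorConfig | None = None,
):
    """Adversarial training loop; returns ``(generator, history)``.

    The returned generator carries the weights with the best validation L1
    seen over the run.
    """
    gen_cfg = gen_cfg or GeneratorConfig()
    disc_cfg = disc_cfg or DiscriminatorConfig(
        in_channels=gen_cfg.in_channels + gen_cfg.out_channels
    )
    x_train, y_train = load_pairs(manifest, root, "train")
    x_val, y_val = load_pairs(manifest, root, "val")

    rng = np.random.default_rng(cfg.seed)
    gen = build_generator(gen_cfg, seed=int(rng.integers(2**31)))
    disc = build_discriminator(disc_cfg, seed=int(rng.integers(2**31)))
    opt_g = Adam(gen.parameters(), lr=cfg.learning_rate, betas=cfg.betas)
    opt_d = Adam(
        disc.parameters(), lr=cfg.learning_rate * cfg.disc_lr_factor,
        betas=cfg.betas,
    )

    history = History()
    best_l1 = np.inf
    best_state = [p.copy() for p in gen.state_arrays()]

    n = len(x_train)
    for epoch in range(cfg.epochs):
        if cfg.lr_decay:
            factor = 1.0 - epoch / cfg.epochs
            opt_g.lr = cfg.learning_rate * factor
            opt_d.lr = cfg.learning_rate * cfg.disc_lr_factor * factor
        order = rng.permutation(n)
        epoch_total, epoch_l1, n_batches = 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x = Tensor(x_train[idx])
            y = Tensor(y_train[idx])

            fake = gen(x)

            # discriminator: push D(x,y) -> 1 and D(x,G(x)) -> 0
            opt_d.zero_grad()
            d_real = disc(x, y).clamp(EPS, 1 - EPS)
            d_fake = disc(x, fake.detach()).clamp(EPS, 1 - EPS)
            loss_d = -(
                d_real.log().mean() + (1.0 - d_fake).log().mean()
            ) * cfg.disc_loss_scale
            loss_d.backward()
            opt_d.step()

            # generator: non-saturating adversarial term plus weighted L1
            opt_g.zero_grad()
            d_fake_g = disc(x, fake).clamp(EPS, 1 - EPS)
            l1 = l1_loss(y, fake)
            loss_g = -d_fake_g.log().mean() + cfg.lambda_l1 * l1
            loss_g.backward()
            opt_g.step()

            epoch_total += float(loss_g.data)
            epoch_l1 += float(l1.data)
            n_batches += 1

        val_l1, val_mse = _validation_scores(gen, x_val, y_val)
        history.train_total.append(epoch_total / n_batches)
        history.train_l1.append(epoch_l1 / n_batches)
        history.val_l1.append(val_l1)
        history.val_mse.append(val_mse)
        if val_l1 < best_l1:
            best_l1 = val_l1
            best_state = [p.copy() for p in gen.state_arrays()]

    gen.load_state_arrays(best_state)
    return gen, history


def predict(gen, rd_image, pixel_size: float) -> OpticalPropertyMap:
    """Predict coefficient maps from one calibrated reflectance image.

    The input must be square with side divisible by 2**depth.  The sigmoid
    output is quantized through the 8-bit RGB label encoding before
    decoding, matching the training-label representation.
    """
    rd_image = np.asarray(rd_image, dtype=np.float64)
    if rd_image.ndim != 2:
        raise ValueError("expected a 2-D reflectance image")
    stride = 2 ** gen.cfg.depth
    if rd_image.shape[0] % stride or rd_image.shape[1] % stride:
        raise ValueError(
            f"image sides must be divisible by {stride} for depth {gen.cfg.depth}"
        )
    x = 2.0 * rd_image - 1.0
    with no_grad():
        out = gen(Tensor(x[None, None])).data[0]
    label = np.rint(np.clip(out, 0.0, 1.0) * 255.0).astype(np.uint8)
    return decode_rgb_label(label.transpose(1, 2, 0), pixel_size)


def save_checkpoint(path, gen, gen_cfg: GeneratorConfig | None = None) -> None:
    arrays = {f"p{i}": a for i, a in enumerate(gen.state_arrays())}
    cfg = gen_cfg or gen.cfg
    meta = np.array(
        [cfg.depth, cfg.base_channels, cfg.residual_blocks,
         cfg.cbam_reduction_ratio, cfg.cbam_spatial_kernel,
         cfg.in_channels, cfg.out_channels]
    )
    np.savez(path, _meta=meta, **arrays)


def load_checkpoint(path):
    with np.load(path) as data:
        meta = data["_meta"].astype(int)
        cfg = GeneratorConfig(
            depth=meta[0], base_channels=meta[1], residual_blocks=meta[2],
            cbam_reduction_ratio=meta[3], cbam_spatial_kernel=meta[4],
            in_channels=meta[5], out_channels=meta[6],
        )
        gen = build_generator(cfg)
        arrays = [data[f"p{i}"] for i in range(len(data.files) - 1)]
    gen.load_state_arrays(arrays)
    return gen
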