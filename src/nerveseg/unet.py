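"""3D U-Net construction and patch-based training protocol.

The reference protocol trains a 7-stage network (features 32, 64, 128, 256,
320, 320, 320; strides (1,1,1), (2,2,2) x 4, (1,2,2) x 2) on 32 x 256 x 256
patches, batch 4, for 500 epochs of 250 iterations with SGD (Nesterov
momentum 0.99), initial learning rate 0.01 under polynomial decay
``lr0 * (1 - e / e_max)^0.9``, a 33% foreground-patch guarantee, and light
geometric/intensity augmentation. That configuration is GPU-scale; the
``scaled()`` constructors give a desk-scale setup (small feature widths,
16 x 64 x 64 patches, tens of epochs) that trains in minutes on one CPU and
is used throughout the test-suite and worked examples.

Training runs entirely in the NumPy engine of :mod:`nerveseg.nn`; every
random choice flows from one seeded generator, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import IntensityVolume, LabelVolume, normalize_intensity
from .losses import LossConfig, compound_loss_grad, one_hot
from .nn import SGDNesterov, UNet3D

__all__ = [
    "ArchitectureConfig",
    "TrainingConfig",
    "AugmentationConfig",
    "build_network",
    "sample_training_patches",
    "poly_lr",
    "train_model",
    "TrainingDiverged",
]


@dataclass
class ArchitectureConfig:
    """Network topology. Defaults are the full-scale 7-stage configuration."""

    features_per_stage: tuple[int, ...] = (32, 64, 128, 256, 320, 320, 320)
    strides_per_stage: tuple[tuple[int, int, int], ...] = (
        (1, 1, 1), (2, 2, 2), (2, 2, 2), (2, 2, 2), (2, 2, 2), (1, 2, 2), (1, 2, 2),
    )
    n_classes: int = 3
    in_channels: int = 1

    def __post_init__(self) -> None:
        if len(self.features_per_stage) != len(self.strides_per_stage):
            raise ValueError("features and strides must have the same length")

    @property
    def n_stages(self) -> int:
        return len(self.features_per_stage)

    @classmethod
    def paper_scale(cls) -> "ArchitectureConfig":
        return cls()

    @classmethod
    def scaled(cls) -> "ArchitectureConfig":
        """Desk-scale network: 3 stages, narrow features."""
        return cls(
            features_per_stage=(8, 16, 32),
            strides_per_stage=((1, 1, 1), (2, 2, 2), (1, 2, 2)),
        )


@dataclass
class TrainingConfig:
    """Optimization protocol. Defaults are the full-scale recipe."""

    patch_size: tuple[int, int, int] = (32, 256, 256)
    batch_size: int = 4
    epochs: int = 500
    iters_per_epoch: int = 250
    foreground_patch_fraction: float = 0.33
    momentum: float = 0.99
    lr0: float = 0.01
    poly_exponent: float = 0.9
    val_patches_per_epoch: int = 50
    grad_clip_norm: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.foreground_patch_fraction <= 1.0:
            raise ValueError("foreground_patch_fraction must lie in [0, 1]")
        if not self.lr0 > 0:
            raise ValueError("lr0 must be > 0")

    @classmethod
    def scaled(cls, epochs: int = 30, seed: int = 0) -> "TrainingConfig":
        """Desk-scale protocol used by the worked examples and tests."""
        return cls(
            patch_size=(16, 64, 64),
            batch_size=2,
            epochs=epochs,
            iters_per_epoch=8,
            val_patches_per_epoch=8,
            seed=seed,
        )


@dataclass
class AugmentationConfig:
    """Training-time augmentation: rotation, Gaussian noise, contrast.

    Parameter ranges are conventional: in-plane rotation up to ±15 degrees
    about z, additive noise with sd up to 10% of the dynamic range, contrast
    scaling 0.75-1.25 about the patch mean; each applied with probability
    0.2. Axis flips exist but are off by default.
    """

    p_rotation: float = 0.2
    max_rotation_deg: float = 15.0
    p_noise: float = 0.2
    max_noise_sd: float = 0.1
    p_contrast: float = 0.2
    contrast_range: tuple[float, float] = (0.75, 1.25)
    p_flip: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.p_rotation, self.p_noise, self.p_contrast, self.p_flip):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def apply(
        self, image: np.ndarray, labels: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        if self.p_rotation and rng.random() < self.p_rotation:
            angle = rng.uniform(-self.max_rotation_deg, self.max_rotation_deg)
            image = ndimage.rotate(image, angle, axes=(1, 2), reshape=False, order=1, mode="nearest")
            labels = ndimage.rotate(labels, angle, axes=(1, 2), reshape=False, order=0, mode="nearest")
        if self.p_flip and rng.random() < self.p_flip:
            axis = int(rng.integers(1, 3))
            image = np.flip(image, axis=axis).copy()
            labels = np.flip(labels, axis=axis).copy()
        if self.p_noise and rng.random() < self.p_noise:
            sd = rng.uniform(0, self.max_noise_sd)
            image = image + rng.normal(0.0, sd, image.shape)
        if self.p_contrast and rng.random() < self.p_contrast:
            f = rng.uniform(*self.contrast_range)
            m = image.mean()
            image = (image - m) * f + m
        return image.astype(np.float32, copy=False), labels


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def build_network(
    cfg: ArchitectureConfig, rng: np.random.Generator | None = None
) -> UNet3D:
    """Instantiate the segmentation network described by ``cfg``."""
    return UNet3D(
        features=cfg.features_per_stage,
        strides=cfg.strides_per_stage,
        n_classes=cfg.n_classes,
        in_channels=cfg.in_channels,
        rng=rng,
    )


def _pad_to(arr: np.ndarray, target: tuple[int, int, int], **kw) -> np.ndarray:
    pads = [(0, max(0, t - s)) for s, t in zip(arr.shape, target)]
    if any(p[1] for p in pads):
        arr = np.pad(arr, pads, **kw)
    return arr


def sample_training_patches(
    volumes: Sequence[tuple[IntensityVolume, LabelVolume]],
    cfg: TrainingConfig,
    rng: np.random.Generator | None = None,
    max_retries: int = 200,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Endless stream of (normalized image patch, label patch) pairs.

    A fraction ``foreground_patch_fraction`` of draws is forced to contain
    at least one foreground voxel by centering the patch on a random
    foreground voxel; the rest are uniform. Raises if foreground is required
    but absent from the whole corpus after bounded retries.
    """
    if not volumes:
        raise ValueError("empty volume list")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pz, py, px = cfg.patch_size
    norm = [
        (
            _pad_to(normalize_intensity(iv), cfg.patch_size, mode="edge"),
            _pad_to(lv.labels, cfg.patch_size, mode="constant"),
        )
        for iv, lv in volumes
    ]
    fg_index = [np.argwhere(lab > 0) for _, lab in norm]
    while True:
        want_fg = rng.random() < cfg.foreground_patch_fraction
        for attempt in range(max_retries):
            vi = int(rng.integers(len(norm)))
            img, lab = norm[vi]
            if want_fg:
                if len(fg_index[vi]) == 0:
                    continue
                cz, cy, cx = fg_index[vi][int(rng.integers(len(fg_index[vi])))]
                z0 = int(np.clip(cz - pz // 2, 0, img.shape[0] - pz))
                y0 = int(np.clip(cy - py // 2, 0, img.shape[1] - py))
                x0 = int(np.clip(cx - px // 2, 0, img.shape[2] - px))
            else:
                z0 = int(rng.integers(img.shape[0] - pz + 1))
                y0 = int(rng.integers(img.shape[1] - py + 1))
                x0 = int(rng.integers(img.shape[2] - px + 1))
            ip = img[z0:z0 + pz, y0:y0 + py, x0:x0 + px]
            lp = lab[z0:z0 + pz, y0:y0 + py, x0:x0 + px]
            if want_fg and not (lp > 0).any():
                continue
            yield ip.copy(), lp.copy()
            break
        else:
            raise RuntimeError(
                "could not draw a foreground-containing patch: corpus appears "
                "to contain no foreground voxels"
            )


def poly_lr(e: int, cfg: TrainingConfig) -> float:
    """Polynomial learning-rate schedule ``lr0 * (1 - e/e_max)^exponent``."""
    if not 0 <= e < cfg.epochs:
        raise ValueError(f"epoch {e} outside [0, {cfg.epochs})")
    return cfg.lr0 * (1.0 - e / cfg.epochs) ** cfg.poly_exponent


def _hard_dice(pred_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Mean foreground-class Dice of an argmax prediction."""
    scores = []
    for c in (1, 2):
        p = pred_labels == c
        g = true_labels == c
        denom = int(p.sum()) + int(g.sum())
        scores.append(1.0 if denom == 0 else 2.0 * int((p & g).sum()) / denom)
    return float(np.mean(scores))


def train_model(
    train_volumes: Sequence[tuple[IntensityVolume, LabelVolume]],
    val_volumes: Sequence[tuple[IntensityVolume, LabelVolume]],
    arch_cfg: ArchitectureConfig,
    train_cfg: TrainingConfig,
    aug_cfg: AugmentationConfig | None = None,
    loss_cfg: LossConfig | None = None,
) -> tuple[UNet3D, pd.DataFrame]:
    """Run the full training protocol and return (network, per-epoch log).

    The log has one row per epoch with columns ``epoch, lr, l_ce, l_dice,
    l_topo, val_dice``. In-training validation scores
    ``val_patches_per_epoch`` random patches (not full volumes). Non-finite
    losses abort with :class:`TrainingDiverged`.
    """
    if not train_volumes or not val_volumes:
        raise ValueError("need at least one training and one validation volume")
    aug_cfg = aug_cfg if aug_cfg is not None else AugmentationConfig()
    loss_cfg = loss_cfg if loss_cfg is not None else LossConfig()
    rng = np.random.default_rng(train_cfg.seed)
    net = build_network(arch_cfg, rng=np.random.default_rng(rng.integers(2**31)))
    patch_rng = np.random.default_rng(rng.integers(2**31))
    aug_rng = np.random.default_rng(rng.integers(2**31))
    val_rng_seed = int(rng.integers(2**31))
    patches = sample_training_patches(train_volumes, train_cfg, patch_rng)
    opt = SGDNesterov(
        net.parameters(), lr=train_cfg.lr0, momentum=train_cfg.momentum,
        clip_norm=train_cfg.grad_clip_norm,
    )

    rows = []
    for epoch in range(train_cfg.epochs):
        opt.lr = poly_lr(epoch, train_cfg)
        ep_ce, ep_dice, ep_topo = [], [], []
        for _ in range(train_cfg.iters_per_epoch):
            net.zero_grad()
            for _ in range(train_cfg.batch_size):
                img, lab = next(patches)
                img, lab = aug_cfg.apply(img, lab, aug_rng)
                logits = net.forward(img[None])
                loss, grad = compound_loss_grad(logits, one_hot(lab), loss_cfg)
                if not np.isfinite(loss.total):
                    raise TrainingDiverged(
                        f"non-finite loss at epoch {epoch}: {loss}"
                    )
                net.backward((grad / train_cfg.batch_size).astype(np.float32))
                ep_ce.append(loss.ce)
                ep_dice.append(loss.dice)
                ep_topo.append(loss.topo)
            opt.step()
        # in-training validation on random patches
        val_patches = sample_training_patches(
            val_volumes, train_cfg, np.random.default_rng([val_rng_seed, epoch])
        )
        dices = []
        for _ in range(train_cfg.val_patches_per_epoch):
            img, lab = next(val_patches)
            pred = np.argmax(net.forward(img[None]), axis=0)
            dices.append(_hard_dice(pred, lab))
        rows.append({
            "epoch": epoch,
            "lr": opt.lr,
            "l_ce": float(np.mean(ep_ce)),
            "l_dice": float(np.mean(ep_dice)),
            "l_topo": float(np.mean(ep_topo)),
            "val_dice": float(np.mean(dices)),
        })
    return net, pd.DataFrame(rows)
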