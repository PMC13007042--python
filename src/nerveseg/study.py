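"""Desk-scale phantom study: train, predict, evaluate, compare.

This module pins the reduced problem sizes used by the shipped experiments
(see docs/methods.md) in one place: a 4/8/16-feature 3-stage U-Net trained
on 16x48x48 patches for 30 epochs x 6 iterations x batch 2, without
augmentation, on four 32x128x128 phantoms with one held-out phantom. The
compound-loss vs ablation comparison repeats both runs at matched seeds.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .inference import BlendConfig, predict_volume
from .io import IntensityVolume, LabelVolume
from .losses import LossConfig
from .metrics import anatomical_error_rate, dice_coefficient, evaluate_pair
from .phantom import PhantomSpec, PhantomTruth, generate_phantom
from .unet import ArchitectureConfig, AugmentationConfig, TrainingConfig, train_model

__all__ = [
    "desk_arch",
    "desk_training",
    "desk_blend",
    "make_phantom_corpus",
    "train_and_score",
    "comparison_study",
]

PATCH_SIZE = (16, 48, 48)


def desk_arch() -> ArchitectureConfig:
    return ArchitectureConfig(
        features_per_stage=(4, 8, 16),
        strides_per_stage=((1, 1, 1), (2, 2, 2), (1, 2, 2)),
    )


def desk_training(seed: int, epochs: int = 30) -> TrainingConfig:
    return TrainingConfig(
        patch_size=PATCH_SIZE,
        batch_size=2,
        epochs=epochs,
        iters_per_epoch=6,
        val_patches_per_epoch=2,
        seed=seed,
    )


def desk_blend() -> BlendConfig:
    return BlendConfig(patch_size=PATCH_SIZE)


def _no_augmentation() -> AugmentationConfig:
    # phantom intensity statistics are stationary by construction; the
    # geometric/noise augmentations only slow desk-scale convergence
    return AugmentationConfig(p_rotation=0.0, p_noise=0.0, p_contrast=0.0)


def make_phantom_corpus(
    seed: int, n_train: int = 4, n_test: int = 1
) -> tuple[list[PhantomTruth], list[PhantomTruth]]:
    """Generate disjoint training and held-out phantoms from one seed."""
    train = [
        generate_phantom(PhantomSpec(seed=seed * 1000 + i, n_splits=1, n_merges=1))
        for i in range(n_train)
    ]
    test = [
        generate_phantom(PhantomSpec(seed=seed * 1000 + 500 + i, n_splits=1, n_merges=1))
        for i in range(n_test)
    ]
    return train, test


def train_and_score(
    train_phantoms: Sequence[PhantomTruth],
    test_phantoms: Sequence[PhantomTruth],
    loss_cfg: LossConfig,
    seed: int,
    epochs: int = 30,
) -> dict:
    """Train one network and evaluate it on the held-out phantoms.

    Returns held-out fascicle Dice, anatomical error rate, the trained
    network, the training log, and the predicted label volumes.
    """
    pairs = [(p.image, p.labels) for p in train_phantoms]
    net, log = train_model(
        pairs[:-1], pairs[-1:], desk_arch(), desk_training(seed, epochs),
        aug_cfg=_no_augmentation(), loss_cfg=loss_cfg,
    )
    blend = desk_blend()
    dscs, errs, preds = [], [], []
    for ph in test_phantoms:
        _, pred = predict_volume(ph.image, net, blend)
        preds.append(pred)
        dscs.append(dice_coefficient(pred.fascicle_mask(), ph.labels.fascicle_mask()))
        try:
            err, _ = anatomical_error_rate(pred)
        except ValueError:  # no foreground predicted at all
            err = 1.0
        errs.append(err)
    return {
        "fascicle_dice": float(np.mean(dscs)),
        "anatomical_error_rate": float(np.mean(errs)),
        "network": net,
        "log": log,
        "predictions": preds,
    }


def comparison_study(
    base_seed: int, n_replicates: int = 10, epochs: int = 30
) -> pd.DataFrame:
    """Compound-loss vs ablation at matched seeds on a fixed phantom corpus.

    One row per replicate with held-out fascicle Dice and anatomical error
    rate for both losses. The phantom corpus is shared across replicates;
    replicates differ only in the training seed.
    """
    train, test = make_phantom_corpus(base_seed)
    rows = []
    for rep in range(n_replicates):
        seed = base_seed + rep
        topo = train_and_score(train, test, LossConfig(), seed, epochs)
        abl = train_and_score(train, test, LossConfig(use_topo=False), seed, epochs)
        rows.append({
            "replicate": rep,
            "seed": seed,
            "dice_topo": topo["fascicle_dice"],
            "dice_ablation": abl["fascicle_dice"],
            "err_topo": topo["anatomical_error_rate"],
            "err_ablation": abl["anatomical_error_rate"],
        })
    return pd.DataFrame(rows)
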