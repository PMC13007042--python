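"""Full-volume prediction by sliding-window tiling with Gaussian blending.

Volumes larger than the network's patch size are covered by overlapping
patches (25% overlap by default). Each patch's class scores are weighted by
a separable Gaussian centered on the patch (sd = 0.125 of the patch edge
per axis, the usual convention when only a relative sigma is quoted) and
accumulated; the blended score at a voxel is the weight-normalized sum, and
the label map is its argmax. Blending operates on softmax probabilities by
default (``apply="softmax"``) or raw logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import IntensityVolume, LabelVolume, normalize_intensity
from .losses import softmax
from .nn import UNet3D

__all__ = ["BlendConfig", "gaussian_weight_map", "tile_volume", "predict_volume"]


@dataclass
class BlendConfig:
    patch_size: tuple[int, int, int] = (32, 256, 256)
    overlap_fraction: float = 0.25
    sigma_rel: float = 0.125
    apply: str = "softmax"  # blend softmax probabilities or raw "logits"

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if not self.sigma_rel > 0:
            raise ValueError("sigma_rel must be > 0")
        if self.apply not in ("softmax", "logits"):
            raise ValueError("apply must be 'softmax' or 'logits'")


def gaussian_weight_map(
    patch_size: tuple[int, int, int], sigma_rel: float = 0.125
) -> np.ndarray:
    """Separable Gaussian patch weights, peak-normalized to 1 at the center.

    Per axis the sd is ``sigma_rel`` times the axis length; the product over
    axes gives a strictly positive 3D weight grid.
    """
    if min(patch_size) < 1:
        raise ValueError("patch dimensions must be >= 1")
    axes = []
    for n in patch_size:
        c = (n - 1) / 2.0
        sd = sigma_rel * n
        i = np.arange(n)
        axes.append(np.exp(-0.5 * ((i - c) / sd) ** 2))
    w = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    return (w / w.max()).astype(np.float64)


def tile_volume(
    shape: tuple[int, int, int], blend: BlendConfig
) -> list[tuple[int, int, int]]:
    """Patch origin coordinates covering ``shape`` with the configured overlap.

    Stride is ``round(patch * (1 - overlap))``; the final patch per axis is
    clamped to the boundary so every voxel is covered. The volume must be at
    least one patch in every axis (pad beforehand otherwise).
    """
    origins_per_axis = []
    for extent, patch in zip(shape, blend.patch_size):
        if extent < patch:
            raise ValueError(
                f"volume extent {extent} smaller than patch {patch}; pad first"
            )
        stride = max(1, int(round(patch * (1.0 - blend.overlap_fraction))))
        origins = list(range(0, extent - patch + 1, stride))
        if origins[-1] != extent - patch:
            origins.append(extent - patch)
        origins_per_axis.append(origins)
    return [
        (z, y, x)
        for z in origins_per_axis[0]
        for y in origins_per_axis[1]
        for x in origins_per_axis[2]
    ]


def predict_volume(
    vol: IntensityVolume,
    network: UNet3D,
    blend: BlendConfig | None = None,
) -> tuple[np.ndarray, LabelVolume]:
    """Predict class probabilities and labels for a full volume.

    The volume is intensity-normalized, padded (edge mode) up to the patch
    size if needed, tiled, and each patch's scores are Gaussian-blended.
    Returns ``(probabilities (class, z, y, x), LabelVolume)``.
    """
    blend = blend or BlendConfig()
    data = normalize_intensity(vol)
    orig_shape = data.shape
    pads = [(0, max(0, p - s)) for s, p in zip(orig_shape, blend.patch_size)]
    if any(p[1] for p in pads):
        data = np.pad(data, pads, mode="edge")
    weights = gaussian_weight_map(blend.patch_size, blend.sigma_rel)
    n_classes = network.n_classes
    acc = np.zeros((n_classes,) + data.shape, dtype=np.float64)
    wsum = np.zeros(data.shape, dtype=np.float64)
    pz, py, px = blend.patch_size
    for z0, y0, x0 in tile_volume(data.shape, blend):
        patch = data[z0:z0 + pz, y0:y0 + py, x0:x0 + px]
        scores = network.forward(patch[None]).astype(np.float64)
        if not np.all(np.isfinite(scores)):
            raise FloatingPointError("network produced non-finite scores")
        if blend.apply == "softmax":
            scores = softmax(scores, axis=0)
        acc[:, z0:z0 + pz, y0:y0 + py, x0:x0 + px] += scores * weights[None]
        wsum[z0:z0 + pz, y0:y0 + py, x0:x0 + px] += weights
    probs = acc / wsum[None]
    sl = tuple(slice(0, s) for s in orig_shape)
    probs = probs[(slice(None),) + sl]
    labels = np.argmax(probs, axis=0).astype(np.uint8)
    return probs, LabelVolume(labels=labels, spacing_um=vol.spacing_um)
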