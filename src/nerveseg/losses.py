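"""Anatomy-aware compound segmentation loss.

The training objective combines three terms::

    L = L_CE + L_Dice + lambda * L_Topo

``L_CE`` is voxel-wise cross-entropy, ``L_Dice`` is soft Dice loss over the
foreground classes, and ``L_Topo`` is cross-entropy restricted (Hadamard
product) to a *critical voxel map* ``V`` — the voxels where the hard-labeled
prediction violates the nerve's anatomical constraints:

1. fascicles must be completely enclosed by epineurium, and
2. fascicle voxels may never directly contact background voxels.

At voxel scale on a 26-connected lattice the two constraints coincide: a
fascicle voxel whose full 26-neighborhood contains no background voxel is
necessarily wrapped in epineurium (or more fascicle). ``V`` therefore flags
every fascicle/background pair of 26-adjacent voxels, on both sides of the
contact.

``V`` is recomputed from the hard argmax of the prediction at every step and
treated as a constant mask (straight-through); gradients flow only through
the cross-entropy term it gates.

Class probability grids are 4D arrays shaped ``(class, z, y, x)`` with the
class order (background, fascicle, epineurium), matching
:mod:`nerveseg.io` label codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .io import LABEL_BACKGROUND, LABEL_FASCICLE, LabelVolume

__all__ = [
    "LossConfig",
    "CompoundLoss",
    "critical_voxel_map",
    "cross_entropy",
    "dice_loss",
    "topology_loss",
    "compound_loss",
    "compound_loss_grad",
    "one_hot",
    "softmax",
]

_EPS = 1e-12

#: 3x3x3 all-ones structuring element = 26-connectivity neighborhood.
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LossConfig:
    """Configuration of the compound loss.

    Parameters
    ----------
    lambda_topo
        Weight of the topology term (default 1e6).
    use_topo
        Ablation switch; ``False`` trains with ``L_CE + L_Dice`` only.
    class_weights
        Optional per-class cross-entropy weights, length 3.
    dice_smooth
        Additive smoothing in the soft Dice numerator and denominator.
    topo_reduction
        Normalization of the masked cross-entropy: ``"total"`` (default)
        divides the flagged-voxel sum by the total voxel count, exactly a
        plain cross-entropy whose per-voxel terms are zeroed outside V — the
        masked-mean reading of CE(p (.) V, g (.) V). ``"mean"`` divides by
        the flagged-voxel count (scale-free in patch size but ill-conditioned
        under large lambda when few voxels are flagged); ``"sum"`` does not
        normalize.
    topo_grad_balance
        Per-term gradient balancing used only by the *training* gradient
        (:func:`compound_loss_grad`): the topology gradient is rescaled so
        its norm never exceeds ``balance`` times the norm of the
        conventional (CE + Dice) gradient. With the large default lambda the
        topology term would otherwise dominate every clipped update whenever
        any violation exists, starving the bulk segmentation objective;
        balancing keeps it a persistent, bounded corrective pressure.
        ``None`` disables balancing (literal weighted sum). Loss *values*
        are never rescaled.
    """

    lambda_topo: float = 1e6
    use_topo: bool = True
    class_weights: tuple[float, float, float] | None = None
    dice_smooth: float = 1e-5
    topo_reduction: str = "total"
    topo_grad_balance: float | None = 1.0

    def __post_init__(self) -> None:
        if self.lambda_topo < 0:
            raise ValueError("lambda_topo must be >= 0")
        if not self.dice_smooth > 0:
            raise ValueError("dice_smooth must be > 0")
        if self.topo_reduction not in ("total", "mean", "sum"):
            raise ValueError("topo_reduction must be 'total', 'mean' or 'sum'")


class CompoundLoss(NamedTuple):
    total: float
    ce: float
    dice: float
    topo: float


def _as_labels(pred_labels: LabelVolume | np.ndarray) -> np.ndarray:
    if isinstance(pred_labels, LabelVolume):
        return pred_labels.labels
    return np.asarray(pred_labels)


def critical_voxel_map(pred_labels: LabelVolume | np.ndarray) -> np.ndarray:
    """Binary mask V of voxels participating in an anatomical violation.

    A fascicle voxel and a background voxel are both flagged iff they are
    26-adjacent; the returned mask is the union over all such pairs.
    """
    labels = _as_labels(pred_labels)
    fasc = labels == LABEL_FASCICLE
    bg = labels == LABEL_BACKGROUND
    if not fasc.any() or not bg.any():
        return np.zeros(labels.shape, dtype=bool)
    fasc_near_bg = fasc & ndimage.binary_dilation(bg, structure=_STRUCT26)
    bg_near_fasc = bg & ndimage.binary_dilation(fasc, structure=_STRUCT26)
    return fasc_near_bg | bg_near_fasc


def one_hot(labels: LabelVolume | np.ndarray, n_classes: int = 3) -> np.ndarray:
    """One-hot encode a label grid to ``(class, z, y, x)`` float32."""
    lab = _as_labels(labels)
    out = np.zeros((n_classes,) + lab.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = lab == c
    return out


def softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _check_probs(p: np.ndarray, g: np.ndarray) -> None:
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs g {g.shape}")
    if p.ndim != 4:
        raise ValueError("probability grids must be (class, z, y, x)")


def cross_entropy(
    p: np.ndarray, g: np.ndarray, class_weights=None, mask: np.ndarray | None = None
) -> float:
    """Mean voxel-wise cross-entropy ``-sum_c g_c log p_c``.

    With ``mask`` given, the mean runs over masked voxels only and is 0 when
    the mask is empty.
    """
    _check_probs(p, g)
    logp = np.log(np.clip(p, _EPS, None))
    if class_weights is not None:
        w = np.asarray(class_weights, dtype=np.float64).reshape(-1, 1, 1, 1)
        per_vox = -(w * g * logp).sum(axis=0)
    else:
        per_vox = -(g * logp).sum(axis=0)
    if mask is not None:
        n = int(mask.sum())
        if n == 0:
            return 0.0
        return float(per_vox[mask].sum() / n)
    return float(per_vox.mean())


def dice_loss(p: np.ndarray, g: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Soft multi-class Dice loss averaged over the two foreground classes."""
    cfg = cfg or LossConfig()
    _check_probs(p, g)
    s = cfg.dice_smooth
    losses = []
    for c in (1, 2):
        inter = float((p[c] * g[c]).sum())
        denom = float(p[c].sum() + g[c].sum())
        losses.append(1.0 - (2.0 * inter + s) / (denom + s))
    return float(np.mean(losses))


def topology_loss(p: np.ndarray, g: np.ndarray, V: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Cross-entropy restricted to the critical voxel map V.

    Exactly 0 when V is empty; equals plain cross-entropy when V covers the
    whole grid (under mean reduction).
    """
    cfg = cfg or LossConfig()
    _check_probs(p, g)
    if V.shape != p.shape[1:]:
        raise ValueError(f"V shape {V.shape} does not match grid {p.shape[1:]}")
    V = V.astype(bool)
    n = int(V.sum())
    if n == 0:
        return 0.0
    logp = np.log(np.clip(p, _EPS, None))
    per_vox = -(g * logp).sum(axis=0)
    total = float(per_vox[V].sum())
    if cfg.topo_reduction == "mean":
        return total / n
    if cfg.topo_reduction == "total":
        return total / per_vox.size
    return total


def compound_loss(
    p: np.ndarray,
    g: np.ndarray,
    cfg: LossConfig | None = None,
    V: np.ndarray | None = None,
) -> CompoundLoss:
    """Total training loss and its components.

    ``V`` defaults to :func:`critical_voxel_map` of the argmax of ``p``. With
    ``cfg.use_topo`` False the topology term is skipped entirely (ablation).
    """
    cfg = cfg or LossConfig()
    ce = cross_entropy(p, g, cfg.class_weights)
    dsc = dice_loss(p, g, cfg)
    if cfg.use_topo:
        if V is None:
            V = critical_voxel_map(np.argmax(p, axis=0))
        topo = topology_loss(p, g, V, cfg)
        total = ce + dsc + cfg.lambda_topo * topo
    else:
        topo = 0.0
        total = ce + dsc
    return CompoundLoss(total=float(total), ce=ce, dice=dsc, topo=topo)


def compound_loss_grad(
    logits: np.ndarray, g: np.ndarray, cfg: LossConfig | None = None
) -> tuple[CompoundLoss, np.ndarray]:
    """Compound loss and its gradient with respect to the class logits.

    Used by the training loop: takes pre-softmax scores ``(class, z, y, x)``,
    returns the loss breakdown and ``dL/dlogits`` with V held constant
    (straight-through through the argmax).
    """
    cfg = cfg or LossConfig()
    _check_probs(logits, g)
    p = softmax(logits, axis=0)
    n_vox = p[0].size
    neg_logp = -np.log(np.clip(p, _EPS, None))

    # cross-entropy: d/dlogits of mean -log p[true] is (p - g)/N, with
    # optional per-class weighting folded in.
    if cfg.class_weights is not None:
        w = np.asarray(cfg.class_weights, dtype=p.dtype).reshape(-1, 1, 1, 1)
        wg = (w * g).sum(axis=0, keepdims=True)  # weight of the true class
        grad = (p * wg - w * g) / n_vox
        ce = float((w * g * neg_logp).sum() / n_vox)
    else:
        grad = (p - g) / n_vox
        ce = float((g * neg_logp).sum() / n_vox)

    # soft Dice over foreground classes: chain dL/dp through the softmax.
    s = cfg.dice_smooth
    dl_dp = np.zeros_like(p)
    dice_losses = []
    for c in (1, 2):
        inter = float((p[c] * g[c]).sum())
        denom = float(p[c].sum() + g[c].sum())
        num = 2.0 * inter + s
        den = denom + s
        dice_losses.append(1.0 - num / den)
        # L_c = 1 - num/den ; dL_c/dp_c(v) = -(2 g_v * den - num) / den^2
        dl_dp[c] = -(2.0 * g[c] * den - num) / (den * den) / 2.0  # mean over 2 classes
    inner = (dl_dp * p).sum(axis=0, keepdims=True)
    grad += p * (dl_dp - inner)
    dsc = float(np.mean(dice_losses))

    topo = 0.0
    if cfg.use_topo:
        V = critical_voxel_map(np.argmax(p, axis=0))
        n_flag = int(V.sum())
        if n_flag > 0:
            norm = {"mean": n_flag, "total": n_vox, "sum": 1}[cfg.topo_reduction]
            topo = float((g * neg_logp).sum(axis=0)[V].sum()) / norm
            g_topo = cfg.lambda_topo * V[None] * (p - g) / norm
            if cfg.topo_grad_balance is not None:
                conv_norm = float(np.sqrt((grad * grad).sum()))
                topo_norm = float(np.sqrt((g_topo * g_topo).sum()))
                cap = cfg.topo_grad_balance * conv_norm
                if topo_norm > cap > 0:
                    g_topo = g_topo * (cap / topo_norm)
            grad += g_topo
    total = ce + dsc + (cfg.lambda_topo * topo if cfg.use_topo else 0.0)
    return CompoundLoss(total=float(total), ce=ce, dice=dsc, topo=topo), grad
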