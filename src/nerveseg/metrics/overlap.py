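"""Volumetric and surface segmentation accuracy metrics.

All operate on binary masks (or a label volume plus a class id) over the
``(z, y, x)`` lattice. Surface voxels are defined by 6-connectivity face
exposure: a mask voxel with at least one face neighbor outside the mask
(voxels at the array border count as exposed). Border regions ``B(L, tau)``
are evaluated on the voxel lattice through a Euclidean distance transform
thresholded at ``tau``.

Empty-mask conventions (stated per metric rather than silently scored):

* ``dice_coefficient``: 1 when both masks are empty.
* ``surface_dice``: 1 when both masks are empty (undefined case, flagged via
  a warning); 0 when exactly one is empty.
* ``assd``: raises on any empty mask (no surface to measure from).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from ..io import LabelVolume

__all__ = [
    "surface_voxels",
    "dice_coefficient",
    "surface_dice",
    "assd",
    "confusion_stats",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _as_mask(m) -> np.ndarray:
    m = np.asarray(m)
    return m.astype(bool)


def _check_shapes(p: np.ndarray, g: np.ndarray) -> None:
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")


def surface_voxels(mask) -> np.ndarray:
    """S(L): mask voxels with >=1 face neighbor outside the mask."""
    mask = _as_mask(mask)
    eroded = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return mask & ~eroded


def dice_coefficient(p_mask, g_mask) -> float:
    """DSC = 2|P n G| / (|P| + |G|); 1 when both masks are empty."""
    p, g = _as_mask(p_mask), _as_mask(g_mask)
    _check_shapes(p, g)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def _dist_to_surface(surf: np.ndarray) -> np.ndarray:
    """Euclidean distance (voxels) from every voxel to the nearest surface voxel."""
    return ndimage.distance_transform_edt(~surf)


def surface_dice(p_mask, g_mask, tau: float = 1.0) -> float:
    """Surface DSC at tolerance ``tau`` (voxels).

    Fraction of each segmentation's surface lying within ``tau`` of the
    other's surface:
    ``(|B(P,tau) n S(G)| + |B(G,tau) n S(P)|) / (|S(P)| + |S(G)|)``.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    p, g = _as_mask(p_mask), _as_mask(g_mask)
    _check_shapes(p, g)
    sp, sg = surface_voxels(p), surface_voxels(g)
    n_sp, n_sg = int(sp.sum()), int(sg.sum())
    if n_sp + n_sg == 0:
        warnings.warn("surface_dice undefined for two empty masks; returning 1.0")
        return 1.0
    if n_sp == 0 or n_sg == 0:
        return 0.0
    in_bp = int((_dist_to_surface(sp)[sg] <= tau).sum())  # |B(P,tau) n S(G)|
    in_bg = int((_dist_to_surface(sg)[sp] <= tau).sum())  # |B(G,tau) n S(P)|
    return (in_bp + in_bg) / (n_sp + n_sg)


def assd(p_mask, g_mask, spacing_um: float = 1.0) -> float:
    """Average symmetric surface distance in micrometres.

    Sum of directed nearest-surface distances in both directions, normalized
    by the total surface voxel count, scaled by the isotropic voxel spacing.
    """
    p, g = _as_mask(p_mask), _as_mask(g_mask)
    _check_shapes(p, g)
    if not p.any() or not g.any():
        raise ValueError("assd undefined for an empty mask")
    sp, sg = surface_voxels(p), surface_voxels(g)
    d_to_sp = _dist_to_surface(sp)
    d_to_sg = _dist_to_surface(sg)
    total = float(d_to_sp[sg].sum() + d_to_sg[sp].sum())
    return total / (int(sp.sum()) + int(sg.sum())) * spacing_um


def confusion_stats(
    pred: LabelVolume | np.ndarray, truth: LabelVolume | np.ndarray, class_id: int
) -> dict[str, float]:
    """Per-class binary IoU, sensitivity, and specificity."""
    p_lab = pred.labels if isinstance(pred, LabelVolume) else np.asarray(pred)
    g_lab = truth.labels if isinstance(truth, LabelVolume) else np.asarray(truth)
    _check_shapes(p_lab, g_lab)
    p = p_lab == class_id
    g = g_lab == class_id
    tp = int((p & g).sum())
    fp = int((p & ~g).sum())
    fn = int((~p & g).sum())
    tn = int((~p & ~g).sum())
    return {
        "iou": tp / (tp + fp + fn) if tp + fp + fn else 1.0,
        "sensitivity": tp / (tp + fn) if tp + fn else 1.0,
        "specificity": tn / (tn + fp) if tn + fp else 1.0,
    }
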