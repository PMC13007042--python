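"""Anatomy-aware evaluation metrics.

Beyond voxel overlap, a nerve segmentation must preserve the *longitudinal*
structure of the organ: fascicles are continuous tubes that split and merge,
they are always wrapped in epineurium, and their cross-sectional boundaries
drift smoothly from slice to slice. The metrics here quantify exactly that:

* :func:`cldice` — centerline Dice: harmonic mean of skeleton-in-mask
  precision and sensitivity, sensitive to broken or spurious connections
  that bulk Dice barely notices;
* :func:`anatomical_error_rate` — fraction of foreground voxels violating
  the anatomical rules (fascicle touching background on the 26-neighborhood,
  or a single-slice class aberration between agreeing longitudinal
  neighbors);
* :func:`interslice_bf` — boundary-F1 between per-class contours of
  adjacent slices (inter-slice jitter);
* :func:`detect_split_merge_events` / :func:`event_rate_deviation` —
  overlap-linked component tracking of fascicle splits and merges along z,
  and the per-mm event-rate deviation between prediction and ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import skeletonize

from ..io import LABEL_FASCICLE, LabelVolume
from ..losses import critical_voxel_map

__all__ = [
    "EventTrack",
    "cldice",
    "anatomical_error_rate",
    "interslice_bf",
    "detect_split_merge_events",
    "event_rate_deviation",
]


@dataclass
class EventTrack:
    """Detected split/merge events of one volume and their per-mm rates."""

    events: list[tuple[str, int]]  # (kind, z of the slice pair start)
    length_mm: float

    def __post_init__(self) -> None:
        if not self.length_mm > 0:
            raise ValueError("segment length must be > 0")

    @property
    def n_split(self) -> int:
        return sum(1 for k, _ in self.events if k == "split")

    @property
    def n_merge(self) -> int:
        return sum(1 for k, _ in self.events if k == "merge")

    @property
    def rate_split(self) -> float:
        return self.n_split / self.length_mm

    @property
    def rate_merge(self) -> float:
        return self.n_merge / self.length_mm


def _as_mask(m) -> np.ndarray:
    return np.asarray(m).astype(bool)


def cldice(f_pred, f_true) -> float:
    """Centerline Dice between two binary fascicle masks.

    ``T_prec = |Sk(P) n G| / |Sk(P)|`` and ``T_sens = |Sk(G) n P| / |Sk(G)|``
    with 3D medial-axis skeletons; clDice is their harmonic mean. Returns 1
    for two empty masks and 0 (with a warning) when a nonempty mask yields an
    empty skeleton.
    """
    p, g = _as_mask(f_pred), _as_mask(f_true)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if not p.any() and not g.any():
        return 1.0
    sk_p = skeletonize(p) if p.any() else np.zeros_like(p)
    sk_g = skeletonize(g) if g.any() else np.zeros_like(g)
    n_p, n_g = int(sk_p.sum()), int(sk_g.sum())
    if n_p == 0 or n_g == 0:
        warnings.warn("degenerate clDice: empty skeleton on a nonempty mask")
        return 0.0
    t_prec = int((sk_p & g).sum()) / n_p
    t_sens = int((sk_g & p).sum()) / n_g
    if t_prec + t_sens == 0:
        return 0.0
    return 2.0 * t_prec * t_sens / (t_prec + t_sens)


def _abrupt_transition_mask(labels: np.ndarray, window: int = 1) -> np.ndarray:
    """Foreground voxels whose class differs from agreeing z-neighbors.

    A voxel at slice z is flagged when the voxels ``window`` slices before
    and after it (same y, x) agree with each other but not with it — the
    signature of a one-slice-thick spurious structure or a broken tube.
    """
    flags = np.zeros(labels.shape, dtype=bool)
    if labels.shape[0] < 2 * window + 1:
        return flags
    prev = labels[: -2 * window]
    nxt = labels[2 * window :]
    cur = labels[window:-window]
    flags[window:-window] = (prev == nxt) & (prev != cur) & (cur > 0)
    return flags


def anatomical_error_rate(
    pred: LabelVolume | np.ndarray, window: int = 1
) -> tuple[float, np.ndarray]:
    """Fraction of foreground voxels violating the anatomical rules.

    The error mask is the union of (1) fascicle voxels in 26-contact with
    background (critical voxel map restricted to foreground) and (2) abrupt
    single-slice class transitions along z. Returns ``(rate, error_mask)``.
    Raises when the volume has no foreground.
    """
    labels = pred.labels if isinstance(pred, LabelVolume) else np.asarray(pred)
    fg = labels > 0
    n_fg = int(fg.sum())
    if n_fg == 0:
        raise ValueError("anatomical error rate undefined: no foreground voxels")
    errors = (critical_voxel_map(labels) & fg) | _abrupt_transition_mask(labels, window)
    return int(errors.sum()) / n_fg, errors


def _slice_contour(mask2d: np.ndarray) -> np.ndarray:
    """One-pixel-wide contour: mask minus its 8-connected erosion."""
    struct = np.ones((3, 3), dtype=bool)
    return mask2d & ~ndimage.binary_erosion(mask2d, structure=struct, border_value=0)


def interslice_bf(
    pred: LabelVolume | np.ndarray,
    class_id: int,
    tau: float = 1.0,
    strict: bool = False,
) -> tuple[float, list[tuple[int, float]]]:
    """Mean boundary-F1 between contours of adjacent slices.

    For each slice pair, precision (recall) is the fraction of contour
    pixels of slice z (z+1) within Euclidean distance ``tau`` of the other
    slice's contour; the BF score is their harmonic mean. ``strict`` uses
    ``d < tau`` instead of the default inclusive ``d <= tau``. Pairs where
    both contours are empty are skipped; a pair with exactly one empty
    contour scores 0 (a vanished boundary is maximal jitter). Returns the
    mean and the per-pair ``(z, score)`` profile.
    """
    labels = pred.labels if isinstance(pred, LabelVolume) else np.asarray(pred)
    if labels.shape[0] < 2:
        raise ValueError("need at least two slices")
    mask = labels == class_id
    if not mask.any():
        raise ValueError(f"class {class_id} absent from the volume")
    profile: list[tuple[int, float]] = []
    contours = [_slice_contour(mask[z]) for z in range(labels.shape[0])]
    for z in range(labels.shape[0] - 1):
        b0, b1 = contours[z], contours[z + 1]
        n0, n1 = int(b0.sum()), int(b1.sum())
        if n0 == 0 and n1 == 0:
            continue
        if n0 == 0 or n1 == 0:
            profile.append((z, 0.0))
            continue
        d_to_b1 = ndimage.distance_transform_edt(~b1)
        d_to_b0 = ndimage.distance_transform_edt(~b0)
        if strict:
            prec = float((d_to_b1[b0] < tau).sum()) / n0
            rec = float((d_to_b0[b1] < tau).sum()) / n1
        else:
            prec = float((d_to_b1[b0] <= tau).sum()) / n0
            rec = float((d_to_b0[b1] <= tau).sum()) / n1
        score = 0.0 if prec + rec == 0 else 2.0 * prec * rec / (prec + rec)
        profile.append((z, score))
    mean = float(np.mean([s for _, s in profile])) if profile else float("nan")
    return mean, profile


def detect_split_merge_events(
    labels: LabelVolume | np.ndarray,
    spacing_um: float | None = None,
    min_overlap_px: int = 1,
    merge_window: int = 3,
) -> EventTrack:
    """Track fascicle components along z and detect split/merge events.

    Per-slice 8-connected fascicle components are linked between consecutive
    slices by pixel overlap of at least ``min_overlap_px``. One component
    overlapping two or more in the next slice is a split; two or more
    collapsing onto one is a merge. Detections of the same kind within
    ``merge_window`` slices whose junction footprints overlap are collapsed
    into a single event. Event z is the earlier slice of the pair.
    """
    lab = labels.labels if isinstance(labels, LabelVolume) else np.asarray(labels)
    if spacing_um is None:
        spacing_um = labels.spacing_um if isinstance(labels, LabelVolume) else 1.0
    n_z = lab.shape[0]
    if n_z < 2:
        raise ValueError("need at least two slices")
    comp = [measure.label(lab[z] == LABEL_FASCICLE, connectivity=2) for z in range(n_z)]

    raw: list[tuple[str, int, np.ndarray]] = []  # (kind, z, junction footprint)
    for z in range(n_z - 1):
        a, b = comp[z], comp[z + 1]
        na, nb = a.max(), b.max()
        if na == 0 or nb == 0:
            continue
        # overlap counts between components of the two slices
        pair = a.astype(np.int64) * (nb + 1) + b
        counts = np.bincount(pair[(a > 0) & (b > 0)].ravel(), minlength=(na + 1) * (nb + 1))
        overlap = counts.reshape(na + 1, nb + 1)[1:, 1:] >= min_overlap_px
        for i in range(na):
            succ = np.nonzero(overlap[i])[0]
            if len(succ) >= 2:
                foot = (a == i + 1) | np.isin(b, succ + 1)
                raw.append(("split", z, foot))
        for j in range(nb):
            pred_ids = np.nonzero(overlap[:, j])[0]
            if len(pred_ids) >= 2:
                foot = (b == j + 1) | np.isin(a, pred_ids + 1)
                raw.append(("merge", z, foot))

    # de-duplicate: same kind, close in z, overlapping junction footprint
    events: list[tuple[str, int]] = []
    for kind in ("split", "merge"):
        group_foot: np.ndarray | None = None
        group_z = -(10 * merge_window)
        for k, z, foot in sorted((r for r in raw if r[0] == kind), key=lambda r: r[1]):
            if z - group_z <= merge_window and group_foot is not None and (group_foot & foot).any():
                group_foot = group_foot | foot
                group_z = z
                continue
            events.append((kind, z))
            group_foot = foot
            group_z = z
    events.sort(key=lambda e: e[1])
    return EventTrack(events=events, length_mm=n_z * spacing_um / 1000.0)


def event_rate_deviation(
    pred_track: EventTrack, gt_track: EventTrack
) -> dict[str, float]:
    """Split/merge rate deviation between prediction and ground truth.

    Absolute form: ``(|dR_split| + |dR_merge|) / 2`` in events/mm, where
    ``dR = R_pred - R_gt``. The relative form expresses the same deviation
    as a percentage of the mean ground-truth event rate (NaN when the ground
    truth has no events).
    """
    if abs(pred_track.length_mm - gt_track.length_mm) > 1e-9:
        raise ValueError("tracks cover different segment lengths")
    d_split = pred_track.rate_split - gt_track.rate_split
    d_merge = pred_track.rate_merge - gt_track.rate_merge
    dev = (abs(d_split) + abs(d_merge)) / 2.0
    gt_mean = (gt_track.rate_split + gt_track.rate_merge) / 2.0
    rel = dev / gt_mean * 100.0 if gt_mean > 0 else float("nan")
    return {"deviation_per_mm": dev, "deviation_pct": rel}
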