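"""Full evaluation report for a prediction / ground-truth volume pair."""

from __future__ import annotations

from typing import Any

import numpy as np

from ..io import LABEL_EPINEURIUM, LABEL_FASCICLE, LabelVolume
from .anatomy import (
    anatomical_error_rate,
    cldice,
    detect_split_merge_events,
    event_rate_deviation,
    interslice_bf,
)
from .instances import SizeBins, f1_curve, missed_by_size, over_under_segmentation
from .overlap import assd, confusion_stats, dice_coefficient, surface_dice

REPORT_SCHEMA_VERSION = 1

_CLASSES = {"fascicle": LABEL_FASCICLE, "epineurium": LABEL_EPINEURIUM}


def evaluate_pair(
    pred: LabelVolume,
    truth: LabelVolume,
    tau_voxels: float = 1.0,
    bins: SizeBins | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Compute every evaluation metric for one volume pair.

    Returns a JSON-serializable dict keyed metric -> class -> value, plus
    instance-level and event-level sections. The over-/under-segmentation
    counting rule below the IoU threshold (majority cover) is a convention
    of this package and is flagged in the report.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    bins = bins or SizeBins()
    spacing = truth.spacing_um
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "spacing_um": spacing,
        "seed": seed,
        "conventions": {
            "surface_tolerance_voxels": tau_voxels,
            "over_under_rule": "majority-cover",
            "bf_tolerance_px": 1,
        },
    }
    dsc, sdsc, asd, conf = {}, {}, {}, {}
    for name, cid in _CLASSES.items():
        p = pred.labels == cid
        g = truth.labels == cid
        dsc[name] = dice_coefficient(p, g)
        sdsc[name] = surface_dice(p, g, tau=tau_voxels)
        asd[name] = assd(p, g, spacing_um=spacing) if p.any() and g.any() else None
        conf[name] = confusion_stats(pred, truth, cid)
    report["dice"] = dsc
    report["surface_dice"] = sdsc
    report["assd_um"] = asd
    report["confusion"] = conf

    report["instance_f1"] = {f"{t:.2f}": v for t, v in f1_curve(truth, pred, bins=bins).items()}
    report["over_under"] = over_under_segmentation(truth, pred, t=0.7, bins=bins)
    report["missed_by_size"] = missed_by_size(truth, pred, t=0.7, bins=bins)

    report["cldice"] = cldice(pred.fascicle_mask(), truth.fascicle_mask())
    err_rate, _ = anatomical_error_rate(pred)
    report["anatomical_error_rate"] = err_rate
    bf = {}
    for name, cid in _CLASSES.items():
        mean, _profile = interslice_bf(pred, cid)
        bf[name] = mean
    report["interslice_bf"] = bf

    pred_track = detect_split_merge_events(pred)
    gt_track = detect_split_merge_events(truth)
    report["events"] = {
        "pred": {"n_split": pred_track.n_split, "n_merge": pred_track.n_merge},
        "truth": {"n_split": gt_track.n_split, "n_merge": gt_track.n_merge},
        **event_rate_deviation(pred_track, gt_track),
    }
    return _to_builtin(report)


def _to_builtin(obj):
    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
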