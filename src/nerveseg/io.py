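"""Reading, writing and preprocessing of nerve microCT volumes.

Volumes are 3D grids indexed ``(z, y, x)`` where ``z`` is the nerve's
longitudinal axis. Two kinds of volume exist:

* :class:`IntensityVolume` — single-channel grayscale microCT data, natively
  signed 16-bit (negative values are reconstruction artifacts outside tissue).
* :class:`LabelVolume` — 3-class semantic labels with the fixed coding
  0 = background, 1 = fascicle, 2 = epineurium.

Both carry an isotropic voxel spacing in micrometres (default 11.4 µm, the
scanner resolution of the nerve volumes this package targets).

Supported on-disk formats are multi-page TIFF stacks (16-bit intensity,
8-bit labels) and Zarr arrays with the spacing stored in array attributes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Union

import numpy as np
import tifffile
import zarr

__all__ = [
    "DEFAULT_SPACING_UM",
    "LABEL_BACKGROUND",
    "LABEL_FASCICLE",
    "LABEL_EPINEURIUM",
    "IntensityVolume",
    "LabelVolume",
    "load_volume",
    "save_volume",
    "normalize_intensity",
    "combine_labels",
]

DEFAULT_SPACING_UM = 11.4

LABEL_BACKGROUND = 0
LABEL_FASCICLE = 1
LABEL_EPINEURIUM = 2

#: Upper clip bound of the 16-bit intensity range used for normalization.
INTENSITY_CLIP_MAX = 32767

VALID_LABELS = frozenset({LABEL_BACKGROUND, LABEL_FASCICLE, LABEL_EPINEURIUM})

VolumeFormat = Literal["tiff", "zarr"]


def _check_grid(data: np.ndarray) -> None:
    if data.ndim != 3:
        raise ValueError(f"volume must be 3D (z, y, x), got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValueError(f"all dimensions must be >= 1, got shape {data.shape}")


@dataclass
class IntensityVolume:
    """Single-channel grayscale volume indexed ``(z, y, x)``."""

    data: np.ndarray
    spacing_um: float = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_grid(self.data)
        if not self.spacing_um > 0:
            raise ValueError(f"spacing_um must be > 0, got {self.spacing_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """3-class label volume (0 background, 1 fascicle, 2 epineurium)."""

    labels: np.ndarray
    spacing_um: float = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        _check_grid(self.labels)
        if not self.spacing_um > 0:
            raise ValueError(f"spacing_um must be > 0, got {self.spacing_um}")
        present = set(np.unique(self.labels).tolist())
        if not present <= VALID_LABELS:
            raise ValueError(
                f"label values outside {{0, 1, 2}} present: {sorted(present - VALID_LABELS)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def fascicle_mask(self) -> np.ndarray:
        """Binary mask of the fascicle class (the F mask of instance metrics)."""
        return self.labels == LABEL_FASCICLE

    def epineurium_mask(self) -> np.ndarray:
        return self.labels == LABEL_EPINEURIUM


Volume = Union[IntensityVolume, LabelVolume]


def _infer_format(path: Path) -> VolumeFormat:
    if path.suffix.lower() in {".tif", ".tiff"}:
        return "tiff"
    if path.suffix.lower() == ".zarr" or path.is_dir():
        return "zarr"
    raise ValueError(f"cannot infer volume format from path {path!r}")


def load_volume(
    path: os.PathLike | str,
    format: VolumeFormat | None = None,
    kind: Literal["intensity", "labels"] = "intensity",
    spacing_um: float | None = None,
) -> Volume:
    """Load a volume from a TIFF stack or a Zarr array.

    Parameters
    ----------
    path
        File (TIFF) or directory (Zarr) to read.
    format
        ``"tiff"`` or ``"zarr"``; inferred from the path when omitted.
    kind
        ``"intensity"`` returns an :class:`IntensityVolume`; ``"labels"``
        validates the value range and returns a :class:`LabelVolume`.
    spacing_um
        Overrides the stored / default voxel spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = format or _infer_format(path)
    stored_spacing = None
    if fmt == "tiff":
        data = tifffile.imread(path)
        if data.ndim == 2:  # single-page stack
            data = data[None]
    elif fmt == "zarr":
        arr = zarr.open_array(str(path), mode="r")
        data = np.asarray(arr[:])
        stored_spacing = dict(arr.attrs).get("spacing_um")
    else:
        raise ValueError(f"unknown format {format!r}")
    _check_grid(data)
    spacing = spacing_um or stored_spacing or DEFAULT_SPACING_UM
    if kind == "labels":
        return LabelVolume(labels=data, spacing_um=spacing)
    return IntensityVolume(data=data, spacing_um=spacing)


def save_volume(
    vol: Volume, path: os.PathLike | str, format: VolumeFormat | None = None
) -> None:
    """Write a volume; ``load_volume(save_volume(v))`` is bit-exact for integer grids."""
    path = Path(path)
    fmt = format or _infer_format(path)
    data = vol.labels if isinstance(vol, LabelVolume) else vol.data
    if isinstance(vol, LabelVolume):
        data = data.astype(np.uint8, copy=False)
    if fmt == "tiff":
        tifffile.imwrite(path, data, photometric="minisblack")
    elif fmt == "zarr":
        arr = zarr.create_array(
            store=str(path), shape=data.shape, dtype=data.dtype, overwrite=True
        )
        arr[:] = data
        arr.attrs["spacing_um"] = float(vol.spacing_um)
        arr.attrs["axes"] = "zyx"
    else:
        raise ValueError(f"unknown format {format!r}")


def normalize_intensity(vol: IntensityVolume | np.ndarray) -> np.ndarray:
    """Map raw 16-bit intensities to the unit interval.

    Values are clipped to ``[0, 32767]`` (removing negative reconstruction
    artifacts) and divided by 32767, so the output lies in ``[0, 1]``.
    """
    data = vol.data if isinstance(vol, IntensityVolume) else np.asarray(vol)
    return np.clip(data, 0, INTENSITY_CLIP_MAX).astype(np.float32) / INTENSITY_CLIP_MAX


def combine_labels(
    fascicle_mask: np.ndarray,
    epineurium_mask: np.ndarray,
    spacing_um: float = DEFAULT_SPACING_UM,
) -> LabelVolume:
    """Merge binary class masks into one label volume.

    Where the masks overlap the fascicle label wins, so fascicle geometry is
    never eaten by the surrounding epineurium annotation.
    """
    fascicle_mask = np.asarray(fascicle_mask).astype(bool)
    epineurium_mask = np.asarray(epineurium_mask).astype(bool)
    if fascicle_mask.shape != epineurium_mask.shape:
        raise ValueError(
            f"mask shapes differ: {fascicle_mask.shape} vs {epineurium_mask.shape}"
        )
    labels = np.zeros(fascicle_mask.shape, dtype=np.uint8)
    labels[epineurium_mask] = LABEL_EPINEURIUM
    labels[fascicle_mask] = LABEL_FASCICLE
    return LabelVolume(labels=labels, spacing_um=spacing_um)
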