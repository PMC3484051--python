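"""Peribronchial shell construction and attenuation densitometry.

The peribronchial shell is built in the three steps that follow lumen
segmentation: (1) 3D morphological dilation of the lumen mask by a fixed
radius (8 voxels by default), (2) a second lumen-band segmentation inside
the dilated volume of interest, which captures all luminal air including
disconnected pockets swept up by the dilation, and (3) subtraction of that
air — plus an optional trachea/mediastinum exclusion mask — leaving only
the peribronchial tissue.

From the shell and the lung field come the three statistics of interest:

* ``TLA``  — total lung attenuation, the mean HU over the lung mask;
* ``PBA``  — peribronchial attenuation, the mean HU over the shell;
* ``normalized PBA`` = 1 − (PBA / TLA), a dimensionless index designed to
  cancel diffuse parenchymal attenuation changes (inflammation) while
  remaining sensitive to attenuation concentrated around the airways
  (wall remodeling).

Dilation semantics: "radius r" means Euclidean distance ≤ r in voxel units
(computed with a distance transform).  A compatibility mode iterates the
face-connected unit structuring element r times instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .segmentation import LUMEN_BAND, ThresholdBand
from .volume_io import CTVolume, VoxelMask

__all__ = [
    "ShellParams",
    "AttenuationSummary",
    "DEFAULT_DILATION_RADIUS",
    "dilate_mask",
    "peribronchial_shell",
    "mean_attenuation",
    "normalized_pba",
    "normalize_image",
    "summarize",
]

#: Default dilation radius in voxels; found optimal for matching the
#: manually delineated peribronchial region at 46 µm isotropic voxels.
DEFAULT_DILATION_RADIUS = 8.0


@dataclass(frozen=True)
class ShellParams:
    dilation_radius_voxels: float = DEFAULT_DILATION_RADIUS
    lumen_band: ThresholdBand = LUMEN_BAND
    dilation_mode: str = "euclidean"  # or "iterated_face"
    restrict_shell_to_lung: bool = False
    exclusion_applied: bool = False

    def __post_init__(self) -> None:
        if self.dilation_radius_voxels <= 0:
            raise ValueError("dilation_radius_voxels must be > 0")
        if self.dilation_mode not in ("euclidean", "iterated_face"):
            raise ValueError(f"unknown dilation_mode {self.dilation_mode!r}")


@dataclass(frozen=True)
class AttenuationSummary:
    """TLA, PBA, normalized PBA and the voxel counts behind them."""

    tla_hu: float
    pba_hu: float
    normalized_pba: float
    lung_voxels: int
    shell_voxels: int

    def __post_init__(self) -> None:
        if self.lung_voxels <= 0 or self.shell_voxels <= 0:
            raise ValueError("summary requires nonempty lung and shell masks")

    def as_dict(self) -> dict:
        return {
            "tla_hu": self.tla_hu,
            "pba_hu": self.pba_hu,
            "normalized_pba": self.normalized_pba,
            "lung_voxels": self.lung_voxels,
            "shell_voxels": self.shell_voxels,
        }


def dilate_mask(mask: VoxelMask, radius_voxels: float, mode: str = "euclidean") -> VoxelMask:
    """3D morphological dilation of a binary mask.

    In ``"euclidean"`` mode the result is the set of voxels whose Euclidean
    distance (in voxel units) to the nearest true voxel is ≤ ``radius_voxels``;
    in ``"iterated_face"`` mode the face-connected unit element is applied
    ``round(radius_voxels)`` times.  Either way the result is a superset of
    the input.
    """
    if mask.voxel_count == 0:
        raise ValueError("cannot dilate an empty mask")
    if radius_voxels <= 0:
        raise ValueError("dilation radius must be > 0")
    if mask.grid is not None:
        mask.grid.require_isotropic()
    if mode == "euclidean":
        dist = ndimage.distance_transform_edt(~mask.data)
        out = dist <= radius_voxels
    elif mode == "iterated_face":
        out = ndimage.binary_dilation(
            mask.data, structure=ndimage.generate_binary_structure(3, 1),
            iterations=int(round(radius_voxels)))
    else:
        raise ValueError(f"unknown dilation mode {mode!r}")
    return VoxelMask(out, grid=mask.grid)


def peribronchial_shell(
    volume: CTVolume,
    lumen: VoxelMask,
    params: ShellParams = ShellParams(),
    exclusion: Optional[VoxelMask] = None,
    lung: Optional[VoxelMask] = None,
) -> VoxelMask:
    """Build the peribronchial shell around a segmented lumen.

    ``shell = dilate(lumen, r)  minus  lumen-band voxels  minus  exclusion``.

    The lumen-band subtraction is the "second segmentation": a plain
    threshold inside the dilated VOI, so any disconnected air pocket swept
    up by the dilation is removed along with the original lumen.  The shell
    is therefore disjoint from every in-band voxel.  Pass ``lung`` together
    with ``params.restrict_shell_to_lung`` to clip leakage outside the lung
    field (off by default).
    """
    if lumen.voxel_count == 0:
        raise ValueError("lumen mask is empty")
    if exclusion is not None and exclusion.data.shape != volume.shape:
        raise ValueError("exclusion mask is not on the volume grid")
    dilated = dilate_mask(lumen, params.dilation_radius_voxels, mode=params.dilation_mode)
    shell = dilated.data & ~params.lumen_band.contains(volume.data)
    if exclusion is not None:
        shell &= ~exclusion.data
    if params.restrict_shell_to_lung:
        if lung is None:
            raise ValueError("restrict_shell_to_lung requires a lung mask")
        shell &= lung.data
    if not shell.any():
        raise ValueError(
            "empty peribronchial shell: dilation radius too small or exclusion too aggressive"
        )
    return VoxelMask(shell, grid=volume)


def mean_attenuation(volume: CTVolume, mask: VoxelMask) -> float:
    """Arithmetic mean HU over the masked voxels."""
    if mask.data.shape != volume.shape:
        raise ValueError("mask is not on the volume grid")
    if mask.voxel_count == 0:
        raise ValueError("mean attenuation of an empty mask is undefined")
    return float(volume.data[mask.data].mean(dtype=np.float64))


def normalized_pba(pba_hu: float, tla_hu: float) -> float:
    """Normalized peribronchial attenuation: ``1 − (PBA / TLA)``."""
    if tla_hu == 0:
        raise ZeroDivisionError("normalized PBA undefined: TLA is 0 HU")
    return 1.0 - (pba_hu / tla_hu)


def normalize_image(volume: CTVolume, tla_hu: float) -> CTVolume:
    """Voxelwise normalization ``y = 1 − (x / TLA)``.

    The result is dimensionless (flagged non-HU): 0 where the voxel equals
    the mean lung attenuation, 1 where it is 0 HU.
    """
    if tla_hu == 0:
        raise ZeroDivisionError("image normalization undefined: TLA is 0 HU")
    data = 1.0 - (volume.data.astype(np.float64) / tla_hu)
    return CTVolume(data=data, spacing=volume.spacing, hu_calibrated=False,
                    provenance=volume.provenance + " [normalized: y=1-(x/TLA)]")


def summarize(volume: CTVolume, lung: VoxelMask, shell: VoxelMask) -> AttenuationSummary:
    """Assemble TLA, PBA and normalized PBA from the lung and shell masks.

    TLA and PBA are computed on their own masks independently; the masks may
    overlap.
    """
    tla = mean_attenuation(volume, lung)
    pba = mean_attenuation(volume, shell)
    return AttenuationSummary(
        tla_hu=tla,
        pba_hu=pba,
        normalized_pba=normalized_pba(pba, tla),
        lung_voxels=lung.voxel_count,
        shell_voxels=shell.voxel_count,
    )
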