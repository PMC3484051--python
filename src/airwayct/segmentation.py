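"""Seeded bi-threshold volume-growing segmentation.

The bronchial lumen and the aerated lung field are both segmented the same
way: keep the voxels whose HU lies inside a closed threshold band, then grow
from explicit seed voxels through connected in-band voxels.  The default
bands are −1024..−900 HU for the air-filled lumen and −900..−100 HU for the
aerated lung (the support of total lung attenuation, TLA).  Both bounds are
inclusive, so a voxel at exactly −900 HU belongs to both bands; the shell
construction downstream resolves that overlap in favour of the lumen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, VoxelMask

__all__ = [
    "SeedPoint",
    "ThresholdBand",
    "LUMEN_BAND",
    "LUNG_BAND",
    "grow_region",
    "segment_lumen",
    "segment_lung",
    "auto_seed",
]


@dataclass(frozen=True)
class SeedPoint:
    """An integer voxel coordinate ``(z, y, x)`` on the volume grid."""

    index: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "index", tuple(int(i) for i in self.index))
        if len(self.index) != 3:
            raise ValueError(f"seed index must be a voxel triple, got {self.index}")


@dataclass(frozen=True)
class ThresholdBand:
    """A closed HU interval [lo, hi]; both bounds inclusive."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"threshold band requires lo < hi, got [{self.lo}, {self.hi}]")

    def contains(self, values: np.ndarray) -> np.ndarray:
        return (values >= self.lo) & (values <= self.hi)


#: Bronchial-lumen band: air-filled voxels down to the scanner minimum.
LUMEN_BAND = ThresholdBand(-1024.0, -900.0)
#: Aerated-lung band: support of total lung attenuation (TLA).
LUNG_BAND = ThresholdBand(-900.0, -100.0)

_STRUCTURES = {
    "face6": ndimage.generate_binary_structure(3, 1),
    "full26": ndimage.generate_binary_structure(3, 3),
}


def _as_seed_list(seeds: Iterable) -> list[SeedPoint]:
    out = []
    for s in seeds:
        out.append(s if isinstance(s, SeedPoint) else SeedPoint(tuple(s)))
    return out


def grow_region(
    volume: CTVolume,
    seeds: Sequence[SeedPoint] | Sequence[tuple[int, int, int]],
    band: ThresholdBand,
    connectivity: str = "face6",
) -> VoxelMask:
    """Volume growing from seed voxels through connected in-band voxels.

    Returns exactly the union of the connected components (under
    ``connectivity``, ``"face6"`` or ``"full26"``) of the in-band voxel set
    that contain at least one seed.  Deterministic for fixed inputs.

    Raises
    ------
    ValueError
        If the seed list is empty, a seed is out of bounds, or a seed's
        voxel value lies outside ``band`` (the error names the seed).
    """
    seeds = _as_seed_list(seeds)
    if not seeds:
        raise ValueError("grow_region requires at least one seed")
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 'face6' or 'full26', got {connectivity!r}")
    data = volume.data
    for s in seeds:
        if any(i < 0 or i >= n for i, n in zip(s.index, data.shape)):
            raise ValueError(f"seed {s.index} outside volume bounds {data.shape}")
        v = float(data[s.index])
        if not (band.lo <= v <= band.hi):
            raise ValueError(
                f"seed {s.index} has value {v:.1f} HU outside band [{band.lo}, {band.hi}]"
            )
    in_band = band.contains(data)
    labels, _ = ndimage.label(in_band, structure=_STRUCTURES[connectivity])
    wanted = {int(labels[s.index]) for s in seeds}
    wanted.discard(0)  # cannot happen: seeds are in band
    mask = np.isin(labels, sorted(wanted))
    return VoxelMask(mask, grid=volume)


def segment_lumen(
    volume: CTVolume,
    seeds: Sequence[SeedPoint] | Sequence[tuple[int, int, int]],
    band: ThresholdBand = LUMEN_BAND,
    connectivity: str = "face6",
) -> VoxelMask:
    """Segment the air-filled bronchial lumen (default band −1024..−900 HU)."""
    if not volume.hu_calibrated:
        raise ValueError("segment_lumen requires an HU-calibrated volume")
    mask = grow_region(volume, seeds, band, connectivity)
    if mask.voxel_count == 0:
        raise ValueError("empty lumen segmentation: check seed placement and calibration")
    return mask


def segment_lung(
    volume: CTVolume,
    seeds: Sequence[SeedPoint] | Sequence[tuple[int, int, int]],
    band: ThresholdBand = LUNG_BAND,
    connectivity: str = "face6",
) -> VoxelMask:
    """Segment the aerated lung field (default band −900..−100 HU).

    The returned mask is the support over which TLA is computed.
    """
    if not volume.hu_calibrated:
        raise ValueError("segment_lung requires an HU-calibrated volume")
    mask = grow_region(volume, seeds, band, connectivity)
    if mask.voxel_count == 0:
        raise ValueError("empty lung segmentation: check seed placement and calibration")
    return mask


def auto_seed(volume: CTVolume, band: ThresholdBand = LUMEN_BAND,
              connectivity: str = "face6") -> SeedPoint:
    """Propose a seed: the centroid voxel of the most cranial in-band component.

    Mimics the obvious manual choice of seeding in the trachea (the airway
    component that reaches the most cranial slices, lowest *z*).  The
    centroid is snapped to the nearest in-band voxel of that component.
    """
    in_band = band.contains(volume.data)
    labels, n = ndimage.label(in_band, structure=_STRUCTURES[connectivity])
    if n == 0:
        raise ValueError("auto_seed found no in-band voxels")
    # component whose minimum z-slice is most cranial; ties -> larger component
    objects = ndimage.find_objects(labels)
    sizes = ndimage.sum_labels(in_band, labels, index=range(1, n + 1))
    order = sorted(range(n), key=lambda i: (objects[i][0].start, -sizes[i]))
    lab = order[0] + 1
    comp = labels == lab
    centroid = np.array(ndimage.center_of_mass(comp))
    coords = np.argwhere(comp)
    nearest = coords[np.argmin(((coords - centroid) ** 2).sum(axis=1))]
    return SeedPoint(tuple(int(c) for c in nearest))
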