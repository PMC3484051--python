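"""Reading, writing and Hounsfield-Unit calibration of 3D attenuation volumes.

Volumes are stored in memory as ``(z, y, x)`` arrays with *z* the
cranio-caudal axis; voxel spacing is carried in micrometres.  Supported
on-disk containers are NIfTI (``.nii``/``.nii.gz``, via nibabel) and
MetaImage (``.mha``, uncompressed; ``.mhd``+``.raw`` read-only).  DICOM
series are not supported in this build because no DICOM library is
available; :func:`read_volume` raises a descriptive error for them.

Raw (uncalibrated) scanner values are mapped to the HU scale with a
two-point affine transform anchored on in-field air and water standards:
air -> -1000 HU, water -> 0 HU.  A bone standard, when supplied, is passed
through the fitted map and reported as a linearity diagnostic only.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "CalibrationStandards",
    "VoxelMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "calibrate_to_hu",
    "read_standards_csv",
    "HU_MIN",
]

logger = logging.getLogger("airwayct")

#: Minimum representable attenuation on the CT scale used throughout.
HU_MIN = -1024.0

#: Relative tolerance within which voxel spacing counts as isotropic.
ISOTROPY_RTOL = 0.01


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CTVolume:
    """A 3D scalar attenuation grid.

    Parameters
    ----------
    data
        3D array of attenuation values, indexed ``(z, y, x)`` with *z* the
        cranio-caudal axis.  HU after calibration.
    spacing
        Per-axis voxel edge length in micrometres, ``(z, y, x)`` order.
    hu_calibrated
        True when ``data`` is on the Hounsfield scale.
    provenance
        Free-text source descriptor (file path, generator spec, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (46.0, 46.0, 46.0)
    hu_calibrated: bool = True
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three strictly positive values, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains undefined (non-finite) values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def is_isotropic(self, rtol: float = ISOTROPY_RTOL) -> bool:
        """True when all voxel edges agree within ``rtol`` relative tolerance."""
        s = np.asarray(self.spacing)
        return bool(np.all(np.abs(s - s.mean()) <= rtol * s.mean()))

    def require_isotropic(self) -> None:
        """Distance-dependent operations call this before measuring anything."""
        if not self.is_isotropic():
            raise ValueError(
                f"operation requires isotropic voxels (within {ISOTROPY_RTOL:.0%}); "
                f"got spacing {self.spacing} µm — resample the volume first"
            )


@dataclass(frozen=True)
class CalibrationStandards:
    """Mean raw values over in-field calibration standards.

    ``air_raw`` and ``water_raw`` anchor the affine raw->HU map; ``bone_raw``
    is optional and only checked for linearity after the fit.
    """

    air_raw: float
    water_raw: float
    bone_raw: Optional[float] = None
    air_hu: float = -1000.0
    water_hu: float = 0.0

    def __post_init__(self) -> None:
        if self.air_raw == self.water_raw:
            raise ValueError("degenerate calibration: air_raw equals water_raw")
        if not self.air_raw < self.water_raw:
            raise ValueError(
                f"air_raw ({self.air_raw}) must be below water_raw ({self.water_raw}): "
                "raw attenuation increases with density"
            )


@dataclass
class VoxelMask:
    """A binary 3D selection on a :class:`CTVolume` grid."""

    data: np.ndarray
    grid: Optional[CTVolume] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.data.ndim}")
        if self.grid is not None and self.grid.shape != self.data.shape:
            raise ValueError(
                f"mask shape {self.data.shape} does not match volume shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def __and__(self, other: "VoxelMask") -> "VoxelMask":
        return VoxelMask(self.data & other.data, grid=self.grid)

    def __or__(self, other: "VoxelMask") -> "VoxelMask":
        return VoxelMask(self.data | other.data, grid=self.grid)

    def __sub__(self, other: "VoxelMask") -> "VoxelMask":
        return VoxelMask(self.data & ~other.data, grid=self.grid)


# ---------------------------------------------------------------------------
# MetaImage (.mha / .mhd) — minimal uncompressed implementation
# ---------------------------------------------------------------------------

_MET_TO_DTYPE = {
    "MET_CHAR": np.int8, "MET_UCHAR": np.uint8,
    "MET_SHORT": np.int16, "MET_USHORT": np.uint16,
    "MET_INT": np.int32, "MET_UINT": np.uint32,
    "MET_LONG": np.int64, "MET_ULONG": np.uint64,
    "MET_FLOAT": np.float32, "MET_DOUBLE": np.float64,
}
_DTYPE_TO_MET = {np.dtype(v): k for k, v in _MET_TO_DTYPE.items()}


def _read_metaimage(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    header: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"unreadable MetaImage header in {path}")
            key, _, val = line.decode("ascii", "replace").partition("=")
            key, val = key.strip(), val.strip()
            header[key] = val
            if key == "ElementDataFile":
                break
        if int(header.get("NDims", "0")) != 3:
            raise ValueError(f"{path}: only 3D MetaImage volumes are supported")
        dims = tuple(int(d) for d in header["DimSize"].split())  # (x, y, z)
        dtype = _MET_TO_DTYPE.get(header.get("ElementType", ""))
        if dtype is None:
            raise ValueError(f"{path}: unsupported ElementType {header.get('ElementType')}")
        if header.get("CompressedData", "False").lower() == "true":
            raise ValueError(f"{path}: compressed MetaImage data is not supported")
        spacing_xyz = tuple(float(s) for s in header.get("ElementSpacing", "1 1 1").split())
        datafile = header["ElementDataFile"]
        if datafile == "LOCAL":
            raw = fh.read()
        else:
            raw = (path.parent / datafile).read_bytes()
    count = dims[0] * dims[1] * dims[2]
    arr = np.frombuffer(raw, dtype=dtype, count=count)
    if arr.size != count:
        raise ValueError(f"{path}: raw data shorter than DimSize implies")
    # MetaImage raw order is x-fastest; reshape to (z, y, x)
    data = arr.reshape(dims[2], dims[1], dims[0])
    spacing_zyx = (spacing_xyz[2], spacing_xyz[1], spacing_xyz[0])
    return data, spacing_zyx


def _write_metaimage(path: Path, data: np.ndarray, spacing_zyx: tuple[float, float, float]) -> None:
    dt = np.dtype(data.dtype)
    if dt not in _DTYPE_TO_MET:
        data = data.astype(np.float64)
        dt = data.dtype
    nz, ny, nx = data.shape
    sz, sy, sx = spacing_zyx
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        f"BinaryDataByteOrderMSB = {'True' if dt.byteorder == '>' else 'False'}\n"
        "CompressedData = False\n"
        f"DimSize = {nx} {ny} {nz}\n"
        f"ElementSpacing = {sx!r} {sy!r} {sz!r}\n"
        f"ElementType = {_DTYPE_TO_MET[dt]}\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(data).tobytes())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sniff_format(path: Path, format_hint: Optional[str]) -> str:
    if format_hint is not None:
        return format_hint
    if path.is_dir():
        return "dicom_series"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "metaimage"
    raise ValueError(f"cannot infer volume format of {path}; pass format_hint")


def read_volume(path: os.PathLike | str, format_hint: Optional[str] = None) -> CTVolume:
    """Read a 3D attenuation volume from NIfTI or MetaImage.

    Non-finite voxels (padding outside the reconstructed field of view) are
    replaced by the minimum representable HU (−1024) and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume path does not exist: {path}")
    fmt = _sniff_format(path, format_hint)
    if fmt == "dicom_series":
        raise ValueError(
            f"{path}: DICOM series reading is not available in this build "
            "(requires pydicom, which is not installed); convert to NIfTI or MetaImage"
        )
    if fmt == "nifti":
        img = nib.load(str(path))
        # on disk: (x, y, z); in memory: (z, y, x)
        data = np.asanyarray(img.dataobj).T
        zooms = img.header.get_zooms()[:3]  # (x, y, z) in mm
        spacing = (zooms[2] * 1000.0, zooms[1] * 1000.0, zooms[0] * 1000.0)
    elif fmt == "metaimage":
        data, spacing = _read_metaimage(path)
    else:
        raise ValueError(f"unreadable format {fmt!r} for {path}")

    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.floating):
        bad = ~np.isfinite(data)
        if bad.any():
            logger.warning("%s: %d undefined voxels mapped to %g HU", path, bad.sum(), HU_MIN)
            data = np.where(bad, HU_MIN, data)
    return CTVolume(data=data, spacing=spacing, hu_calibrated=True, provenance=str(path))


def write_volume(volume: CTVolume, path: os.PathLike | str, format: Optional[str] = None) -> None:
    """Write a volume as NIfTI (``.nii``/``.nii.gz``) or MetaImage (``.mha``)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    fmt = format
    if fmt is None:
        name = path.name.lower()
        fmt = "nifti" if name.endswith((".nii", ".nii.gz")) else "metaimage"
    sz, sy, sx = volume.spacing
    if fmt == "nifti":
        # store (x, y, z) on disk, zooms in mm
        affine = np.diag([sx / 1000.0, sy / 1000.0, sz / 1000.0, 1.0])
        img = nib.Nifti1Image(np.ascontiguousarray(volume.data.T), affine)
        img.header.set_zooms((sx / 1000.0, sy / 1000.0, sz / 1000.0))
        img.header.set_xyzt_units("mm")
        nib.save(img, str(path))
    elif fmt == "metaimage":
        _write_metaimage(path, volume.data, volume.spacing)
    else:
        raise ValueError(f"unsupported write format {fmt!r}")


def write_mask(mask: VoxelMask, path: os.PathLike | str, format: Optional[str] = None) -> None:
    """Write a binary mask as a {0,1}-valued uint8 volume."""
    spacing = mask.grid.spacing if mask.grid is not None else (46.0, 46.0, 46.0)
    vol = CTVolume(mask.data.astype(np.uint8), spacing=spacing, hu_calibrated=False)
    write_volume(vol, path, format=format)


def read_mask(path: os.PathLike | str, grid: Optional[CTVolume] = None) -> VoxelMask:
    """Read a {0,1} volume back as a boolean mask, optionally bound to ``grid``."""
    vol = read_volume(path)
    return VoxelMask(vol.data != 0, grid=grid)


# ---------------------------------------------------------------------------
# HU calibration
# ---------------------------------------------------------------------------

def calibrate_to_hu(volume: CTVolume, standards: CalibrationStandards) -> CTVolume:
    """Affine two-point calibration of raw scanner values to Hounsfield Units.

    The map sends ``air_raw`` to ``air_hu`` (−1000 by default) and
    ``water_raw`` to ``water_hu`` (0).  If a bone standard is present its
    mapped HU is logged as a linearity diagnostic; it does not influence
    the fit.

    Returns a new, HU-calibrated :class:`CTVolume`.
    """
    if volume.hu_calibrated:
        raise ValueError("volume is already HU-calibrated")
    slope = (standards.water_hu - standards.air_hu) / (standards.water_raw - standards.air_raw)
    intercept = standards.air_hu - slope * standards.air_raw
    hu = slope * volume.data.astype(np.float64) + intercept
    if standards.bone_raw is not None:
        logger.info(
            "calibration linearity check: bone standard raw=%g maps to %.1f HU",
            standards.bone_raw, slope * standards.bone_raw + intercept,
        )
    return replace(volume, data=hu, hu_calibrated=True,
                   provenance=volume.provenance + " [HU-calibrated]")


def read_standards_csv(path: os.PathLike | str) -> CalibrationStandards:
    """Read calibration standards from a CSV with columns ``standard,mean_raw``."""
    import pandas as pd

    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"standard", "mean_raw"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'standard' and 'mean_raw'")
    vals = {str(k).strip().lower(): float(v) for k, v in zip(df["standard"], df["mean_raw"])}
    if "air" not in vals or "water" not in vals:
        raise ValueError(f"{path}: calibration CSV must contain 'air' and 'water' rows")
    return CalibrationStandards(air_raw=vals["air"], water_raw=vals["water"],
                                bone_raw=vals.get("bone"))
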