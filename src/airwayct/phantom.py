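"""Synthetic respiratory-gated mouse-thorax phantom with ground truth.

Emulates the imaging situation the densitometry pipeline is built for: an
isotropic 46 µm micro-CT volume of a mouse thorax containing a branching
air-filled airway tree (≈ −1000 HU) sheathed in bronchial wall tissue,
embedded in aerated parenchyma (≈ −550 HU), surrounded by soft tissue
(≈ 0 HU), with optional in-field air/water calibration cylinders and
additive Gaussian noise.  Every voxel's label is known, so the generator
also returns ground-truth masks and oracle attenuation values against
which the segmentation and shell pipeline can be validated exactly.

Two biological contrasts can be dialed in:

* **wall remodeling** — thicker bronchial walls (``wall_thickness_voxels``,
  or denser ``wall_hu``), attenuation concentrated at the airway;
* **inflammation** — a wide halo of raised parenchymal attenuation around
  the airways (``inflammation_halo``), emulating inflammatory infiltrates
  that extend well into the distal parenchyma rather than stopping at the
  bronchial wall.  Its default extent (48 voxels, 2.2 mm — pan-parenchymal
  at the default geometry) is deliberately much larger than the 8-voxel
  peribronchial shell: attenuation added lung-wide moves PBA and TLA
  together, which is exactly what TLA-normalization cancels.  A halo
  confined to the shell's neighbourhood would instead mimic remodeling.

The generated volume is clamped at −1024 HU, the minimum representable
value of the CT scale, as a real reconstruction would be; without the
clamp, additive noise would push air voxels below the lumen band's lower
bound, which no scanner output does.

Ground-truth expectations are computed from the truth masks with a
brute-force shifted-mask dilation (independent of the distance-transform
dilation used by the pipeline under test).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, VoxelMask, HU_MIN
from .segmentation import SeedPoint, LUMEN_BAND

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "remodeling_series",
    "inflammation_series",
    "brute_force_dilate",
]

# label codes of the painted volume
_BODY, _PARENCHYMA, _WALL, _LUMEN, _AIR_STD, _WATER_STD = 0, 1, 2, 3, 4, 5


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of the synthetic thorax.

    Defaults describe the stated imaging world: 46 µm isotropic voxels, a
    4-generation dichotomous airway tree, air lumen at −1000 HU, wall at
    −200 HU, aerated parenchyma at −550 HU (mid lung band), soft tissue at
    0 HU, and 20 HU Gaussian noise.
    """

    grid_shape: tuple[int, int, int] = (192, 192, 192)
    spacing_um: float = 46.0
    tree_depth: int = 4
    root_radius_voxels: float = 5.0
    radius_decay: float = 0.75
    wall_thickness_voxels: float = 2.0
    lumen_hu: float = -1000.0
    wall_hu: float = -200.0
    parenchyma_hu: float = -550.0
    body_hu: float = 0.0
    #: optional (extent_voxels, delta_hu): raise parenchymal attenuation by
    #: delta_hu within extent_voxels of the airway wall's outer surface.
    inflammation_halo: Optional[tuple[float, float]] = None
    noise_sd_hu: float = 20.0
    rng_seed: int = 0
    include_standards: bool = True
    branch_angle_deg: float = 32.0
    branch_length_voxels: float = 0.0  # 0 -> scaled from grid
    length_decay: float = 0.78

    def __post_init__(self) -> None:
        if not (self.lumen_hu < self.parenchyma_hu < self.body_hu):
            raise ValueError("phantom requires lumen_hu < parenchyma_hu < body_hu")
        if self.wall_thickness_voxels < 1:
            raise ValueError("wall_thickness_voxels must be >= 1")
        if self.root_radius_voxels < 1:
            raise ValueError("root_radius_voxels must be >= 1")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")
        if self.tree_depth < 1:
            raise ValueError("tree_depth must be >= 1")


@dataclass
class PhantomTruth:
    """Ground-truth masks, oracle attenuations and suggested seeds."""

    lumen_mask: VoxelMask
    wall_mask: VoxelMask
    parenchyma_mask: VoxelMask
    body_mask: VoxelMask
    air_standard_mask: VoxelMask
    water_standard_mask: VoxelMask
    trachea_exclusion_mask: VoxelMask
    halo_mask: VoxelMask
    expected_tla_hu: float
    expected_pba_hu: float
    expected_normalized_pba: float
    lumen_seed: SeedPoint
    lung_seed: SeedPoint
    spec: PhantomSpec = field(repr=False)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of vector v around unit axis by angle (radians)."""
    axis = axis / np.linalg.norm(axis)
    return (v * np.cos(angle)
            + np.cross(axis, v) * np.sin(angle)
            + axis * np.dot(axis, v) * (1 - np.cos(angle)))


def _tree_segments(spec: PhantomSpec, rng: np.random.Generator
                   ) -> list[tuple[np.ndarray, np.ndarray, float, int]]:
    """Build the airway tree as a list of (p0, p1, lumen_radius, generation).

    Generation 0 is the straight trachea along +z; each subsequent
    generation splits dichotomously at ``branch_angle_deg`` in a plane that
    alternates per generation, with a small deterministic jitter rotation
    around the parent axis.
    """
    nz, ny, nx = spec.grid_shape
    n = min(spec.grid_shape)
    seg_len = spec.branch_length_voxels or 0.21 * n
    theta = np.deg2rad(spec.branch_angle_deg)

    cy, cx = ny / 2.0, nx / 2.0
    z_top = 0.03 * nz
    z_carina = 0.30 * nz
    segments: list[tuple[np.ndarray, np.ndarray, float, int]] = []
    trachea = (np.array([z_top, cy, cx]), np.array([z_carina, cy, cx]),
               float(spec.root_radius_voxels), 0)
    segments.append(trachea)

    def recurse(p0: np.ndarray, direction: np.ndarray, gen: int) -> None:
        if gen > spec.tree_depth:
            return
        radius = spec.root_radius_voxels * spec.radius_decay ** gen
        length = seg_len * spec.length_decay ** (gen - 1)
        # branching plane alternates; jitter keeps children off exact lattice planes
        plane_axis = np.array([0.0, 1.0, 0.0]) if gen % 2 == 1 else np.array([0.0, 0.0, 1.0])
        # make the rotation axis perpendicular to the parent direction
        axis = plane_axis - np.dot(plane_axis, direction) * direction
        if np.linalg.norm(axis) < 1e-9:
            axis = np.array([0.0, 1.0, 0.0])
        jitter = rng.uniform(-np.deg2rad(12), np.deg2rad(12))
        for sign in (+1.0, -1.0):
            d = _rotate(direction, axis, sign * theta)
            d = _rotate(d, direction, jitter)
            d = d / np.linalg.norm(d)
            p1 = p0 + d * length
            segments.append((p0.copy(), p1, float(radius), gen))
            recurse(p1, d, gen + 1)

    recurse(np.array([z_carina, cy, cx]), np.array([1.0, 0.0, 0.0]), 1)
    return segments


def _paint_segment(labels: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                   radius: float, code: int, over: tuple[int, ...]) -> None:
    """Set label ``code`` on voxels within ``radius`` of segment p0-p1,
    but only where the current label is in ``over``."""
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius + 2).astype(int),
                    np.array(labels.shape))
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(*(np.arange(a, b) for a, b in zip(lo, hi)),
                             indexing="ij", sparse=False)
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    v = p1 - p0
    vv = float(np.dot(v, v))
    t = np.clip(np.tensordot(pts - p0, v, axes=([-1], [0])) / vv, 0.0, 1.0)
    closest = p0 + t[..., None] * v
    dist2 = ((pts - closest) ** 2).sum(axis=-1)
    inside = dist2 <= radius * radius
    sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[inside & np.isin(sub, over)] = code


def brute_force_dilate(mask: np.ndarray, radius: float) -> np.ndarray:
    """Dilation by Euclidean distance ≤ radius, via OR of shifted masks.

    Enumerates every integer offset inside the ball of the given radius and
    ORs the correspondingly shifted mask.  Slower than a distance
    transform but entirely independent of it; used to build ground-truth
    expectations.
    """
    r = int(np.floor(radius))
    out = np.zeros_like(mask, dtype=bool)
    shape = mask.shape
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if dz * dz + dy * dy + dx * dx > radius * radius:
                    continue
                src = [slice(max(0, -d), min(s, s - d)) for d, s in zip((dz, dy, dx), shape)]
                dst = [slice(max(0, d), min(s, s + d)) for d, s in zip((dz, dy, dx), shape)]
                out[tuple(dst)] |= mask[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec = PhantomSpec(),
                     shell_radius_voxels: float = 8.0) -> tuple[CTVolume, PhantomTruth]:
    """Generate a synthetic thorax volume and its ground truth.

    Deterministic given ``spec.rng_seed``.  ``shell_radius_voxels`` is the
    dilation radius the truth oracle uses when computing the expected
    peribronchial attenuation (it must match the radius the pipeline will
    be run with; default 8).

    Raises
    ------
    ValueError
        If the airway tree does not fit the grid (reduce ``tree_depth``,
        ``root_radius_voxels`` or branch lengths).
    """
    rng = np.random.default_rng(spec.rng_seed)
    nz, ny, nx = spec.grid_shape
    segments = _tree_segments(spec, rng)

    # fit check: bronchi must lie fully inside the grid with their wall;
    # the trachea's cranial end may leave the field of view, as in a real
    # scan, so only its lateral extent is checked
    margin = spec.wall_thickness_voxels + 1
    bounds = np.array(spec.grid_shape)
    for p0, p1, radius, gen in segments:
        for p in (p0, p1):
            lo_ok = p - radius - margin >= 0
            hi_ok = p + radius + margin < bounds
            if gen == 0:
                lo_ok[0] = hi_ok[0] = True  # trachea may touch the cranial face
            if not (lo_ok.all() and hi_ok.all()):
                raise ValueError(
                    "airway tree does not fit the grid: reduce tree_depth, "
                    "root_radius_voxels or branch length"
                )

    labels = np.full(spec.grid_shape, _BODY, dtype=np.uint8)

    # lung parenchyma: ellipsoid in the caudal two thirds of the grid
    cz, cy, cx = 0.58 * nz, ny / 2.0, nx / 2.0
    az, ay, ax_ = 0.36 * nz, 0.40 * ny, 0.40 * nx
    zz = ((np.arange(nz) - cz) / az) ** 2
    yy = ((np.arange(ny) - cy) / ay) ** 2
    xx = ((np.arange(nx) - cx) / ax_) ** 2
    ellipsoid = zz[:, None, None] + yy[None, :, None] + xx[None, None, :] <= 1.0
    labels[ellipsoid] = _PARENCHYMA

    # bronchial walls first, lumina on top (lumen overrides sibling walls)
    for p0, p1, radius, _gen in segments:
        _paint_segment(labels, p0, p1, radius + spec.wall_thickness_voxels,
                       _WALL, over=(_BODY, _PARENCHYMA))
    for p0, p1, radius, _gen in segments:
        _paint_segment(labels, p0, p1, radius, _LUMEN,
                       over=(_BODY, _PARENCHYMA, _WALL))

    # calibration standards: axial cylinders in the soft-tissue corner regions
    if spec.include_standards:
        z0, z1 = np.array([0.72 * nz, ny * 0.125, nx * 0.125]), \
                 np.array([0.93 * nz, ny * 0.125, nx * 0.125])
        _paint_segment(labels, z0, z1, 0.04 * min(ny, nx), _AIR_STD, over=(_BODY,))
        w0, w1 = np.array([0.72 * nz, ny * 0.125, nx * 0.875]), \
                 np.array([0.93 * nz, ny * 0.125, nx * 0.875])
        _paint_segment(labels, w0, w1, 0.04 * min(ny, nx), _WATER_STD, over=(_BODY,))

    # inflammation halo: raised parenchymal attenuation near the airways
    halo = np.zeros(spec.grid_shape, dtype=bool)
    if spec.inflammation_halo is not None:
        extent, delta = spec.inflammation_halo
        airway = (labels == _LUMEN) | (labels == _WALL)
        near = ndimage.distance_transform_edt(~airway) <= extent
        halo = near & (labels == _PARENCHYMA)

    hu_map = {
        _BODY: spec.body_hu, _PARENCHYMA: spec.parenchyma_hu,
        _WALL: spec.wall_hu, _LUMEN: spec.lumen_hu,
        _AIR_STD: -1000.0, _WATER_STD: 0.0,
    }
    clean = np.empty(spec.grid_shape, dtype=np.float64)
    for code, hu in hu_map.items():
        clean[labels == code] = hu
    if spec.inflammation_halo is not None:
        clean[halo] += spec.inflammation_halo[1]

    data = clean.copy()
    if spec.noise_sd_hu > 0:
        data = data + rng.normal(0.0, spec.noise_sd_hu, size=spec.grid_shape)
        np.maximum(data, HU_MIN, out=data)  # CT scale floors at -1024

    spacing = (spec.spacing_um,) * 3
    volume = CTVolume(data=data, spacing=spacing, hu_calibrated=True,
                      provenance=f"synthetic thorax phantom (seed={spec.rng_seed})")

    truth = _build_truth(spec, volume, labels, clean, halo, segments,
                         shell_radius_voxels)
    return volume, truth


def _build_truth(spec: PhantomSpec, volume: CTVolume, labels: np.ndarray,
                 clean: np.ndarray, halo: np.ndarray,
                 segments: list, shell_radius_voxels: float) -> PhantomTruth:
    g = volume
    lumen = labels == _LUMEN
    wall = labels == _WALL
    parenchyma = labels == _PARENCHYMA
    body = labels == _BODY
    air_std = labels == _AIR_STD
    water_std = labels == _WATER_STD

    # trachea/mediastinum exclusion: every slice down to (and including) the carina
    z_carina = int(round(0.30 * spec.grid_shape[0]))
    exclusion = np.zeros(spec.grid_shape, dtype=bool)
    exclusion[: z_carina + 1] = True

    # oracle TLA: the in-band tissue is parenchyma (+halo) and wall, one
    # connected region by construction -> plain mean over the truth masks
    lung_truth = parenchyma | wall
    expected_tla = float(clean[lung_truth].mean())

    # oracle PBA: brute-force dilation of the truth lumen, minus all
    # lumen-band voxels of the clean volume, minus the exclusion
    dilated = brute_force_dilate(lumen, shell_radius_voxels)
    in_lumen_band = LUMEN_BAND.contains(clean)
    shell_truth = dilated & ~in_lumen_band & ~exclusion
    expected_pba = float(clean[shell_truth].mean())

    # suggested seeds: trachea axis, and the lateral-most parenchyma voxel
    # on the ellipsoid's central slice (far from the airways)
    nz, ny, nx = spec.grid_shape
    lumen_seed = SeedPoint((int(0.05 * nz) + 1, ny // 2, nx // 2))
    if not lumen[lumen_seed.index]:
        zs = np.argwhere(lumen)
        lumen_seed = SeedPoint(tuple(zs[np.argmin(zs[:, 0])]))
    cz = int(round(0.58 * nz))
    row = np.argwhere(parenchyma[cz] & ~halo[cz])
    if row.size == 0:
        row = np.argwhere(parenchyma[cz])
    sel = row[np.argmax(row[:, 0])]
    lung_seed = SeedPoint((cz, int(sel[0]), int(sel[1])))

    return PhantomTruth(
        lumen_mask=VoxelMask(lumen, grid=g),
        wall_mask=VoxelMask(wall, grid=g),
        parenchyma_mask=VoxelMask(parenchyma, grid=g),
        body_mask=VoxelMask(body, grid=g),
        air_standard_mask=VoxelMask(air_std, grid=g),
        water_standard_mask=VoxelMask(water_std, grid=g),
        trachea_exclusion_mask=VoxelMask(exclusion, grid=g),
        halo_mask=VoxelMask(halo, grid=g),
        expected_tla_hu=expected_tla,
        expected_pba_hu=expected_pba,
        expected_normalized_pba=1.0 - expected_pba / expected_tla,
        lumen_seed=lumen_seed,
        lung_seed=lung_seed,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# contrast series
# ---------------------------------------------------------------------------

def remodeling_series(
    spec: PhantomSpec, wall_thickness_list: Sequence[float],
    shell_radius_voxels: float = 8.0,
) -> list[tuple[CTVolume, PhantomTruth]]:
    """Phantoms identical except for bronchial wall thickness.

    Emulates progressive airway remodeling (smooth-muscle/wall mass
    accumulating at the airway) with fixed tree geometry, noise seed and
    parenchyma: only ``wall_thickness_voxels`` varies.
    """
    if any(t < 1 for t in wall_thickness_list):
        raise ValueError("wall thicknesses must be >= 1 voxel")
    return [
        generate_phantom(replace(spec, wall_thickness_voxels=float(t)),
                         shell_radius_voxels=shell_radius_voxels)
        for t in wall_thickness_list
    ]


def inflammation_series(
    spec: PhantomSpec, delta_hu_list: Sequence[float],
    extent_voxels: float = 48.0,
    shell_radius_voxels: float = 8.0,
) -> list[tuple[CTVolume, PhantomTruth]]:
    """Phantoms identical except for the inflammation halo intensity.

    Walls are fixed; a wide halo (default extent 48 voxels, reaching from
    the airways to the pleura at the default geometry, i.e. diffuse
    alveolitis) raises parenchymal attenuation by each ``delta_hu``.
    ``delta_hu = 0`` means no halo.
    """
    out = []
    for d in delta_hu_list:
        halo = None if d == 0 else (float(extent_voxels), float(d))
        out.append(generate_phantom(replace(spec, inflammation_halo=halo),
                                    shell_radius_voxels=shell_radius_voxels))
    return out
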