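"""Shared fixtures: a small synthetic thorax and independent oracles."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from airwayct import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A 96³, 3-generation thorax with 20 HU noise (shared, read-only)."""
    spec = PhantomSpec(grid_shape=(96, 96, 96), tree_depth=3, noise_sd_hu=20.0,
                       rng_seed=1)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def quiet_phantom():
    """Noise-free variant of the small thorax (shared, read-only)."""
    spec = PhantomSpec(grid_shape=(96, 96, 96), tree_depth=3, noise_sd_hu=0.0,
                       rng_seed=1)
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


# ---------------------------------------------------------------------------
# independent oracles (shared between unit and acceptance tests)
# ---------------------------------------------------------------------------

def flood_fill_oracle(data: np.ndarray, seeds, lo: float, hi: float,
                      connectivity: str = "face6") -> np.ndarray:
    """Breadth-first flood fill over in-band voxels; independent of
    scipy.ndimage labeling."""
    if connectivity == "face6":
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                   for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    in_band = (data >= lo) & (data <= hi)
    out = np.zeros_like(in_band)
    queue = deque()
    for s in seeds:
        s = tuple(int(i) for i in s)
        if in_band[s] and not out[s]:
            out[s] = True
            queue.append(s)
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            p = (z + dz, y + dy, x + dx)
            if all(0 <= c < n for c, n in zip(p, data.shape)):
                if in_band[p] and not out[p]:
                    out[p] = True
                    queue.append(p)
    return out


def brute_distance_dilate_oracle(mask: np.ndarray, radius: float) -> np.ndarray:
    """All-pairs Euclidean distance thresholding (for small grids only)."""
    true_pts = np.argwhere(mask)
    grid = np.indices(mask.shape).reshape(3, -1).T
    d2 = ((grid[:, None, :] - true_pts[None, :, :]) ** 2).sum(axis=2)
    return (d2.min(axis=1) <= radius * radius).reshape(mask.shape)
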