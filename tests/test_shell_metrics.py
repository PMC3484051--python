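"""Dilation, peribronchial shell and attenuation statistics."""

import numpy as np
import pytest

from airwayct import (CTVolume, ShellParams, VoxelMask, dilate_mask,
                      mean_attenuation, normalize_image, normalized_pba,
                      peribronchial_shell, summarize, PhantomSpec,
                      generate_phantom, segment_lumen, segment_lung)
from conftest import brute_distance_dilate_oracle


def _mask(data, grid=None):
    return VoxelMask(np.asarray(data, dtype=bool), grid=grid)


class TestDilate:
    def test_unit_ball_is_seven_voxels(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        out = dilate_mask(_mask(m), 1.0)
        assert out.voxel_count == 7
        assert out.data[2, 2, 2] and out.data[1, 2, 2] and out.data[2, 3, 2]

    @pytest.mark.parametrize("trial", range(6))
    def test_matches_brute_force_distance_oracle(self, rng, trial):
        shape = tuple(rng.integers(6, 17, size=3))
        m = rng.random(shape) > 0.97
        if not m.any():
            m[tuple(rng.integers(0, s) for s in shape)] = True
        radius = float(rng.uniform(1.0, 5.0))
        got = dilate_mask(_mask(m), radius).data
        np.testing.assert_array_equal(got, brute_distance_dilate_oracle(m, radius))

    def test_radius_monotonicity_and_superset(self, rng):
        m = rng.random((12, 12, 12)) > 0.98
        m[5, 5, 5] = True
        d2 = dilate_mask(_mask(m), 2.0).data
        d4 = dilate_mask(_mask(m), 4.0).data
        assert not np.any(m & ~d2)
        assert not np.any(d2 & ~d4)

    def test_iterated_face_mode(self):
        m = np.zeros((7, 7, 7), dtype=bool)
        m[3, 3, 3] = True
        out = dilate_mask(_mask(m), 2.0, mode="iterated_face")
        # 2 iterations of the face element: L1 ball of radius 2 (25 voxels)
        zz, yy, xx = np.indices(m.shape)
        l1 = np.abs(zz - 3) + np.abs(yy - 3) + np.abs(xx - 3) <= 2
        np.testing.assert_array_equal(out.data, l1)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dilate_mask(_mask(np.zeros((3, 3, 3))), 2.0)

    def test_anisotropic_grid_rejected(self):
        grid = CTVolume(np.zeros((4, 4, 4)), spacing=(92.0, 46.0, 46.0))
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1, 1, 1] = True
        with pytest.raises(ValueError, match="isotropic"):
            dilate_mask(_mask(m, grid=grid), 1.0)


def _tube_volume(shape=(24, 33, 33), lumen_r=3, wall_t=2,
                 wall_hu=-200.0, parenchyma_hu=-550.0):
    zz, yy, xx = np.indices(shape)
    cy, cx = shape[1] // 2, shape[2] // 2
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    data = np.full(shape, parenchyma_hu)
    data[r2 <= (lumen_r + wall_t) ** 2] = wall_hu
    lumen = r2 <= lumen_r ** 2
    data[lumen] = -1000.0
    return CTVolume(data), lumen


class TestShell:
    def test_straight_tube_matches_geometric_oracle(self):
        """Shell = voxels within Euclidean distance 8 of the lumen,
        excluding all lumen-band air."""
        vol, lumen = _tube_volume()
        shell = peribronchial_shell(vol, _mask(lumen, grid=vol),
                                    ShellParams(dilation_radius_voxels=8.0))
        dilated = brute_distance_dilate_oracle(lumen, 8.0)
        want = dilated & (vol.data > -900.0)
        np.testing.assert_array_equal(shell.data, want)
        # disjoint from every lumen-band voxel
        assert not np.any(shell.data & (vol.data <= -900.0))

    def test_whole_volume_lumen_leaves_no_shell(self):
        vol = CTVolume(np.full((6, 6, 6), -1000.0))
        with pytest.raises(ValueError, match="empty peribronchial shell"):
            peribronchial_shell(vol, _mask(np.ones((6, 6, 6)), grid=vol))

    def test_exclusion_mask_subtracted(self):
        vol, lumen = _tube_volume()
        excl = np.zeros(vol.shape, dtype=bool)
        excl[:8] = True
        shell = peribronchial_shell(vol, _mask(lumen, grid=vol),
                                    exclusion=_mask(excl, grid=vol))
        assert not np.any(shell.data & excl)

    def test_empty_lumen_rejected(self):
        vol, _ = _tube_volume()
        with pytest.raises(ValueError, match="empty"):
            peribronchial_shell(vol, _mask(np.zeros(vol.shape), grid=vol))

    def test_shell_within_dilated_lumen(self):
        vol, lumen = _tube_volume()
        r = 5.0
        shell = peribronchial_shell(vol, _mask(lumen, grid=vol),
                                    ShellParams(dilation_radius_voxels=r))
        dilated = dilate_mask(_mask(lumen, grid=vol), r)
        assert not np.any(shell.data & ~dilated.data)

    def test_pure_wall_shell_recovers_wall_hu_exactly(self):
        """When the shell contains only wall voxels at a single HU value,
        PBA equals that value exactly."""
        vol, lumen = _tube_volume(lumen_r=3, wall_t=9, wall_hu=-300.0)
        shell = peribronchial_shell(vol, _mask(lumen, grid=vol),
                                    ShellParams(dilation_radius_voxels=8.0))
        assert mean_attenuation(vol, shell) == -300.0


class TestStatistics:
    def test_mean_attenuation_basics(self):
        vol = CTVolume(np.full((4, 4, 4), -400.0))
        assert mean_attenuation(vol, _mask(np.ones((4, 4, 4)))) == -400.0
        two = CTVolume(np.array([[[-1000.0, 0.0]]]))
        assert mean_attenuation(two, _mask(np.ones((1, 1, 2)))) == -500.0

    def test_mean_attenuation_matches_summation_oracle(self, rng):
        data = rng.uniform(-1024, 300, size=(10, 10, 10))
        m = rng.random((10, 10, 10)) > 0.5
        got = mean_attenuation(CTVolume(data), _mask(m))
        want = data[m].sum() / m.sum()
        assert got == pytest.approx(want, rel=1e-9)

    def test_mean_attenuation_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_attenuation(CTVolume(np.zeros((2, 2, 2))), _mask(np.zeros((2, 2, 2))))

    def test_normalized_pba_formula(self):
        assert normalized_pba(-420.0, -500.0) == pytest.approx(0.16, abs=1e-12)
        assert normalized_pba(-500.0, -500.0) == 0.0
        with pytest.raises(ZeroDivisionError):
            normalized_pba(-420.0, 0.0)

    def test_normalize_image_fixed_points(self):
        vol = CTVolume(np.array([[[-500.0, 0.0, -250.0]]]))
        out = normalize_image(vol, -500.0)
        assert not out.hu_calibrated
        np.testing.assert_allclose(out.data[0, 0], [0.0, 1.0, 0.5], atol=1e-12)
        with pytest.raises(ZeroDivisionError):
            normalize_image(vol, 0.0)

    def test_normalization_identity_on_shell_mean(self, small_phantom):
        """Mean of the normalized image over the shell equals
        1 − PBA/TLA computed from the raw attenuations."""
        vol, truth = small_phantom
        lumen = segment_lumen(vol, [truth.lumen_seed])
        lung = segment_lung(vol, [truth.lung_seed])
        shell = peribronchial_shell(vol, lumen, exclusion=truth.trachea_exclusion_mask)
        s = summarize(vol, lung, shell)
        norm = normalize_image(vol, s.tla_hu)
        assert mean_attenuation(norm, shell) == pytest.approx(s.normalized_pba, rel=1e-9)

    def test_summarize_consistency_and_degenerate_cases(self, small_phantom):
        vol, truth = small_phantom
        lung = truth.parenchyma_mask | truth.wall_mask
        s = summarize(vol, lung, lung)
        assert s.normalized_pba == 0.0  # pba == tla on identical masks
        assert s.lung_voxels == s.shell_voxels == lung.voxel_count
        with pytest.raises(ValueError):
            summarize(vol, lung, _mask(np.zeros(vol.shape)))


def test_pba_monotone_in_wall_attenuation():
    """Fixed geometry, fixed TLA support: denser walls give strictly higher
    PBA and strictly higher normalized PBA."""
    pbas, npbas = [], []
    for wall_hu in (-300.0, -250.0, -200.0):
        spec = PhantomSpec(grid_shape=(80, 80, 80), tree_depth=2,
                           noise_sd_hu=0.0, rng_seed=7, wall_hu=wall_hu)
        vol, truth = generate_phantom(spec)
        lumen = segment_lumen(vol, [truth.lumen_seed])
        lung = segment_lung(vol, [truth.lung_seed])
        shell = peribronchial_shell(vol, lumen, exclusion=truth.trachea_exclusion_mask)
        s = summarize(vol, lung, shell)
        pbas.append(s.pba_hu)
        npbas.append(s.normalized_pba)
    assert pbas[0] < pbas[1] < pbas[2]
    assert npbas[0] < npbas[1] < npbas[2]
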