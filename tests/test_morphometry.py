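"""Grid geometry, BV/TV sampling, MIL fabric and sphere-fitting thickness."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from trabmorph import VoxelVolume, build_grid, local_thickness_map, \
    make_phantom, mil_fabric, region_thickness, sample_bvtv, sample_grid
from trabmorph.morphometry import fibonacci_hemisphere, mil_directional, \
    _orthobasis
from trabmorph.synthetic import PhantomSpec
from conftest import full_mask


def brute_force_mil(bone, mask, center, radius, directions,
                    line_spacing=1.0, step=1.0):
    """Independent per-direction crossing counter: explicit Python loops
    over lines and samples, same sampling definition as the package
    (parallel line families, nearest-voxel lookup, sphere and mask
    restriction)."""
    nz, ny, nx = bone.shape
    n_off = int(math.floor(2.0 * radius / line_spacing)) + 1
    offs = [(i - (n_off - 1) / 2.0) * line_spacing for i in range(n_off)]
    n_t = int(math.floor(2.0 * radius / step)) + 1
    ts = [(i - (n_t - 1) / 2.0) * step for i in range(n_t)]
    crossings, lengths = [], []
    for w in directions:
        u, v = _orthobasis(w)
        n_cross = 0
        n_pair = 0
        for a in offs:
            for b in offs:
                if a * a + b * b > radius * radius:
                    continue
                prev_valid = False
                prev_bone = False
                for t in ts:
                    if a * a + b * b + t * t > radius * radius:
                        valid = False
                    else:
                        p = center + a * u + b * v + t * w
                        i0, i1, i2 = (int(np.rint(p[0])), int(np.rint(p[1])),
                                      int(np.rint(p[2])))
                        inb = (0 <= i0 < nz and 0 <= i1 < ny and 0 <= i2 < nx)
                        valid = inb and bool(mask[i0, i1, i2])
                    this_bone = valid and bool(bone[i0, i1, i2])
                    if valid and prev_valid:
                        n_pair += 1
                        if this_bone and not prev_bone:
                            n_cross += 1
                    prev_valid, prev_bone = valid, this_bone
        crossings.append(n_cross)
        lengths.append(n_pair * step)
    return np.array(crossings), np.array(lengths)


class TestBackgroundGrid:
    def test_cube_lattice_exact_spacing(self, solid_cube_mask):
        grid = build_grid(solid_cube_mask, spacing=2.5, voi_diameter=5.0)
        # 10 mm cube: 5 nodes per axis before edge filtering
        assert len(grid.nodes) == 125
        d, _ = cKDTree(grid.nodes).query(grid.nodes, k=2)
        assert np.all(d[:, 1] == 2.5)

    def test_spacing_larger_than_mask(self):
        mask = VoxelVolume(np.ones((20, 20, 20), np.uint8), 0.1)
        grid = build_grid(mask, spacing=50.0, voi_diameter=2.0)
        assert len(grid.nodes) == 1

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            build_grid(VoxelVolume(np.zeros((10, 10, 10), np.uint8), 0.1))

    def test_node_set_matches_brute_force_enumeration(self, adult_specimen):
        from trabmorph import binarize, separate_cortex
        from trabmorph.morphometry import _sphere_bool

        binary = binarize(adult_specimen.volume, window=40)
        inner = separate_cortex(binary).inner_mask
        sub = VoxelVolume(inner.data[:60], inner.voxel_size)
        grid = build_grid(sub, spacing=1.0, voi_diameter=2.0)
        # independent enumeration: full lattice, padded-array convolution
        mask = sub.as_bool()
        vs = sub.voxel_size
        idx = np.nonzero(mask)
        lo = np.array([a.min() for a in idx]) * vs
        hi = np.array([a.max() for a in idx]) * vs
        ball = _sphere_bool(1.0 / vs)
        r = ball.shape[0] // 2
        padded = np.pad(mask, r)
        expected = []
        for z in np.arange(lo[0], hi[0] + 1e-9, 1.0):
            for y in np.arange(lo[1], hi[1] + 1e-9, 1.0):
                for x in np.arange(lo[2], hi[2] + 1e-9, 1.0):
                    c = np.rint(np.array([z, y, x]) / vs).astype(int)
                    region = padded[c[0]:c[0] + 2 * r + 1,
                                    c[1]:c[1] + 2 * r + 1,
                                    c[2]:c[2] + 2 * r + 1]
                    if (region & ball).sum() >= 0.1 * ball.sum():
                        expected.append([z, y, x])
        assert len(grid.nodes) == len(expected)
        assert np.allclose(np.sort(grid.nodes, axis=0),
                           np.sort(np.array(expected), axis=0))


class TestSampleBvtv:
    def test_all_bone_sphere(self):
        vol = VoxelVolume(np.ones((40, 40, 40), np.uint8), 0.1)
        bv = sample_bvtv(vol, full_mask(vol), np.array([2.0, 2.0, 2.0]),
                         voi_diameter=2.0)
        assert bv == 1.0

    def test_empty_sphere(self):
        vol = VoxelVolume(np.zeros((40, 40, 40), np.uint8), 0.1)
        bv = sample_bvtv(vol, full_mask(vol), np.array([2.0, 2.0, 2.0]),
                         voi_diameter=2.0)
        assert bv == 0.0

    def test_no_mask_flags_invalid(self):
        vol = VoxelVolume(np.ones((40, 40, 40), np.uint8), 0.1)
        mask = vol.like(np.zeros(vol.shape, np.uint8))
        assert math.isnan(sample_bvtv(vol, mask, np.array([2.0, 2.0, 2.0]),
                                      voi_diameter=2.0))

    def test_plate_interior_node(self, plate_phantom):
        # standard 5 mm VOI: spans three plate periods, so the sphere's
        # area weighting of individual slabs averages out
        _, vol, truth = plate_phantom
        node = np.array([60, 60, 60]) * vol.voxel_size
        bv = sample_bvtv(vol, full_mask(vol), node, voi_diameter=5.0)
        assert bv == pytest.approx(truth.bvtv, abs=0.02)

    def test_voxel_size_metadata_invariance(self, plate_phantom):
        _, vol, _ = plate_phantom
        doubled = VoxelVolume(vol.data, vol.voxel_size * 2)
        node = np.array([60, 60, 60])
        b1 = sample_bvtv(vol, full_mask(vol), node * vol.voxel_size, 2.0)
        b2 = sample_bvtv(doubled, full_mask(doubled),
                         node * doubled.voxel_size, 4.0)
        assert b1 == b2


class TestMILFabric:
    def test_oracle_equivalence_exact(self):
        """Vectorised crossing counts equal the brute-force loop counter
        exactly on small random volumes."""
        rng = np.random.default_rng(5)
        bone = rng.random((32, 32, 32)) < 0.3
        mask = np.ones_like(bone)
        dirs = fibonacci_hemisphere(8)
        center = np.array([16.0, 16.0, 16.0])
        cr_fast = mil_directional(bone, mask, center, 12.0, dirs)[1]
        cr_slow, len_slow = brute_force_mil(bone, mask, center, 12.0, dirs)
        assert np.array_equal(cr_fast, cr_slow)
        len_fast = mil_directional(bone, mask, center, 12.0, dirs)[2]
        assert np.allclose(len_fast, len_slow)

    def test_oracle_equivalence_with_mask(self, foam_phantom):
        _, vol, _ = foam_phantom
        bone = vol.as_bool()
        rng = np.random.default_rng(1)
        mask = rng.random(bone.shape) < 0.9
        dirs = fibonacci_hemisphere(5)
        center = np.array([32.0, 32.0, 32.0])
        cr_fast = mil_directional(bone, mask, center, 20.0, dirs)[1]
        cr_slow, _ = brute_force_mil(bone, mask, center, 20.0, dirs)
        assert np.array_equal(cr_fast, cr_slow)

    def test_plate_fabric(self, plate_phantom):
        _, vol, truth = plate_phantom
        node = np.array([60, 60, 60]) * vol.voxel_size
        fr = mil_fabric(vol, full_mask(vol), node, voi_diameter=2.5)
        assert fr.valid
        assert fr.da >= 0.8
        # the minor MIL axis aligns with the plate normal (axis 0)
        minor = fr.eigenvectors[:, 2]
        angle = math.degrees(math.acos(abs(float(minor @ truth.principal_axis))))
        assert angle < 5.0

    def test_foam_isotropic(self):
        das = []
        for seed in range(1, 6):
            spec = PhantomSpec(kind="sphere_foam", voxel_size=0.05,
                               dims=(64, 64, 64), target_bvtv=0.3, seed=seed)
            vol, _ = make_phantom(spec)
            node = np.array([32, 32, 32]) * 0.05
            fr = mil_fabric(vol, full_mask(vol), node, voi_diameter=2.5)
            assert fr.valid and 0.0 <= fr.da <= 1.0
            das.append(fr.da)
        assert np.mean(das) <= 0.15

    def test_rotation_invariance(self, foam_phantom):
        _, vol, _ = foam_phantom
        rot = VoxelVolume(np.rot90(vol.data, axes=(0, 1)).copy(),
                          vol.voxel_size)
        node = np.array([32, 32, 32]) * 0.05
        f1 = mil_fabric(vol, full_mask(vol), node, voi_diameter=2.5)
        f2 = mil_fabric(rot, full_mask(rot), node, voi_diameter=2.5)
        assert abs(f1.da - f2.da) <= 0.02

    def test_single_phase_flagged_invalid(self):
        vol = VoxelVolume(np.ones((48, 48, 48), np.uint8), 0.1)
        fr = mil_fabric(vol, full_mask(vol), np.array([2.4, 2.4, 2.4]),
                        voi_diameter=2.0)
        assert not fr.valid and "crossings" in fr.diagnostic

    def test_da_bounds_on_random_volumes(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            fill = rng.uniform(0.15, 0.6)
            bone = (rng.random((40, 40, 40)) < fill).astype(np.uint8)
            vol = VoxelVolume(bone, 0.1)
            fr = mil_fabric(vol, full_mask(vol), np.array([2.0, 2.0, 2.0]),
                            voi_diameter=2.5, n_directions=64)
            if fr.valid:
                assert 0.0 <= fr.da <= 1.0


class TestLocalThickness:
    def test_slab(self):
        phase = np.zeros((40, 30, 30), np.uint8)
        phase[10:20] = 1  # 10-voxel slab, periodic continuation via wrap pad
        lt = local_thickness_map(VoxelVolume(phase, 0.1))
        inside = phase.astype(bool)
        assert np.allclose(lt.data[inside], 1.0, atol=0.05)

    def test_single_ball(self):
        Z, Y, X = np.ogrid[:33, :33, :33]
        ball = ((Z - 16) ** 2 + (Y - 16) ** 2 + (X - 16) ** 2 <= 100)
        lt = local_thickness_map(VoxelVolume(ball.astype(np.uint8), 1.0),
                                 pad_mode="constant")
        assert lt.data[16, 16, 16] == pytest.approx(20.0, abs=1.0)

    def test_empty_phase(self):
        lt = local_thickness_map(VoxelVolume(np.zeros((8, 8, 8), np.uint8),
                                             1.0))
        assert not lt.data.any()

    def test_plate_marrow_spacing(self, plate_phantom):
        _, vol, truth = plate_phantom
        marrow = vol.like((1 - vol.data).astype(np.uint8))
        lt = local_thickness_map(marrow)
        sel = marrow.as_bool()
        assert lt.data[sel].mean() == pytest.approx(truth.tb_sp,
                                                    abs=vol.voxel_size)


class TestRegionThickness:
    def test_plate_closed_forms(self):
        spec = PhantomSpec(kind="plate", voxel_size=0.02, dims=(100, 60, 60),
                           thickness=0.2, period=1.0, axis=(1, 0, 0))
        vol, truth = make_phantom(spec)
        ts = region_thickness(vol, full_mask(vol))
        assert ts.tb_th == pytest.approx(0.2, abs=0.02)
        assert ts.tb_sp == pytest.approx(0.8, abs=0.02)
        assert ts.tb_n == pytest.approx(1.0, abs=0.05)

    def test_identity_machine_precision(self, foam_phantom):
        _, vol, _ = foam_phantom
        ts = region_thickness(vol, full_mask(vol))
        assert ts.tb_n * (ts.tb_th + ts.tb_sp) == pytest.approx(1.0, abs=1e-12)

    def test_voxel_size_scaling(self, foam_phantom):
        _, vol, _ = foam_phantom
        ts1 = region_thickness(vol, full_mask(vol))
        doubled = VoxelVolume(vol.data, vol.voxel_size * 2)
        ts2 = region_thickness(doubled, full_mask(doubled))
        assert ts2.tb_th == pytest.approx(2 * ts1.tb_th)
        assert ts2.tb_sp == pytest.approx(2 * ts1.tb_sp)
        assert ts2.tb_n == pytest.approx(ts1.tb_n / 2)

    def test_single_phase_errors(self):
        solid = VoxelVolume(np.ones((20, 20, 20), np.uint8), 0.1)
        with pytest.raises(ValueError, match="marrow"):
            region_thickness(solid, full_mask(solid))
        empty = VoxelVolume(np.zeros((20, 20, 20), np.uint8), 0.1)
        with pytest.raises(ValueError, match="bone"):
            region_thickness(empty, full_mask(empty))


class TestSampleGrid:
    def test_samples_valid_and_bounded(self, foam_phantom):
        _, vol, truth = foam_phantom
        mask = full_mask(vol)
        grid = build_grid(mask, spacing=1.0, voi_diameter=2.0)
        samples = sample_grid(vol, mask, grid, compute_fabric=True,
                              n_directions=32)
        assert any(s.valid for s in samples)
        for s in samples:
            assert 0.0 <= s.bvtv <= 1.0
            if s.fabric is not None and s.fabric.valid:
                assert 0.0 <= s.fabric.da <= 1.0
        interior = [s.bvtv for s in samples if s.valid]
        assert np.mean(interior) == pytest.approx(truth.bvtv, abs=0.03)
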