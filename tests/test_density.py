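import math

import gemmi
import numpy as np
import pytest
from scipy import integrate

from emfit import fixtures as fx
from emfit.density import (
    DensityMap,
    DensitySimParams,
    ccc,
    crop_map,
    read_map,
    segment_map_zone,
    simulate_density,
    write_map,
)
from emfit.errors import ConfigError, DegenerateInputError, FormatError, GridError
from emfit.structures import Atom, AtomicModel


def one_atom(pos=(0.0, 0.0, 0.0)):
    return AtomicModel([Atom("A", 1, "ALA", "CA", "C", pos)])


def kernel_total(sigma: float) -> float:
    return (2.0 * math.pi * sigma**2 / 3.0) ** 1.5


class TestMapIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        dmap = DensityMap(rng.random((4, 5, 6)), [1.0, -2.0, 3.5],
                          [1.25, 1.25, 1.25])
        path = tmp_path / "m.mrc"
        write_map(dmap, path)
        back = read_map(path)
        assert np.array_equal(back.values,
                              dmap.values.astype(np.float32).astype(float))
        assert np.allclose(back.origin, dmap.origin, atol=1e-6)
        assert np.allclose(back.spacing, dmap.spacing, atol=1e-6)

    def test_permuted_axis_order_reads_to_same_world_density(self, tmp_path):
        rng = np.random.default_rng(1)
        vals = rng.random((3, 4, 5))
        canonical = DensityMap(vals, [1.0, 2.0, 3.0], [1.5, 1.5, 1.5])
        write_map(canonical, tmp_path / "a.mrc")

        # same world-space grid stored with file axes (y, z, x)
        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(np.ascontiguousarray(
            np.transpose(vals, (1, 2, 0)), dtype=np.float32))
        m.grid.unit_cell = gemmi.UnitCell(4.5, 6.0, 7.5, 90, 90, 90)
        m.grid.spacegroup = gemmi.SpaceGroup("P1")
        m.update_ccp4_header()
        m.set_header_i32(17, 2)
        m.set_header_i32(18, 3)
        m.set_header_i32(19, 1)
        m.set_header_i32(8, 3)
        m.set_header_i32(9, 4)
        m.set_header_i32(10, 5)
        for w, v in zip((50, 51, 52), (1.0, 2.0, 3.0)):
            m.set_header_float(w, v)
        m.write_ccp4_map(str(tmp_path / "b.mrc"))

        a = read_map(tmp_path / "a.mrc")
        b = read_map(tmp_path / "b.mrc")
        assert np.array_equal(a.values, b.values)
        assert np.allclose(a.origin, b.origin)

    def test_truncated_file_rejected(self, tmp_path):
        write_map(DensityMap(np.ones((3, 3, 3)), [0, 0, 0], [1, 1, 1]),
                  tmp_path / "m.mrc")
        blob = (tmp_path / "m.mrc").read_bytes()[:100]
        (tmp_path / "t.mrc").write_bytes(blob)
        with pytest.raises(FormatError):
            read_map(tmp_path / "t.mrc")


class TestSimulateDensity:
    @pytest.mark.parametrize("sigma", [4.0, 6.0, 8.0])
    def test_total_density_conservation(self, helix30, sigma):
        params = DensitySimParams(sigma=sigma)
        dmap = simulate_density(helix30, "auto", params)
        expected = len(helix30) * kernel_total(sigma)
        assert dmap.values.sum() == pytest.approx(expected, rel=1e-3)

    def test_linearity_two_far_atoms(self):
        params = DensitySimParams(sigma=4.0, voxel_size=2.0)
        single = simulate_density(one_atom(), "auto", params).values.sum()
        two = AtomicModel([Atom("A", 1, "ALA", "CA", "C", (0, 0, 0)),
                           Atom("A", 2, "ALA", "CA", "C", (60.0, 0, 0))])
        total = simulate_density(two, "auto", params).values.sum()
        assert total == pytest.approx(2 * single, rel=1e-6)

    def test_voxel_value_matches_quadrature(self):
        """One voxel integral vs adaptive 3-D quadrature of the kernel."""
        sigma = 3.0
        pos = (0.37, -0.81, 0.55)
        params = DensitySimParams(sigma=sigma, voxel_size=2.0)
        dmap = simulate_density(one_atom(pos), "auto", params)
        idx = (3, 2, 4)
        lo = dmap.origin + (np.array(idx) - 0.5) * dmap.spacing
        hi = lo + dmap.spacing
        a = 3.0 / (2.0 * sigma**2)

        val, _ = integrate.tplquad(
            lambda z, y, x: math.exp(-a * ((x - pos[0]) ** 2
                                           + (y - pos[1]) ** 2
                                           + (z - pos[2]) ** 2)),
            lo[0], hi[0], lo[1], hi[1], lo[2], hi[2],
            epsabs=1e-13, epsrel=1e-12)
        assert dmap.values[idx] == pytest.approx(val, rel=1e-8)

    def test_integer_voxel_translation_equivariance(self, helix30):
        params = DensitySimParams(sigma=4.0, voxel_size=2.0)
        base = simulate_density(helix30, "auto", params)
        shift_vox = np.array([2, 1, 3])
        moved = helix30.with_coords(helix30.coords
                                    + shift_vox * base.spacing)
        grid2 = DensityMap(np.zeros(base.dims),
                           base.origin + shift_vox * base.spacing,
                           base.spacing)
        moved_map = simulate_density(moved, grid2, params)
        assert np.allclose(moved_map.values, base.values, atol=1e-10)

    def test_bad_sigma_rejected(self):
        with pytest.raises(ConfigError):
            DensitySimParams(sigma=-1.0)


class TestCcc:
    def grid(self, values):
        values = np.asarray(values, float).reshape(-1, 1, 1)
        return DensityMap(values, [0, 0, 0], [1, 1, 1])

    def test_algebra(self):
        a = self.grid([1, 2, 3])
        b = self.grid([3, 2, 1])
        assert ccc(a, a) == pytest.approx(1.0)
        scaled = self.grid([2.5, 5.0, 7.5])
        assert ccc(a, scaled) == pytest.approx(1.0)
        assert ccc(a, b) == pytest.approx(10.0 / 14.0)
        assert ccc(a, b) == pytest.approx(ccc(b, a))

    def test_cauchy_schwarz_bound(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = self.grid(rng.normal(size=7))
            b = self.grid(rng.normal(size=7))
            assert abs(ccc(a, b)) <= 1.0 + 1e-12

    def test_degenerate_inputs(self):
        a = self.grid([1, 2, 3])
        with pytest.raises(DegenerateInputError):
            ccc(a, self.grid([0, 0, 0]))
        other = DensityMap(np.ones((3, 1, 1)), [0, 0, 0], [2, 2, 2])
        with pytest.raises(GridError):
            ccc(a, other)


class TestSegmentation:
    def test_full_radius_is_identity(self, helix30):
        params = DensitySimParams(sigma=4.0, voxel_size=2.0)
        dmap = simulate_density(helix30, "auto", params)
        seg = segment_map_zone(dmap, helix30, radius=1000.0)
        assert np.array_equal(seg.values, dmap.values)

    def test_tiny_radius_single_voxel(self):
        dmap = DensityMap(np.ones((5, 5, 5)), [0, 0, 0], [2, 2, 2])
        center = np.array([4.0, 4.0, 4.0])  # center of voxel (2,2,2)
        seg = segment_map_zone(dmap, center[None, :], radius=1.0)
        assert seg.metadata["zone_voxels"] == 1
        assert seg.values[2, 2, 2] == 1.0
        assert seg.values.sum() == 1.0

    def test_disjoint_anchors_add(self):
        dmap = DensityMap(np.ones((20, 5, 5)), [0, 0, 0], [1, 1, 1])
        a = np.array([[2.0, 2.0, 2.0]])
        b = np.array([[16.0, 2.0, 2.0]])
        na = segment_map_zone(dmap, a, 3.0).metadata["zone_voxels"]
        nb = segment_map_zone(dmap, b, 3.0).metadata["zone_voxels"]
        both = segment_map_zone(dmap, np.vstack([a, b]), 3.0)
        assert both.metadata["zone_voxels"] == na + nb

    def test_zone_missing_map_rejected(self):
        dmap = DensityMap(np.ones((4, 4, 4)), [0, 0, 0], [1, 1, 1])
        with pytest.raises(GridError):
            segment_map_zone(dmap, np.array([[100.0, 100.0, 100.0]]), 2.0)


class TestCrop:
    def test_full_box_identity(self):
        dmap = DensityMap(np.arange(27.0).reshape(3, 3, 3), [1, 2, 3],
                          [1, 1, 1])
        out = crop_map(dmap, [(0, 3), (0, 3), (0, 3)])
        assert np.array_equal(out.values, dmap.values)
        assert np.allclose(out.origin, dmap.origin)

    def test_single_voxel_origin(self):
        dmap = DensityMap(np.arange(27.0).reshape(3, 3, 3), [1.0, 2.0, 3.0],
                          [2.0, 2.0, 2.0])
        out = crop_map(dmap, [(1, 2), (2, 3), (0, 1)])
        assert out.dims == (1, 1, 1)
        assert np.allclose(out.origin, [3.0, 6.0, 3.0])
        assert out.values[0, 0, 0] == dmap.values[1, 2, 0]

    def test_crop_ccc_equals_restricted_ccc(self):
        rng = np.random.default_rng(5)
        a = DensityMap(rng.random((6, 6, 6)), [0, 0, 0], [1, 1, 1])
        b = DensityMap(rng.random((6, 6, 6)), [0, 0, 0], [1, 1, 1])
        box = [(1, 4), (2, 6), (0, 3)]
        direct = ccc(crop_map(a, box), crop_map(b, box))
        sa = a.values[1:4, 2:6, 0:3].ravel()
        sb = b.values[1:4, 2:6, 0:3].ravel()
        manual = float(sa @ sb / np.sqrt((sa @ sa) * (sb @ sb)))
        assert direct == pytest.approx(manual, abs=1e-12)

    def test_out_of_bounds_rejected(self):
        dmap = DensityMap(np.ones((3, 3, 3)), [0, 0, 0], [1, 1, 1])
        with pytest.raises(GridError):
            crop_map(dmap, [(0, 4), (0, 3), (0, 3)])
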