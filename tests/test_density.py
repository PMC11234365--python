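import numpy as np
import pytest

from nmfit.density import (DensityMap, blur_map, cc_structure,
                           cross_correlation, em_forces, potential_grid,
                           read_map, sigma_from_resolution, simulate_map,
                           write_map)
from conftest import make_structure


@pytest.fixture()
def small_structure(rng):
    coords = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 1, 0],
                       [11, 2, 1], [13, 5, 2]], dtype=float)
    return make_structure(coords + rng.uniform(0.11, 0.29, coords.shape))


class TestSimulateMap:
    def test_single_atom_integral_equals_mass(self):
        s = make_structure([[0.0, 0.0, 0.0]], masses=[12.011])
        m = simulate_map(s, resolution=5.0, voxel=1.0, padding=10.0)
        integral = m.data.sum() * m.voxel_volume()
        assert integral == pytest.approx(12.011, rel=0.01)
        # maximum at the origin voxel
        peak = np.unravel_index(m.data.argmax(), m.shape)
        pos = m.origin + m.voxel * np.array(peak)
        assert np.linalg.norm(pos) < m.voxel.max()

    def test_two_far_atoms_two_equal_maxima(self):
        s = make_structure([[0, 0, 0], [30, 0, 0]])
        m = simulate_map(s, 5.0, voxel=1.0, padding=8.0)
        left = m.data[: m.shape[0] // 2]
        right = m.data[m.shape[0] // 2:]
        assert left.max() == pytest.approx(right.max(), rel=1e-6)

    def test_translation_equivariance_integer_voxel(self, small_structure):
        m1 = simulate_map(small_structure, 5.0, voxel=1.0, padding=8.0)
        shifted = small_structure.with_coords(
            small_structure.coords + [1.0, 0.0, 0.0])
        m2 = simulate_map(shifted, 5.0, like=DensityMap(
            np.zeros(m1.shape), m1.voxel, m1.origin + [1.0, 0, 0]))
        assert np.abs(m1.data - m2.data).max() < 1e-10

    def test_permutation_invariance(self, small_structure):
        m1 = simulate_map(small_structure, 5.0)
        perm = np.array([4, 2, 0, 1, 3])
        s2 = make_structure(small_structure.coords[perm])
        m2 = simulate_map(s2, 5.0, like=m1)
        assert np.abs(m1.data - m2.data).max() < 1e-12

    def test_undersampling_rejected(self, small_structure):
        with pytest.raises(ValueError, match="undersample"):
            simulate_map(small_structure, 5.0, voxel=3.0)

    def test_hydrogens_excluded(self):
        s = make_structure([[0, 0, 0], [1, 0, 0]], names=["CA", "H"],
                           elements=["C", "H"], masses=[12.011, 1.008])
        m = simulate_map(s, 5.0, padding=10.0)
        assert m.data.sum() * m.voxel_volume() == pytest.approx(12.011,
                                                                rel=0.01)


class TestMapIO:
    def test_round_trip(self, tmp_path, rng):
        data = rng.random((8, 8, 8))
        m = DensityMap(data, voxel=1.25, origin=[-3.0, 2.0, 0.5])
        p = tmp_path / "m.mrc"
        write_map(m, p)
        m2 = read_map(p)
        assert m2.shape == m.shape
        assert np.allclose(m2.voxel, m.voxel, atol=1e-5)
        assert np.allclose(m2.origin, m.origin, atol=1e-4)
        assert np.abs(m2.data - m.data).max() < 1e-6  # float32 storage

    def test_permuted_axes_normalised(self, tmp_path, rng):
        # hand-build an MRC2014 file whose fastest file axis is z
        # (MAPC/MAPR/MAPS = 3,2,1); reading must normalise to x,y,z
        data = rng.random((4, 6, 8)).astype(np.float32)  # logical x,y,z
        p = tmp_path / "perm.mrc"
        header = np.zeros(256, dtype=np.int32)
        fheader = header.view(np.float32)
        header[0:3] = (8, 6, 4)       # NC, NR, NS = z, y, x counts
        header[3] = 2                 # mode 2 float32
        header[7:10] = (4, 6, 8)      # MX,MY,MZ intervals along x,y,z
        fheader[10:13] = (4.0, 6.0, 8.0)  # cell a,b,c (x,y,z) for 1 Å voxels
        fheader[13:16] = (90.0, 90.0, 90.0)
        header[16:19] = (3, 2, 1)     # MAPC, MAPR, MAPS
        fheader[19:22] = (float(data.min()), float(data.max()),
                          float(data.mean()))
        header[22] = 1                # P1
        header[52] = int.from_bytes(b"MAP ", "little")
        header[53] = int.from_bytes(b"\x44\x44\x00\x00", "little")
        with open(p, "wb") as fh:
            fh.write(header.tobytes())
            # file order: sections=x, rows=y, columns=z (z fastest)
            fh.write(np.ascontiguousarray(
                np.transpose(data, (0, 1, 2))).tobytes())
        m = read_map(p)
        assert m.shape == (4, 6, 8)
        assert np.abs(m.data - data).max() < 1e-6

    def test_truncated_file_errors(self, tmp_path):
        p = tmp_path / "bad.mrc"
        p.write_bytes(b"\x00" * 100)
        with pytest.raises(IOError):
            read_map(p)


class TestCrossCorrelation:
    def test_self_correlation(self, small_structure):
        m = simulate_map(small_structure, 5.0)
        assert cross_correlation(m, m) == pytest.approx(1.0)

    def test_anticorrelation(self, small_structure):
        m = simulate_map(small_structure, 5.0)
        neg = DensityMap(-m.data, m.voxel, m.origin)
        assert cross_correlation(m, neg, threshold=-np.inf) == pytest.approx(-1.0)

    def test_matches_direct_voxel_sum(self, small_structure):
        m1 = simulate_map(small_structure, 5.0)
        shifted = small_structure.with_coords(small_structure.coords
                                              + [3.0, 0, 0])
        m2 = simulate_map(shifted, 5.0, like=m1)
        cc = cross_correlation(m1, m2)
        a, b = m1.data.ravel(), m2.data.ravel()
        oracle = float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))
        assert cc == pytest.approx(oracle, abs=1e-12)

    def test_scale_invariance(self, small_structure):
        m = simulate_map(small_structure, 5.0)
        scaled = DensityMap(3.7 * m.data, m.voxel, m.origin)
        assert cross_correlation(m, scaled) == pytest.approx(1.0)

    def test_zero_map_rejected(self):
        z = DensityMap(np.zeros((4, 4, 4)), 1.0, [0, 0, 0])
        with pytest.raises(ValueError):
            cross_correlation(z, z)

    def test_cc_structure_self_consistency(self, small_structure):
        m = simulate_map(small_structure, 5.0)
        assert cc_structure(small_structure, m, 5.0) >= 0.999

    def test_cc_far_displaced_is_negligible(self, small_structure):
        m = simulate_map(small_structure, 5.0)
        far = small_structure.with_coords(small_structure.coords + 500.0)
        assert abs(cc_structure(far, m, 5.0)) < 1e-3

    def test_cc_increases_toward_generating_structure(self, small_structure):
        m = simulate_map(small_structure, 5.0)
        ccs = []
        for t in (0.0, 0.25, 0.5, 0.75, 1.0):
            s = small_structure.with_coords(
                small_structure.coords + (1 - t) * np.array([6.0, 0, 0]))
            ccs.append(cc_structure(s, m, 5.0))
        assert all(np.diff(ccs) > 0)


class TestBlur:
    def test_near_identity_limit(self, small_structure):
        m = simulate_map(small_structure, 5.0)
        b = blur_map(m, 5.0, 5.0 + 1e-6)
        assert np.abs(b.data - m.data).max() / m.data.max() < 1e-6

    def test_gaussian_semigroup(self, small_structure):
        m = simulate_map(small_structure, 5.0)
        one = blur_map(m, 5.0, 9.0)
        two = blur_map(blur_map(m, 5.0, 7.0), 7.0, 9.0)
        assert np.abs(one.data - two.data).max() / one.data.max() < 1e-5

    def test_blurred_width_matches_analytic_sigma(self):
        s = make_structure([[0.0, 0.0, 0.0]])
        m = simulate_map(s, 4.0, voxel=1.0, padding=20.0)
        b = blur_map(m, 4.0, 9.0)
        # fit sigma from second moment along x through the peak
        x = m.origin[0] + np.arange(m.shape[0]) * m.voxel[0]
        peak = np.array(np.unravel_index(b.data.argmax(), b.shape))
        prof = b.data[:, peak[1], peak[2]]
        mu = (prof * x).sum() / prof.sum()
        sigma_fit = np.sqrt((prof * (x - mu) ** 2).sum() / prof.sum())
        assert sigma_fit == pytest.approx(sigma_from_resolution(9.0),
                                          rel=0.02)

    def test_sharpening_rejected(self, small_structure):
        m = simulate_map(small_structure, 5.0)
        with pytest.raises(ValueError):
            blur_map(m, 5.0, 4.0)


class TestPotentialGrid:
    def test_extremes_and_linearity(self, small_structure):
        m = simulate_map(small_structure, 5.0)
        pg = potential_grid(m, gscale=0.3, floor=0.0)
        assert pg.potential.min() == pytest.approx(0.0, abs=1e-12)
        assert pg.potential.flat[np.argmax(m.data)] == pytest.approx(0.0)
        assert pg.potential.max() <= 0.3 + 1e-12
        rho_max = m.data.max()
        mid = np.abs(m.data - rho_max / 2).argmin()
        expected = 0.3 * (1 - m.data.flat[mid] / rho_max)
        assert pg.potential.flat[mid] == pytest.approx(expected, rel=1e-10)

    def test_floor_above_max_rejected(self, small_structure):
        m = simulate_map(small_structure, 5.0)
        with pytest.raises(ValueError):
            potential_grid(m, floor=m.data.max() * 2)


class TestEmForces:
    def test_force_is_negative_gradient(self, small_structure):
        # non-integral padding keeps every atom off the grid planes, where
        # the trilinear gradient is two-sided
        m = simulate_map(small_structure, 5.0, padding=8.3)
        pg = potential_grid(m, 0.3)
        F, E = em_forces(pg, small_structure)
        h = 1e-4
        scale = np.abs(F).max()
        for i in range(small_structure.n_atoms):
            for ax in range(3):
                c = small_structure.coords.copy()
                c[i, ax] += h
                _, ep = em_forces(pg, small_structure.with_coords(c))
                c[i, ax] -= 2 * h
                _, em = em_forces(pg, small_structure.with_coords(c))
                fd = -(ep - em) / (2 * h)
                assert abs(fd - F[i, ax]) / scale < 1e-4

    def test_gscale_linearity(self, small_structure):
        m = simulate_map(small_structure, 5.0)
        F1, E1 = em_forces(potential_grid(m, 0.3), small_structure)
        F2, E2 = em_forces(potential_grid(m, 0.6), small_structure)
        assert E2 == pytest.approx(2 * E1, rel=1e-12)
        assert np.allclose(F2, 2 * F1, rtol=1e-12)

    def test_atom_at_density_maximum(self):
        # half-integral padding centres the atom in a grid cell, where the
        # trilinear gradient of the symmetric peak cancels exactly
        s = make_structure([[0.0, 0.0, 0.0]])
        m = simulate_map(s, 5.0, voxel=1.0, padding=7.5)
        pg = potential_grid(m, 0.3)
        F, E = em_forces(pg, s)
        assert E < 0.05 * 0.3 * s.masses[0]
        assert np.abs(F).max() < 0.02

    def test_first_order_descent(self, small_structure):
        m = simulate_map(small_structure, 5.0)
        pg = potential_grid(m, 0.3)
        s = small_structure.with_coords(small_structure.coords + 2.0)
        F, E = em_forces(pg, s)
        step = 1e-3 * F / max(np.abs(F).max(), 1e-12)
        _, E2 = em_forces(pg, s.with_coords(s.coords + step))
        assert E2 < E

    def test_out_of_grid_restoring_force(self, small_structure):
        m = simulate_map(small_structure, 5.0)
        pg = potential_grid(m, 0.3)
        outside = small_structure.with_coords(small_structure.coords
                                              + [100.0, 0, 0])
        F, E = em_forces(pg, outside)
        assert E > 0
        assert (F[:, 0] < 0).all()  # pulled back toward the grid
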