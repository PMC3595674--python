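"""Phantom construction, forward physics, and MR signal synthesis."""

import numpy as np
import pytest

from mreit import phantom as ph
from mreit.errors import ValidationError
from mreit.grids import SliceGrid
from conftest import make_square_setup


class TestSheppLogan:
    def test_degenerate_contrast_gives_uniform_sigma(self):
        grid = SliceGrid(32, 32, 1e-3, 1e-3, 1e-3)
        ells = [ph.EllipseSpec((0, 0), (0.8, 0.9), 0.0, 1.0),
                ph.EllipseSpec((0.1, 0.0), (0.3, 0.2), 0.5, 1.0)]
        p = ph.make_shepp_logan(grid, ells)
        assert np.all(p.sigma[p.domain_mask] == 1.0)

    def test_nonpositive_value_rejected(self):
        grid = SliceGrid(32, 32, 1e-3, 1e-3, 1e-3)
        with pytest.raises(ValidationError):
            ph.make_shepp_logan(grid, [ph.EllipseSpec((0, 0), (0.8, 0.8), 0, -0.5)])

    def test_outer_ellipse_must_fit_grid(self):
        grid = SliceGrid(32, 32, 1e-3, 1e-3, 1e-3)
        with pytest.raises(ValidationError):
            ph.make_shepp_logan(grid, [ph.EllipseSpec((0.5, 0), (0.8, 0.8), 0, 1.0)])

    def test_default_phantom_matches_membership_oracle(self):
        """Pixel counts per conductivity level agree with a brute-force
        point-in-ellipse loop over every pixel."""
        import math

        grid = SliceGrid(128, 128, 2e-3, 2e-3, 2e-3)
        p = ph.make_shepp_logan(grid)
        ells = ph.default_shepp_logan_ellipses()

        cx, cy = grid.center()
        half = 0.5 * max(grid.dx * (grid.nx - 1), grid.dy * (grid.ny - 1))
        sigma_oracle = np.ones(grid.shape)
        mask_oracle = np.zeros(grid.shape, dtype=bool)
        for iy in range(grid.ny):
            for ix in range(grid.nx):
                xn = (grid.origin[0] + ix * grid.dx - cx) / half
                yn = (grid.origin[1] + iy * grid.dy - cy) / half
                for k, e in enumerate(ells):
                    ct, st = math.cos(e.angle), math.sin(e.angle)
                    u = ct * (xn - e.center[0]) + st * (yn - e.center[1])
                    v = -st * (xn - e.center[0]) + ct * (yn - e.center[1])
                    inside = (u / e.axes[0]) ** 2 + (v / e.axes[1]) ** 2 <= 1.0
                    if k == 0:
                        mask_oracle[iy, ix] = inside
                    elif inside:
                        sigma_oracle[iy, ix] = e.value
        assert np.array_equal(p.domain_mask, mask_oracle)
        for value in sorted({e.value for e in ells}):
            assert (np.sum(p.sigma[p.domain_mask] == value)
                    == np.sum(sigma_oracle[mask_oracle] == value))


class TestForwardSolve:
    def test_uniform_square_recovers_linear_potential(self, square):
        pot = ph.solve_forward_2d(square.phantom, square.electrodes, 1, square.mesh)
        expected = (2 * square.mesh.vertices[:, 0] - square.L) / square.L
        assert np.abs(pot.u - expected).max() < 1e-9

    def test_swapping_electrodes_negates_potential(self, square):
        pot = ph.solve_forward_2d(square.phantom, square.electrodes, 1, square.mesh)
        swapped = make_square_setup(swap_injection1=True)
        pot_sw = ph.solve_forward_2d(swapped.phantom, swapped.electrodes, 1,
                                     swapped.mesh)
        assert np.abs(pot_sw.u + pot.u).max() < 1e-9

    def test_two_disk_phantom_matches_finite_difference_oracle(self):
        """Nodal potential agrees with an independent 5-point FD solver on
        the pixel grid within 1% relative L2."""
        setup = make_square_setup(n=48)
        grid = setup.grid
        X, Y = grid.meshgrid()
        cx, cy = grid.center()
        sigma = np.ones(grid.shape)
        sigma[(X - cx - 8e-3) ** 2 + (Y - cy) ** 2 < (7e-3) ** 2] = 2.0
        sigma[(X - cx + 9e-3) ** 2 + (Y - cy + 5e-3) ** 2 < (6e-3) ** 2] = 0.5
        phantom = ph.ConductivityPhantom(grid, sigma, np.ones(grid.shape, bool))
        pot = ph.solve_forward_2d(phantom, setup.electrodes, 1, setup.mesh)
        u_pix = setup.mesh.rasterize_vertex_values(pot.u, grid)

        u_fd = _fd_forward_oracle(sigma, grid)
        err = np.linalg.norm(u_pix - u_fd) / np.linalg.norm(u_fd)
        assert err < 0.01


def _fd_forward_oracle(sigma, grid):
    """Independent 5-point finite-difference solve of div(sigma grad u) = 0
    on the full square with u = +/-1 on the right/left pixel columns and
    zero-flux top/bottom (harmonic-mean face conductivities)."""
    from scipy import sparse
    from scipy.sparse.linalg import spsolve

    ny, nx = grid.shape
    idx = np.arange(ny * nx).reshape(ny, nx)
    rows, cols, vals = [], [], []
    b = np.zeros(ny * nx)

    def face(s1, s2):
        return 2.0 * s1 * s2 / (s1 + s2)

    for iy in range(ny):
        for ix in range(nx):
            k = idx[iy, ix]
            if ix == 0:
                rows.append(k); cols.append(k); vals.append(1.0); b[k] = -1.0
                continue
            if ix == nx - 1:
                rows.append(k); cols.append(k); vals.append(1.0); b[k] = 1.0
                continue
            diag = 0.0
            for jy, jx in ((iy, ix - 1), (iy, ix + 1), (iy - 1, ix), (iy + 1, ix)):
                if not (0 <= jy < ny):
                    continue   # no-flux
                w = face(sigma[iy, ix], sigma[jy, jx])
                diag += w
                rows.append(k); cols.append(idx[jy, jx]); vals.append(-w)
            rows.append(k); cols.append(k); vals.append(diag)
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(ny * nx,) * 2)
    return spsolve(A.tocsc(), b).reshape(ny, nx)


class TestCurrentDensity:
    def test_uniform_square_current_is_constant(self, square):
        pot = ph.solve_forward_2d(square.phantom, square.electrodes, 1, square.mesh)
        J = ph.current_density(square.phantom, pot)
        jx = J.Jx[J.valid]
        assert np.std(jx) / np.abs(np.mean(jx)) < 1e-6
        assert np.abs(J.Jy[J.valid]).max() < 1e-6 * np.abs(np.mean(jx))

    def test_electrode_flux_balance(self, low_contrast64):
        sim = low_contrast64
        for pot in sim.potentials:
            f_in = ph.electrode_flux(pot, "+")
            f_out = ph.electrode_flux(pot, "-")
            assert abs(f_in + f_out) <= 1e-8 * abs(f_in)

    def test_curl_vanishes_in_homogeneous_subregion(self, disk64):
        """J = -sigma grad u is curl-free where sigma is constant."""
        sim = disk64
        J = sim.currents[0]
        h = sim.grid.dx
        curl = ((J.Jy[1:-1, 2:] - J.Jy[1:-1, :-2])
                - (J.Jx[2:, 1:-1] - J.Jx[:-2, 1:-1])) / (2 * h)
        from scipy.ndimage import binary_erosion
        interior = binary_erosion(sim.valid, iterations=6)[1:-1, 1:-1]
        scale = np.nanmedian(np.abs(J.Jx[sim.valid])) / h
        assert np.nanmax(np.abs(curl[interior])) < 5e-2 * scale


class TestBiotSavart:
    def test_zero_current_gives_zero_field(self):
        grid = SliceGrid(16, 16, 1e-3, 1e-3, 1e-3)
        J = ph.CurrentDensityField(grid, np.zeros(grid.shape),
                                   np.zeros(grid.shape),
                                   np.ones(grid.shape, bool))
        assert np.all(ph.biot_savart_bz(J) == 0)

    def test_mirror_symmetric_current_gives_odd_bz(self):
        """A current field mirror-symmetric about the vertical axis
        (x-component odd, y-component even as functions of x) induces a Bz
        that is odd about that axis."""
        grid = SliceGrid(24, 24, 1e-3, 1e-3, 1e-3)
        X, Y = grid.meshgrid()
        cx, cy = grid.center()
        gauss = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (5e-3) ** 2)
        Jx = (X - cx) / grid.dx * gauss
        Jy = gauss
        J = ph.CurrentDensityField(grid, Jx, Jy, np.ones(grid.shape, bool))
        bz = ph.biot_savart_bz(J)
        assert np.abs(bz + bz[:, ::-1]).max() < 1e-10 * np.abs(bz).max()

    def test_laplacian_matches_curl_identity(self, low_contrast64):
        """Discrete lap(Bz) equals -mu0 (dJy/dx - dJx/dy) from the simulated
        current within discretization tolerance (2D magnetostatics)."""
        sim = low_contrast64
        from scipy.ndimage import binary_erosion

        h = sim.grid.dx
        J = sim.currents[0]
        bz = sim.bz[0]
        lap = (bz[1:-1, 2:] + bz[1:-1, :-2] + bz[2:, 1:-1] + bz[:-2, 1:-1]
               - 4 * bz[1:-1, 1:-1]) / h ** 2
        curl = ((J.Jy[1:-1, 2:] - J.Jy[1:-1, :-2])
                - (J.Jx[2:, 1:-1] - J.Jx[:-2, 1:-1])) / (2 * h)
        rhs = -ph.MU0 * curl
        interior = binary_erosion(sim.valid, iterations=4)[1:-1, 1:-1]
        a, b = lap[interior], rhs[interior]
        assert np.corrcoef(a, b)[0, 1] > 0.98
        assert np.linalg.norm(a - b) <= 0.2 * np.linalg.norm(b)

    def test_empty_grid_rejected(self):
        grid = SliceGrid(16, 16, 1e-3, 1e-3, 1e-3)
        J = ph.CurrentDensityField(grid, np.zeros(grid.shape),
                                   np.zeros(grid.shape),
                                   np.ones(grid.shape, bool))
        assert ph.biot_savart_bz(J, grid).shape == grid.shape


class TestSignalSynthesis:
    def test_zero_field_gives_equal_images(self):
        M = np.full((8, 8), 2.0)
        pair = ph.synthesize_complex_pair(M, 0.0, np.zeros((8, 8)), Tc=0.01)
        assert np.array_equal(pair.m_plus, pair.m_minus)
        assert np.allclose(pair.m_plus, M)

    def test_phase_difference_matches_construction(self):
        rng = np.random.default_rng(0)
        M = 1 + rng.random((16, 16))
        bz = 1e-9 * rng.standard_normal((16, 16))
        delta = rng.standard_normal((16, 16))
        pair = ph.synthesize_complex_pair(M, delta, bz, Tc=0.01)
        phase = np.angle(pair.m_plus * np.conj(pair.m_minus))
        expected = 2 * ph.GAMMA_HYDROGEN * 0.01 * bz
        wrapped = np.angle(np.exp(1j * expected))
        assert np.abs(phase - wrapped).max() < 1e-12

    def test_hydrogen_gamma_phase_scale(self):
        """gamma Bz Tc with the hydrogen gyromagnetic ratio: 26.75e7 rad/T/s
        at Bz = 1 nT and Tc = 10 ms gives 2.675e-3 rad per pixel."""
        M = np.ones((8, 8))
        pair = ph.synthesize_complex_pair(M, 0.0, np.full((8, 8), 1e-9), Tc=0.01)
        phase = np.angle(pair.m_plus)
        assert np.allclose(phase, 26.75e7 * 1e-9 * 0.01)

    def test_noise_reproducible_from_seed(self):
        M = np.ones((8, 8))
        bz = np.zeros((8, 8))
        a = ph.synthesize_complex_pair(M, 0.0, bz, 0.01, noise_sd=0.1, rng=42)
        b = ph.synthesize_complex_pair(M, 0.0, bz, 0.01, noise_sd=0.1, rng=42)
        assert np.array_equal(a.m_plus, b.m_plus)
        assert np.array_equal(a.m_minus, b.m_minus)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValidationError):
            ph.synthesize_complex_pair(np.ones((8, 8)), 0.0, np.zeros((8, 8)),
                                       0.01, noise_sd=-1.0)


class TestKSpace:
    def test_round_trip_identity(self):
        from mreit.phase import kspace_to_image

        rng = np.random.default_rng(1)
        grid = SliceGrid(12, 10, 1e-3, 1e-3, 1e-3)
        img = rng.standard_normal((10, 12)) + 1j * rng.standard_normal((10, 12))
        pair = ph.ComplexImagePair(img, img.conj(), np.abs(img),
                                   np.zeros((10, 12)), 0.01)
        k = ph.synthesize_kspace(pair, grid)
        back = kspace_to_image(k.s_plus, k.convention)
        assert np.abs(back - img).max() < 1e-12

    def test_constant_image_is_dc_only(self):
        grid = SliceGrid(8, 8, 1e-3, 1e-3, 1e-3)
        img = np.full((8, 8), 3.0, dtype=complex)
        pair = ph.ComplexImagePair(img, img, np.abs(img), np.zeros((8, 8)), 0.01)
        k = ph.synthesize_kspace(pair, grid)
        dc = k.s_plus[4, 4]   # fftshifted DC position
        assert abs(dc - 3.0 * 64) < 1e-10
        off = k.s_plus.copy()
        off[4, 4] = 0
        assert np.abs(off).max() < 1e-10

    def test_parseval(self):
        rng = np.random.default_rng(2)
        grid = SliceGrid(16, 16, 1e-3, 1e-3, 1e-3)
        img = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        pair = ph.ComplexImagePair(img, img, np.abs(img), np.zeros((16, 16)), 0.01)
        k = ph.synthesize_kspace(pair, grid)
        lhs = np.sum(np.abs(img) ** 2)
        rhs = np.sum(np.abs(k.s_plus) ** 2) / (16 * 16)
        assert abs(lhs - rhs) < 1e-10 * lhs

    def test_nan_rejected(self):
        grid = SliceGrid(8, 8, 1e-3, 1e-3, 1e-3)
        img = np.full((8, 8), np.nan, dtype=complex)
        pair = ph.ComplexImagePair(img, img, np.ones((8, 8)), np.zeros((8, 8)), 0.01)
        with pytest.raises(ValidationError):
            ph.synthesize_kspace(pair, grid)
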