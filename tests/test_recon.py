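"""P1 FEM assembly, CG, Bz Laplacians, the A matrix, and the Poisson solve."""

import numpy as np
import pytest

from mreit import fem
from mreit import phantom as ph
from mreit.errors import QualityError, SolverError, ValidationError
from mreit.geometry import DomainPolygon, LocalRegion, TriangleMesh, triangulate
from mreit.grids import SliceGrid
from mreit.recon import (build_a_matrix, harmonic_bz_reconstruct, laplacian_bz,
                         local_harmonic_bz, solve_cg)
from conftest import simulate_case, LOW_CONTRAST


def tiny_mesh(vertices, triangles):
    return TriangleMesh(np.asarray(vertices, float), np.asarray(triangles, int),
                        np.zeros((0, 2), int), [])


class TestAssembly:
    def test_reference_triangle_element_matrix(self):
        """Unit right triangle, coefficient 1: the classic P1 element matrix
        [[1, -1/2, -1/2], [-1/2, 1/2, 0], [-1/2, 0, 1/2]]."""
        mesh = tiny_mesh([[0, 0], [1, 0], [0, 1]], [[0, 1, 2]])
        K = fem.assemble_p1(mesh, 1.0).stiffness.toarray()
        expected = np.array([[1.0, -0.5, -0.5], [-0.5, 0.5, 0.0], [-0.5, 0.0, 0.5]])
        assert np.abs(K - expected).max() < 1e-14

    def test_constants_in_kernel(self, disk64):
        K = fem.assemble_p1(disk64.mesh, 1.0).stiffness
        ones = np.ones(K.shape[0])
        assert np.abs(K @ ones).max() < 1e-10

    def test_two_element_square_matches_quadrature_oracle(self):
        """Global matrix equals brute-force assembly by midpoint quadrature
        of grad(phi_i) . grad(phi_j) over each element."""
        verts = [[0, 0], [1, 0], [1, 1], [0, 1]]
        tris = [[0, 1, 2], [0, 2, 3]]
        mesh = tiny_mesh(verts, tris)
        K = fem.assemble_p1(mesh, 2.0).stiffness.toarray()

        def hat_grads(a, b, c):
            det = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            return (np.array([[b[1] - c[1], c[0] - b[0]],
                              [c[1] - a[1], a[0] - c[0]],
                              [a[1] - b[1], b[0] - a[0]]]) / det,
                    abs(det) / 2)

        oracle = np.zeros((4, 4))
        for t in tris:
            a, b, c = (np.array(verts[i], float) for i in t)
            G, area = hat_grads(a, b, c)
            for i in range(3):
                for j in range(3):
                    oracle[t[i], t[j]] += 2.0 * area * G[i] @ G[j]
        assert np.abs(K - oracle).max() < 1e-14

    def test_nonpositive_coefficient_rejected(self):
        mesh = tiny_mesh([[0, 0], [1, 0], [0, 1]], [[0, 1, 2]])
        with pytest.raises(ValidationError):
            fem.assemble_p1(mesh, 0.0)


class TestSolve:
    def test_constraints_returned_exactly(self):
        mesh = tiny_mesh([[0, 0], [1, 0], [0, 1]], [[0, 1, 2]])
        system = fem.assemble_p1(mesh, 1.0)
        system.constraints = [(0, 2.0), (1, -1.0), (2, 0.5)]
        u = solve_cg(system)
        assert np.array_equal(u, [2.0, -1.0, 0.5])

    def test_laplace_on_square_linear_boundary(self, square):
        """u = x on the boundary extends to u = x exactly (P1-exact)."""
        mesh = square.mesh
        system = fem.assemble_p1(mesh, 1.0)
        bverts = mesh.boundary_vertices()
        system.constraints = [(int(i), float(mesh.vertices[i, 0])) for i in bverts]
        u = solve_cg(system, tol=1e-12)
        assert np.abs(u - mesh.vertices[:, 0]).max() < 1e-9

    def test_matches_dense_direct_solve(self):
        rng = np.random.default_rng(51)
        mesh = triangulate(DomainPolygon(np.array([[0, 0], [1, 0], [1, 1], [0, 1]],
                                                  float)), 0.05)
        system = fem.assemble_p1(mesh, 1.0)
        n = len(mesh.vertices)
        system.load = rng.standard_normal(n)
        bverts = mesh.boundary_vertices()
        system.constraints = [(int(i), 0.0) for i in bverts]
        u = solve_cg(system, tol=1e-12)

        K = system.stiffness.toarray()
        free = np.setdiff1d(np.arange(n), bverts)
        u_direct = np.zeros(n)
        u_direct[free] = np.linalg.solve(K[np.ix_(free, free)], system.load[free])
        assert np.abs(u - u_direct).max() < 1e-8


class TestLaplacian:
    def _vol(self, b, grid, nz=1):
        stack = np.broadcast_to(b, (nz,) + b.shape)
        return ph.BzVolume(grid, np.stack([stack, stack]),
                           np.ones(grid.shape, bool))

    def test_quadratic_exact(self):
        grid = SliceGrid(16, 16, 2e-3, 2e-3, 2e-3)
        X, _ = grid.meshgrid()
        lap = laplacian_bz(self._vol(X ** 2, grid), 0, "2d")
        assert np.abs(lap.values[lap.valid] - 2.0).max() < 1e-10

    def test_linear_gives_zero(self):
        grid = SliceGrid(16, 16, 2e-3, 2e-3, 2e-3)
        X, Y = grid.meshgrid()
        lap = laplacian_bz(self._vol(3 * X - 2 * Y, grid), 0, "2d")
        assert np.abs(lap.values[lap.valid]).max() < 1e-10

    def test_3d_mode_adds_z_second_difference(self):
        """Bz = z^2 with dz = 2 mm adds the constant 2 to the in-plane
        Laplacian; cross-checked by an explicit stencil on a small block."""
        grid = SliceGrid(8, 8, 1e-3, 1e-3, 2e-3)
        zs = np.array([0.0, 2e-3, 4e-3])
        stack = np.stack([np.full(grid.shape, z ** 2) for z in zs])
        vol = ph.BzVolume(grid, np.stack([stack, stack]),
                          np.ones(grid.shape, bool))
        lap = laplacian_bz(vol, 1, "3d")
        # hand stencil: (z0^2 - 2 z1^2 + z2^2)/dz^2 = 2, in-plane part 0
        hand = (zs[0] ** 2 - 2 * zs[1] ** 2 + zs[2] ** 2) / (2e-3) ** 2
        assert hand == pytest.approx(2.0)
        assert np.abs(lap.values[lap.valid] - 2.0).max() < 1e-9

    def test_3d_refused_on_failed_continuity(self):
        from mreit.phase import ContinuityReport

        grid = SliceGrid(8, 8, 1e-3, 1e-3, 2e-3)
        stack = np.zeros((3,) + grid.shape)
        vol = ph.BzVolume(grid, np.stack([stack, stack]), np.ones(grid.shape, bool))
        bad = ContinuityReport(ratios=[10.0], passes=[False],
                               recommended_mode="2d")
        with pytest.raises(QualityError):
            laplacian_bz(vol, 1, "3d", continuity=bad)
        # force overrides
        lap = laplacian_bz(vol, 1, "3d", continuity=bad, force=True)
        assert lap.mode == "3d"


class TestAMatrix:
    def _uniform_currents(self, c=2.0):
        grid = SliceGrid(8, 8, 1e-3, 1e-3, 1e-3)
        ones = np.ones(grid.shape, bool)
        J1 = ph.CurrentDensityField(grid, np.full(grid.shape, -c),
                                    np.zeros(grid.shape), ones)
        J2 = ph.CurrentDensityField(grid, np.zeros(grid.shape),
                                    np.full(grid.shape, -c), ones)
        return J1, J2

    def test_orthogonal_uniform_currents_closed_form(self):
        """J1 = (-c, 0), J2 = (0, -c): rows (0, -c) and (c, 0), so
        det = 0*0 - (-c)*c = c^2."""
        J1, J2 = self._uniform_currents(2.0)
        A = build_a_matrix(J1, J2)
        assert np.allclose(A.a11, 0.0) and np.allclose(A.a12, -2.0)
        assert np.allclose(A.a21, 2.0) and np.allclose(A.a22, 0.0)
        assert np.allclose(A.det, 4.0)
        assert A.reliable.all()

    def test_parallel_currents_flagged(self):
        J1, _ = self._uniform_currents(2.0)
        with pytest.warns(UserWarning):
            A = build_a_matrix(J1, J1)
        assert not A.reliable.any()

    def test_det_matches_recomputation_from_stored_currents(self, low_contrast64):
        sim = low_contrast64
        A = build_a_matrix(*sim.currents)
        J1, J2 = sim.currents
        det = (-J1.Jy) * J2.Jx - J1.Jx * (-J2.Jy)
        ok = A.valid
        assert np.allclose(A.det[ok], det[ok], equal_nan=True)


class TestReconstruction:
    def test_zero_rhs_gives_unit_sigma(self, disk64):
        sim = disk64
        A = build_a_matrix(*sim.currents)
        zero = np.zeros(sim.grid.shape)
        from mreit.recon import LaplacianField
        lap = LaplacianField(zero, sim.valid, "2d",
                             (sim.grid.dx, sim.grid.dy, sim.grid.dz))
        img = harmonic_bz_reconstruct(sim.mesh, A, lap, lap, sim.grid)
        assert np.abs(img.sigma - 1.0).max() < 1e-9
        assert np.abs(img.log_sigma[sim.mesh.boundary_vertices()]).max() == 0.0

    def _reconstruct(self, sim, bz_pair, margin=4, **kw):
        from scipy.ndimage import binary_erosion

        valid = binary_erosion(sim.valid, iterations=margin)
        vol = ph.BzVolume(sim.grid, np.stack([b[None] for b in bz_pair]), valid)
        lap1 = laplacian_bz(vol, 0, "2d", injection=0)
        lap2 = laplacian_bz(vol, 0, "2d", injection=1)
        A = build_a_matrix(*sim.currents)
        return harmonic_bz_reconstruct(sim.mesh, A, lap1, lap2, sim.grid, **kw)

    def test_homogeneous_phantom_recovers_unit_sigma(self, disk64):
        img = self._reconstruct(disk64, disk64.bz)
        assert np.abs(img.sigma - 1.0).max() < 0.05

    def test_affine_background_field_is_invisible(self, disk64):
        """Adding an affine (harmonic) background to both Bz fields leaves
        the reconstruction unchanged."""
        sim = disk64
        X, Y = sim.grid.meshgrid()
        background = 1e-8 * (1.0 + 3 * X - 2 * Y)
        base = self._reconstruct(sim, sim.bz)
        shifted = self._reconstruct(sim, [b + background for b in sim.bz])
        assert np.abs(base.log_sigma - shifted.log_sigma).max() < 1e-10

    def test_scale_invariance(self, low_contrast64):
        """Scaling both Bz fields and compensating in the A matrix leaves
        the scaled conductivity unchanged (all-linear chain before exp)."""
        sim = low_contrast64
        base = self._reconstruct(sim, sim.bz)
        c = 3.7
        scaled_currents = [
            ph.CurrentDensityField(J.grid, c * J.Jx, c * J.Jy, J.valid)
            for J in sim.currents]
        from scipy.ndimage import binary_erosion
        valid = binary_erosion(sim.valid, iterations=4)
        vol = ph.BzVolume(sim.grid,
                          np.stack([(c * b)[None] for b in sim.bz]), valid)
        lap1 = laplacian_bz(vol, 0, "2d", injection=0)
        lap2 = laplacian_bz(vol, 0, "2d", injection=1)
        A = build_a_matrix(*scaled_currents)
        img = harmonic_bz_reconstruct(sim.mesh, A, lap1, lap2, sim.grid)
        assert np.abs(img.log_sigma - base.log_sigma).max() < 1e-8

    def test_low_contrast_phantom_recovered(self, low_contrast64):
        """ln(sigma1) correlates with ln(sigma_true) and both anomalies get
        the right sign at their centroids."""
        sim = low_contrast64
        img = self._reconstruct(sim, sim.bz)
        ok = np.isfinite(img.raster) & sim.phantom.domain_mask
        r = np.corrcoef(np.log(img.raster[ok]), np.log(sim.phantom.sigma[ok]))[0, 1]
        assert r >= 0.9
        cx, cy = sim.grid.center()
        half = 0.5 * sim.grid.dx * (sim.grid.nx - 1)
        for e in LOW_CONTRAST[1:]:
            ix = int(round((cx + half * e.center[0]) / sim.grid.dx))
            iy = int(round((cy + half * e.center[1]) / sim.grid.dy))
            rec = img.raster[iy, ix]
            assert (rec - 1.0) * (e.value - 1.0) > 0

    def test_neumann_variant_recovers_contrast(self, low_contrast64):
        sim = low_contrast64
        img = self._reconstruct(sim, sim.bz, boundary="neumann")
        ok = np.isfinite(img.raster) & sim.phantom.domain_mask
        r = np.corrcoef(np.log(img.raster[ok]), np.log(sim.phantom.sigma[ok]))[0, 1]
        assert r >= 0.85

    def test_monotone_refinement_on_homogeneous_phantom(self):
        """max |sigma1 - 1| does not increase as the mesh is refined."""
        devs = []
        for max_area_px in (2.0, 1.0, 0.5):
            sim = simulate_case(48, [ph.EllipseSpec((0, 0), (0.85, 0.85), 0, 1.0)],
                                max_area_px=max_area_px)
            img = self._reconstruct(sim, sim.bz)
            devs.append(np.abs(img.sigma - 1.0).max())
        assert devs[2] <= devs[0] + 1e-12

    def test_local_solve_on_homogeneous_region_is_unit(self, disk64):
        sim = disk64
        from scipy.ndimage import binary_erosion
        valid = binary_erosion(sim.valid, iterations=4)
        vol = ph.BzVolume(sim.grid, np.stack([b[None] for b in sim.bz]), valid)
        lap1 = laplacian_bz(vol, 0, "2d", injection=0)
        lap2 = laplacian_bz(vol, 0, "2d", injection=1)
        A = build_a_matrix(*sim.currents)
        cx, cy = sim.grid.center()
        w = 15 * sim.grid.dx
        region = LocalRegion(np.array([[cx - w, cy - w], [cx + w, cy - w],
                                       [cx + w, cy + w], [cx - w, cy + w]]))
        img = local_harmonic_bz(region, A, lap1, lap2, sim.grid)
        ok = np.isfinite(img.raster)
        assert ok.sum() > 100
        assert np.abs(img.raster[ok] - 1.0).max() < 0.05

    def test_local_beats_corrupted_global_restriction(self, low_contrast64):
        """Heavy noise outside D corrupts the global solve everywhere
        (the Poisson problem couples the domain); the local solve on the
        clean subregion D is closer to the truth on D."""
        sim = low_contrast64
        rng = np.random.default_rng(77)
        X, Y = sim.grid.meshgrid()
        cx, cy = sim.grid.center()
        half = 0.5 * sim.grid.dx * (sim.grid.nx - 1)
        # noise patch near the bottom-left boundary, outside D
        patch = ((X - (cx - 0.45 * half)) ** 2
                 + (Y - (cy - 0.45 * half)) ** 2) < (0.25 * half) ** 2
        bz_bad = []
        for b in sim.bz:
            noise = np.where(patch, 0.3 * np.ptp(b) * rng.standard_normal(b.shape), 0)
            bz_bad.append(b + noise)

        w = 0.35 * half
        region = LocalRegion(np.array([[cx - w, cy - w], [cx + w, cy - w],
                                       [cx + w, cy + w], [cx - w, cy + w]]))
        from scipy.ndimage import binary_erosion
        valid = binary_erosion(sim.valid, iterations=4)
        vol = ph.BzVolume(sim.grid, np.stack([b[None] for b in bz_bad]), valid)
        lap1 = laplacian_bz(vol, 0, "2d", injection=0)
        lap2 = laplacian_bz(vol, 0, "2d", injection=1)
        A = build_a_matrix(*sim.currents)
        glob = harmonic_bz_reconstruct(sim.mesh, A, lap1, lap2, sim.grid)
        loc = local_harmonic_bz(region, A, lap1, lap2, sim.grid)

        truth = np.log(sim.phantom.sigma)
        okl = np.isfinite(loc.raster)
        okg = okl & np.isfinite(glob.raster)
        rmse_local = np.sqrt(np.mean((np.log(loc.raster[okg]) - truth[okg]) ** 2))
        rmse_global = np.sqrt(np.mean((np.log(glob.raster[okg]) - truth[okg]) ** 2))
        assert rmse_local < rmse_global
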