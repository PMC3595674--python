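"""Harmonic Bz reconstruction of scaled conductivity.

One-pass algorithm: with the homogeneous initial guess sigma0 = 1 the two
forward potentials give the transverse-current matrix

    A(x) = [[-Jy1, Jx1], [-Jy2, Jx2]],

and the scaled log-conductivity solves the Poisson problem

    lap ln(sigma1) = div( A^{-1} [lap Bz1, lap Bz2] / mu0 )   in the region,
    ln(sigma1) = 0                                            on its boundary,

realized weakly (the divergence source is integrated against test-function
gradients, so the noisy right-hand side is never differentiated again) with
P1 elements and CG.  The same solve restricted to a user polygon D is the
local variant, which isolates D from corrupted data elsewhere.  The output
is contrast-only: multiplying both currents or Bz fields by a common
constant rescales ln(sigma1) but a harmonic (e.g. affine) additive
background in Bz is invisible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import fem
from .errors import QualityError, ValidationError
from .fem import FemSystem, assemble_p1, solve_cg  # re-exported FEM surface
from .geometry import LocalRegion, TriangleMesh, triangulate
from .grids import SliceGrid, bilinear_sample
from .phantom import (MU0, BzVolume, ConductivityPhantom, CurrentDensityField,
                      PotentialField, current_density)
from .phase import ContinuityReport

__all__ = [
    "FemSystem", "assemble_p1", "solve_cg",
    "LaplacianField", "laplacian_bz",
    "AMatrixField", "build_a_matrix",
    "ScaledConductivityImage", "harmonic_bz_reconstruct", "local_harmonic_bz",
]


# ---------------------------------------------------------------------------
# Laplacian of Bz
# ---------------------------------------------------------------------------

@dataclass
class LaplacianField:
    """Grid-sampled Laplacian of Bz for one injection (NaN off-mask)."""

    values: np.ndarray
    valid: np.ndarray
    mode: str
    spacing: tuple[float, float, float]


def laplacian_bz(bz: BzVolume, slice_index: int = 0, mode: str = "2d",
                 injection: int = 0,
                 continuity: ContinuityReport | None = None,
                 force: bool = False) -> LaplacianField:
    """5-point (2d) or 7-point (3d) discrete Laplacian with physical spacing.

    3d mode needs at least 3 slices, an interior slice, and a passing
    z-continuity report (``force=True`` overrides a failing one); when the
    report recommends 2d, adding the cross-slice second difference would
    inject 2-pi jump artifacts into the reconstruction.
    """
    if mode not in ("2d", "3d"):
        raise ValidationError("mode must be '2d' or '3d'")
    g = bz.grid
    vol = bz.bz[injection]
    b = vol[slice_index]
    lap = np.full(g.shape, np.nan)
    lap[1:-1, 1:-1] = ((b[1:-1, 2:] - 2 * b[1:-1, 1:-1] + b[1:-1, :-2]) / g.dx ** 2
                       + (b[2:, 1:-1] - 2 * b[1:-1, 1:-1] + b[:-2, 1:-1]) / g.dy ** 2)
    valid = np.zeros(g.shape, dtype=bool)
    m = bz.valid_mask
    valid[1:-1, 1:-1] = (m[1:-1, 1:-1] & m[1:-1, 2:] & m[1:-1, :-2]
                         & m[2:, 1:-1] & m[:-2, 1:-1])
    if mode == "3d":
        if bz.nz < 3 or not (0 < slice_index < bz.nz - 1):
            raise ValidationError("3d Laplacian needs an interior slice of >= 3")
        if continuity is not None and continuity.recommended_mode != "3d" and not force:
            raise QualityError("z-continuity verification failed; "
                               "use mode='2d' or force=True")
        lap[1:-1, 1:-1] += ((vol[slice_index + 1] - 2 * b
                             + vol[slice_index - 1])[1:-1, 1:-1] / g.dz ** 2)
    lap[~valid] = np.nan
    return LaplacianField(lap, valid, mode, (g.dx, g.dy, g.dz))


# ---------------------------------------------------------------------------
# the matrix field A
# ---------------------------------------------------------------------------

@dataclass
class AMatrixField:
    """Per-pixel 2x2 matrix of transverse sigma0-currents, with reliability."""

    a11: np.ndarray
    a12: np.ndarray
    a21: np.ndarray
    a22: np.ndarray
    det: np.ndarray
    reliable: np.ndarray
    valid: np.ndarray


def build_a_matrix(J1: CurrentDensityField, J2: CurrentDensityField,
                   det_threshold: float = 1e-3) -> AMatrixField:
    """Rows (-Jy1, Jx1) and (-Jy2, Jx2) from the two sigma0 = 1 forward
    solves; points with |det| below ``det_threshold`` times the median |det|
    are flagged unreliable (near-parallel currents there)."""
    valid = J1.valid & J2.valid
    a11, a12 = -J1.Jy, J1.Jx
    a21, a22 = -J2.Jy, J2.Jx
    det = a11 * a22 - a12 * a21
    med = float(np.median(np.abs(det[valid]))) if np.any(valid) else 0.0
    if med > 0:
        reliable = valid & (np.abs(det) >= det_threshold * med)
    else:
        reliable = np.zeros_like(valid)   # rank-deficient everywhere
    n_valid = int(valid.sum())
    if n_valid and (n_valid - int(reliable.sum())) > 0.2 * n_valid:
        warnings.warn("more than 20% of points have near-singular current "
                      "matrices; reconstruction may be unreliable", stacklevel=2)
    return AMatrixField(a11, a12, a21, a22, det, reliable, valid)


# ---------------------------------------------------------------------------
# the Poisson solve
# ---------------------------------------------------------------------------

@dataclass
class ScaledConductivityImage:
    """Scaled conductivity on mesh vertices and rasterized to pixels.

    ``sigma`` is exp(log_sigma): positive everywhere, equal to 1 on the
    Dirichlet boundary of its region, and determined only up to the global
    scale that the boundary condition pins down.
    """

    mesh: TriangleMesh
    log_sigma: np.ndarray
    sigma: np.ndarray
    raster: np.ndarray
    region: str | LocalRegion = "global"
    excluded_points: int = 0
    residual: float = 0.0


def _rhs_field(a_field: AMatrixField, lap1: LaplacianField, lap2: LaplacianField,
               mu0_scaling: bool) -> tuple[np.ndarray, np.ndarray, int]:
    """Pixel field F = A^{-1} [lap Bz1, lap Bz2] (0 where unreliable)."""
    ok = a_field.reliable & lap1.valid & lap2.valid
    l1 = np.where(ok, np.nan_to_num(lap1.values), 0.0)
    l2 = np.where(ok, np.nan_to_num(lap2.values), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_det = np.where(ok, 1.0 / np.where(ok, a_field.det, 1.0), 0.0)
    fx = inv_det * (a_field.a22 * l1 - a_field.a12 * l2)
    fy = inv_det * (-a_field.a21 * l1 + a_field.a11 * l2)
    if mu0_scaling:
        fx = fx / MU0
        fy = fy / MU0
    excluded = int(np.sum((lap1.valid & lap2.valid) & ~a_field.reliable))
    fx = np.where(ok, fx, 0.0)
    fy = np.where(ok, fy, 0.0)
    return fx, fy, excluded


def harmonic_bz_reconstruct(mesh: TriangleMesh, a_field: AMatrixField,
                            lap1: LaplacianField, lap2: LaplacianField,
                            grid: SliceGrid,
                            mu0_scaling: bool = True,
                            boundary: str = "dirichlet",
                            tol: float = 1e-10,
                            region: str | LocalRegion = "global"
                            ) -> ScaledConductivityImage:
    """Weak-form Poisson solve for ln(sigma1) on the given mesh.

    ``boundary='dirichlet'`` imposes sigma1 = 1 on the region boundary (the
    default); ``'neumann'`` uses the natural flux condition of the identity
    with the mean of ln(sigma1) pinned to zero instead.
    """
    if boundary not in ("dirichlet", "neumann"):
        raise ValidationError("boundary must be 'dirichlet' or 'neumann'")
    fx, fy, excluded = _rhs_field(a_field, lap1, lap2, mu0_scaling)
    if not np.any(a_field.reliable & lap1.valid & lap2.valid):
        raise ValidationError("no reliable points for the right-hand side")
    cent = mesh.vertices[mesh.triangles].mean(axis=1)
    F = np.stack([bilinear_sample(fx, grid, cent, fill=0.0),
                  bilinear_sample(fy, grid, cent, fill=0.0)], axis=-1)
    system = assemble_p1(mesh, 1.0)
    system.load = fem.divergence_load(mesh, F)
    if boundary == "dirichlet":
        system.constraints = [(int(i), 0.0) for i in mesh.boundary_vertices()]
        log_sigma = solve_cg(system, tol=tol)
    else:
        # natural BC: fix one vertex, then remove the mean
        system.constraints = [(0, 0.0)]
        log_sigma = solve_cg(system, tol=tol)
        log_sigma = log_sigma - log_sigma.mean()
    resid = float(np.linalg.norm(system.stiffness @ log_sigma - system.load))
    raster = mesh.rasterize_vertex_values(log_sigma, grid)
    return ScaledConductivityImage(mesh, log_sigma, np.exp(log_sigma),
                                   np.exp(raster), region=region,
                                   excluded_points=excluded, residual=resid)


def local_harmonic_bz(region: LocalRegion, a_field: AMatrixField,
                      lap1: LaplacianField, lap2: LaplacianField,
                      grid: SliceGrid, max_area: float | None = None,
                      defect_mask: np.ndarray | None = None,
                      **kwargs) -> ScaledConductivityImage:
    """Local variant: mesh the polygon D and solve with ln(sigma1) = 0 on
    its boundary, isolating D from data outside it."""
    if defect_mask is not None and np.any(defect_mask):
        from matplotlib.path import Path

        X, Y = grid.meshgrid()
        pts = np.stack([X.ravel(), Y.ravel()], axis=-1)
        inside = Path(region.polygon).contains_points(pts).reshape(grid.shape)
        if np.any(inside & defect_mask):
            warnings.warn("local region overlaps the defected region",
                          stacklevel=2)
    if max_area is None:
        max_area = 0.5 * grid.dx * grid.dy
    from .geometry import DomainPolygon
    mesh = triangulate(DomainPolygon(region.polygon), max_area)
    return harmonic_bz_reconstruct(mesh, a_field, lap1, lap2, grid,
                                   region=region, **kwargs)
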