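"""Synthetic MREIT experiment generator.

This module is the forward half of the physics: conductivity phantoms on a
pixel grid, the simplified 2D forward potential solve with +/-1 Dirichlet
electrodes, current density J = -sigma grad u, the Biot-Savart magnetic
flux density Bz, and the complex MR image / k-space synthesis

    M+ = M exp(i delta) exp(+i gamma Bz Tc)
    M- = M exp(i delta) exp(-i gamma Bz Tc)

with circular complex Gaussian noise.  The current of one injection is
modelled as z-invariant (the slice's conductivity extruded along z), which
is the regime in which the in-plane Laplacian of Bz carries the
conductivity-contrast information the reconstruction uses; a finite
extrusion thickness is available through ``extrusion_slices``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from . import fem
from .errors import ValidationError
from .geometry import DomainPolygon, ElectrodeArcSpec, TriangleMesh, attach_electrodes
from .grids import SliceGrid, bilinear_sample

#: Gyromagnetic ratio of hydrogen, rad / (T s).
GAMMA_HYDROGEN = 26.75e7
#: Vacuum permeability, T m / A.
MU0 = 4e-7 * np.pi


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipseSpec:
    """One ellipse in normalized slice coordinates.

    ``center`` and ``axes`` are given in units of the grid half-extent, i.e.
    the frame spans [-1, 1] in the larger dimension; ``angle`` is the CCW
    rotation in radians; ``value`` the conductivity in S/m.
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    angle: float
    value: float


def default_shepp_logan_ellipses() -> list[EllipseSpec]:
    """Modified Shepp-Logan layout with conductivity-valued contrasts.

    The geometry is the classic head-phantom ellipse set; intensities are
    replaced by positive conductivities with the outer rim at the background
    value of 1 S/m, as the reconstruction's homogeneous-boundary assumption
    requires.
    """
    d = np.deg2rad(18.0)
    return [
        EllipseSpec((0.0, 0.0), (0.69, 0.92), 0.0, 1.0),          # outer rim
        EllipseSpec((0.0, -0.0184), (0.64, 0.85), 0.0, 1.2),      # brain
        EllipseSpec((0.22, 0.0), (0.11, 0.31), -d, 0.7),
        EllipseSpec((-0.22, 0.0), (0.16, 0.41), d, 0.7),
        EllipseSpec((0.0, 0.35), (0.21, 0.25), 0.0, 1.5),
        EllipseSpec((0.0, 0.1), (0.046, 0.046), 0.0, 2.0),
        EllipseSpec((0.0, -0.1), (0.046, 0.046), 0.0, 2.0),
        EllipseSpec((-0.08, -0.605), (0.046, 0.023), 0.0, 1.5),
        EllipseSpec((0.0, -0.605), (0.023, 0.023), 0.0, 1.5),
        EllipseSpec((0.06, -0.605), (0.023, 0.046), 0.0, 1.5),
    ]


@dataclass
class ConductivityPhantom:
    """Ground-truth conductivity map sigma (S/m) on a slice grid."""

    grid: SliceGrid
    sigma: np.ndarray
    domain_mask: np.ndarray
    outer_ellipse: EllipseSpec | None = None

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.domain_mask = np.asarray(self.domain_mask, dtype=bool)
        if self.sigma.shape != self.grid.shape or self.domain_mask.shape != self.grid.shape:
            raise ValidationError("sigma/domain_mask shape must match the grid")
        if np.any(self.sigma[self.domain_mask] <= 0):
            raise ValidationError("conductivity must be positive inside the domain")
        ring = self.domain_mask & ~binary_erosion_4(self.domain_mask)
        ring_vals = self.sigma[ring]
        if ring_vals.size and np.ptp(ring_vals) > 1e-12 * max(1.0, ring_vals.max()):
            warnings.warn("conductivity is not constant on the domain boundary ring; "
                          "the reconstruction assumes a homogeneous boundary",
                          stacklevel=2)


def binary_erosion_4(mask: np.ndarray) -> np.ndarray:
    """4-neighborhood binary erosion (treating outside as False)."""
    from scipy.ndimage import binary_erosion
    return binary_erosion(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))


def _norm_coords(grid: SliceGrid):
    """Pixel centers in normalized [-1, 1] coordinates (larger dim spans 2)."""
    X, Y = grid.meshgrid()
    cx, cy = grid.center()
    half = 0.5 * max(grid.dx * (grid.nx - 1), grid.dy * (grid.ny - 1))
    return (X - cx) / half, (Y - cy) / half


def _ellipse_membership(xn, yn, e: EllipseSpec):
    ct, st = np.cos(e.angle), np.sin(e.angle)
    u = ct * (xn - e.center[0]) + st * (yn - e.center[1])
    v = -st * (xn - e.center[0]) + ct * (yn - e.center[1])
    return (u / e.axes[0]) ** 2 + (v / e.axes[1]) ** 2 <= 1.0


def make_shepp_logan(grid: SliceGrid,
                     ellipses: list[EllipseSpec] | None = None) -> ConductivityPhantom:
    """Build a conductivity phantom from a list of ellipses.

    The first ellipse defines the imaging domain Omega_z; the background
    conductivity inside it is 1 S/m, later ellipses overwrite earlier ones.
    """
    if ellipses is None:
        ellipses = default_shepp_logan_ellipses()
    if not ellipses:
        raise ValidationError("need at least the outer ellipse")
    for e in ellipses:
        if e.value <= 0:
            raise ValidationError(f"conductivity must be positive, got {e.value}")
        if min(e.axes) <= 0:
            raise ValidationError("ellipse axes must be positive")
    outer = ellipses[0]
    if (abs(outer.center[0]) + outer.axes[0] > 1.0 + 1e-9
            or abs(outer.center[1]) + outer.axes[1] > 1.0 + 1e-9):
        raise ValidationError("outer ellipse exceeds the grid frame")
    xn, yn = _norm_coords(grid)
    domain = _ellipse_membership(xn, yn, outer)
    sigma = np.ones(grid.shape)
    for e in ellipses[1:]:
        inside = _ellipse_membership(xn, yn, e)
        if np.any(inside & ~domain):
            raise ValidationError("interior ellipse extends outside the outer ellipse")
        sigma[inside] = e.value
    return ConductivityPhantom(grid, sigma, domain, outer_ellipse=outer)


def domain_polygon(phantom: ConductivityPhantom, n_vertices: int = 180) -> DomainPolygon:
    """Analytic boundary polygon of the phantom's outer ellipse."""
    if phantom.outer_ellipse is None:
        raise ValidationError("phantom has no analytic outer ellipse; "
                              "use geometry.segment_domain on a magnitude image")
    e = phantom.outer_ellipse
    g = phantom.grid
    cx, cy = g.center()
    half = 0.5 * max(g.dx * (g.nx - 1), g.dy * (g.ny - 1))
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    u = e.axes[0] * np.cos(t)
    v = e.axes[1] * np.sin(t)
    ct, st = np.cos(e.angle), np.sin(e.angle)
    xs = cx + half * (e.center[0] + ct * u - st * v)
    ys = cy + half * (e.center[1] + st * u + ct * v)
    return DomainPolygon(np.column_stack([xs, ys]))


# ---------------------------------------------------------------------------
# electrodes
# ---------------------------------------------------------------------------

@dataclass
class ElectrodeConfig:
    """Two electrode pairs, injected current amplitude and pulse width.

    ``arcs`` lists four :class:`ElectrodeArcSpec` entries, one per
    (injection, polarity).  The two injection directions must not be
    parallel; the default layout is a horizontal pair (injection 1) and a
    vertical pair (injection 2).
    """

    arcs: list[ElectrodeArcSpec]
    current: float = 1e-3          # amperes
    pulse_width: float = 30e-3     # Tc, seconds

    def __post_init__(self):
        keys = {(a.injection, a.polarity) for a in self.arcs}
        expected = {(1, "+"), (1, "-"), (2, "+"), (2, "-")}
        if keys != expected:
            raise ValidationError(f"need exactly the four arcs {sorted(expected)}")
        if self.current <= 0 or self.pulse_width <= 0:
            raise ValidationError("current and pulse width must be positive")


def default_electrodes(poly: DomainPolygon, arc_fraction: float = 0.10,
                       current: float = 1e-3,
                       pulse_width: float = 30e-3) -> ElectrodeConfig:
    """Horizontal + vertical electrode pairs sized as a perimeter fraction."""
    length = arc_fraction * float(poly.perimeter_params()[-1])
    arcs = [
        ElectrodeArcSpec(1, "+", 0.0, length),
        ElectrodeArcSpec(1, "-", np.pi, length),
        ElectrodeArcSpec(2, "+", np.pi / 2, length),
        ElectrodeArcSpec(2, "-", -np.pi / 2, length),
    ]
    return ElectrodeConfig(arcs, current=current, pulse_width=pulse_width)


def electrode_polygon(phantom: ConductivityPhantom, electrodes: ElectrodeConfig,
                      n_vertices: int = 180) -> DomainPolygon:
    """Domain polygon with the electrode arcs attached."""
    return attach_electrodes(domain_polygon(phantom, n_vertices), electrodes.arcs)


# ---------------------------------------------------------------------------
# forward solve and current density
# ---------------------------------------------------------------------------

@dataclass
class PotentialField:
    """Dimensionless forward potential with +/-1 Dirichlet electrode data."""

    mesh: TriangleMesh
    u: np.ndarray
    injection_index: int
    element_sigma: np.ndarray | None = None


def element_conductivity(phantom: ConductivityPhantom, mesh: TriangleMesh) -> np.ndarray:
    """Conductivity sampled at element centroids (background 1 outside data)."""
    cent = mesh.vertices[mesh.triangles].mean(axis=1)
    sig = bilinear_sample(phantom.sigma, phantom.grid, cent, fill=1.0)
    return np.clip(sig, 1e-12, None)


def solve_forward_2d(phantom: ConductivityPhantom, electrodes: ElectrodeConfig,
                     injection: int, mesh: TriangleMesh,
                     tol: float = 1e-12) -> PotentialField:
    """Solve the simplified slice problem div(sigma grad u) = 0 with u = +1 on
    the positive electrode arc, -1 on the negative one, and zero Neumann flux
    elsewhere."""
    sig = element_conductivity(phantom, mesh)
    system = fem.assemble_p1(mesh, sig)
    vp = mesh.electrode_vertices(injection, "+")
    vm = mesh.electrode_vertices(injection, "-")
    if len(vp) == 0 or len(vm) == 0:
        raise ValidationError(
            f"mesh has no electrode markers for injection {injection}")
    system.constraints = [(int(i), 1.0) for i in vp] + [(int(i), -1.0) for i in vm]
    u = fem.solve_cg(system, tol=tol)
    return PotentialField(mesh, u, injection, element_sigma=sig)


def electrode_flux(potential: PotentialField, polarity: str = "+") -> float:
    """Discrete current flux through one electrode arc (stiffness residual)."""
    system = fem.assemble_p1(potential.mesh, potential.element_sigma)
    r = system.stiffness @ potential.u
    verts = potential.mesh.electrode_vertices(potential.injection_index, polarity)
    return float(np.sum(r[verts]))


@dataclass
class CurrentDensityField:
    """In-plane current density rasterized to pixel centers."""

    grid: SliceGrid
    Jx: np.ndarray
    Jy: np.ndarray
    valid: np.ndarray


def current_density(phantom: ConductivityPhantom, potential: PotentialField,
                    subsamples: int = 2) -> CurrentDensityField:
    """Current density J = -sigma grad u rasterized to pixel centers.

    Element-wise constant gradients are area-weighted averaged onto mesh
    vertices (recovering one order of accuracy) and the resulting piecewise
    linear field is pixel-averaged over a ``subsamples x subsamples``
    midpoint rule per pixel, which suppresses element-scale aliasing in the
    downstream Laplacian.  Pixels not fully covered by the mesh are marked
    invalid rather than extrapolated.
    """
    mesh = potential.mesh
    grads, areas = fem.element_gradients(mesh)
    grad_u = np.einsum("eid,ei->ed", grads, potential.u[mesh.triangles])
    sig = (potential.element_sigma if potential.element_sigma is not None
           else element_conductivity(phantom, mesh))
    J_elem = -sig[:, None] * grad_u
    # area-weighted average onto vertices
    wsum = np.zeros(len(mesh.vertices))
    Jv = np.zeros((len(mesh.vertices), 2))
    np.add.at(wsum, mesh.triangles.ravel(), np.repeat(areas, 3))
    np.add.at(Jv, mesh.triangles.ravel(),
              np.repeat(J_elem[:, None, :], 3, axis=1).reshape(-1, 2)
              * np.repeat(areas, 3)[:, None])
    Jv /= np.maximum(wsum, 1e-300)[:, None]
    g = phantom.grid
    ss = max(1, int(subsamples))
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    acc_x = np.zeros(g.shape)
    acc_y = np.zeros(g.shape)
    acc_m = np.zeros(g.shape, dtype=int)
    for oy in offs:
        for ox in offs:
            shifted = SliceGrid(g.nx, g.ny, g.dx, g.dy, g.dz,
                                (g.origin[0] + ox * g.dx, g.origin[1] + oy * g.dy))
            jx = mesh.rasterize_vertex_values(Jv[:, 0], shifted)
            jy = mesh.rasterize_vertex_values(Jv[:, 1], shifted)
            ok = np.isfinite(jx) & np.isfinite(jy)
            acc_x += np.nan_to_num(jx)
            acc_y += np.nan_to_num(jy)
            acc_m += ok
    covered = acc_m == ss * ss
    Jx = np.where(covered, acc_x / (ss * ss), np.nan)
    Jy = np.where(covered, acc_y / (ss * ss), np.nan)
    return CurrentDensityField(g, Jx, Jy, covered)


# ---------------------------------------------------------------------------
# Biot-Savart
# ---------------------------------------------------------------------------

def _bz_kernel(grid: SliceGrid, extrusion_slices: int | None):
    """Displacement kernels K_x, K_y on the (2ny-1, 2nx-1) offset grid.

    Bz(t) = (mu0 / 4 pi) * sum_s [Jx(s) Ky(t-s) - Jy(s) Kx(t-s)] dx dy with
    K_d(delta) = delta_d * k(rho), where k integrates the 3D Biot-Savart
    kernel across the extruded source thickness.  ``extrusion_slices=None``
    is the infinite-extrusion (2D magnetostatics) limit k = 2 / rho^2.
    """
    dx_off = grid.dx * np.arange(-(grid.nx - 1), grid.nx)
    dy_off = grid.dy * np.arange(-(grid.ny - 1), grid.ny)
    DX, DY = np.meshgrid(dx_off, dy_off)

    def radial(rho2):
        if extrusion_slices is None:
            return 2.0 / rho2
        t = extrusion_slices * grid.dz
        return t / (rho2 * np.sqrt(rho2 + 0.25 * t * t))

    with np.errstate(divide="ignore", invalid="ignore"):
        rho2 = DX ** 2 + DY ** 2
        k = radial(rho2)
        KX = DX * k
        KY = DY * k
    # singular self-pixel: 4x4 sub-pixel midpoint quadrature (the midpoints
    # avoid the singular point; by oddness of the kernel the result is 0,
    # computed explicitly for the documented rule)
    sub = (np.arange(4) + 0.5) / 4 - 0.5
    sx, sy = np.meshgrid(sub * grid.dx, sub * grid.dy)
    r2 = sx ** 2 + sy ** 2
    kc = radial(r2)
    cy, cx = grid.ny - 1, grid.nx - 1
    KX[cy, cx] = float(np.mean(sx * kc))
    KY[cy, cx] = float(np.mean(sy * kc))
    return KX, KY


def biot_savart_bz(J: CurrentDensityField, grid: SliceGrid | None = None,
                   extrusion_slices: int | None = None,
                   background: np.ndarray | None = None) -> np.ndarray:
    """z-component of the magnetic flux density from an in-plane current sheet.

    Evaluates the Biot-Savart integral at all pixel centers of the slice;
    invalid source pixels contribute nothing.  ``background`` adds an
    optional harmonic term (e.g. fields from leads) after the integral.
    """
    if grid is None:
        grid = J.grid
    if grid.nx == 0 or grid.ny == 0:
        raise ValidationError("empty evaluation grid")
    Jx = np.where(J.valid, J.Jx, 0.0)
    Jy = np.where(J.valid, J.Jy, 0.0)
    KX, KY = _bz_kernel(grid, extrusion_slices)
    scale = MU0 / (4 * np.pi) * grid.dx * grid.dy
    bz = scale * (fftconvolve(KY, Jx, mode="valid")
                  - fftconvolve(KX, Jy, mode="valid"))
    if background is not None:
        bz = bz + background
    return bz


@dataclass
class BzVolume:
    """Per-slice, per-injection z-component magnetic flux density (Tesla)."""

    grid: SliceGrid
    bz: np.ndarray              # (n_injections, nz, ny, nx)
    valid_mask: np.ndarray      # (ny, nx)

    def __post_init__(self):
        self.bz = np.asarray(self.bz, dtype=float)
        if self.bz.ndim == 3:
            self.bz = self.bz[:, None]
        if not np.all(np.isfinite(self.bz[:, :, self.valid_mask])):
            raise ValidationError("Bz must be finite on the valid mask")

    @property
    def nz(self) -> int:
        return self.bz.shape[1]


# ---------------------------------------------------------------------------
# MR signal synthesis
# ---------------------------------------------------------------------------

@dataclass
class ComplexImagePair:
    """Complex MR images for one slice and one injection, both polarities."""

    m_plus: np.ndarray
    m_minus: np.ndarray
    magnitude: np.ndarray
    phase_artifact: np.ndarray
    Tc: float
    gamma: float = GAMMA_HYDROGEN


def synthesize_complex_pair(M: np.ndarray, delta: np.ndarray, bz_slice: np.ndarray,
                            Tc: float, gamma: float = GAMMA_HYDROGEN,
                            noise_sd: float = 0.0,
                            rng: np.random.Generator | int | None = None
                            ) -> ComplexImagePair:
    """Complex image pair M exp(i delta) exp(+/- i gamma Bz Tc) with optional
    circular complex Gaussian noise (reproducible from ``rng``)."""
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValidationError("magnitude image must be nonnegative")
    if Tc <= 0 or gamma <= 0:
        raise ValidationError("Tc and gamma must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    delta = np.broadcast_to(np.asarray(delta, dtype=float), M.shape)
    phase = gamma * np.asarray(bz_slice, dtype=float) * Tc
    base = M * np.exp(1j * delta)
    m_plus = base * np.exp(1j * phase)
    m_minus = base * np.exp(-1j * phase)
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        m_plus = m_plus + noise_sd * (gen.standard_normal(M.shape)
                                      + 1j * gen.standard_normal(M.shape))
        m_minus = m_minus + noise_sd * (gen.standard_normal(M.shape)
                                        + 1j * gen.standard_normal(M.shape))
    return ComplexImagePair(m_plus, m_minus, M, np.array(delta), Tc, gamma)


#: k-space storage convention used by the whole package: DC-centered
#: ("fftshift" layout), unnormalized forward DFT, 1/(nx*ny) inverse.
KSPACE_CONVENTION = "dc_centered_unnormalized_forward"


@dataclass
class KSpaceData:
    """DC-centered complex k-space arrays for one slice and one injection."""

    s_plus: np.ndarray
    s_minus: np.ndarray
    dkx: float
    dky: float
    convention: str = KSPACE_CONVENTION


def synthesize_kspace(pair: ComplexImagePair, grid: SliceGrid) -> KSpaceData:
    """Forward 2D DFT of both complex images (DC-centered storage)."""
    for arr in (pair.m_plus, pair.m_minus):
        if not np.all(np.isfinite(arr)):
            raise ValidationError("complex image contains NaN/inf")
    s_plus = np.fft.fftshift(np.fft.fft2(pair.m_plus))
    s_minus = np.fft.fftshift(np.fft.fft2(pair.m_minus))
    return KSpaceData(s_plus, s_minus,
                      dkx=1.0 / (grid.nx * grid.dx), dky=1.0 / (grid.ny * grid.dy))
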