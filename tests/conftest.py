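"""Shared fixtures: analytic square setups and cached phantom simulations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from mreit import phantom as ph
from mreit.geometry import DomainPolygon, TriangleMesh, triangulate
from mreit.grids import SliceGrid


@dataclass
class SquareSetup:
    """Unit-square domain with full opposite-edge electrodes (P1-exact case)."""

    grid: SliceGrid
    L: float
    poly: DomainPolygon
    mesh: TriangleMesh
    phantom: ph.ConductivityPhantom
    electrodes: ph.ElectrodeConfig


def make_square_setup(n: int = 32, swap_injection1: bool = False) -> SquareSetup:
    grid = SliceGrid(n, n, 1e-3, 1e-3, 1e-3)
    L = (n - 1) * grid.dx
    arcs = {(1, "+"): (1, 2), (1, "-"): (3, 0),
            (2, "+"): (2, 3), (2, "-"): (0, 1)}
    if swap_injection1:
        arcs[(1, "+")], arcs[(1, "-")] = arcs[(1, "-")], arcs[(1, "+")]
    poly = DomainPolygon(np.array([[0, 0], [L, 0], [L, L], [0, L]], float),
                         electrode_arcs=arcs)
    mesh = triangulate(poly, 0.5 * grid.dx * grid.dy)
    phantom = ph.ConductivityPhantom(grid, np.ones(grid.shape),
                                     np.ones(grid.shape, bool))
    electrodes = ph.default_electrodes(poly)
    return SquareSetup(grid, L, poly, mesh, phantom, electrodes)


@pytest.fixture(scope="session")
def square():
    return make_square_setup()


@dataclass
class SimCase:
    """One fully simulated phantom: forward solves, currents, Bz fields."""

    grid: SliceGrid
    phantom: ph.ConductivityPhantom
    poly: DomainPolygon
    electrodes: ph.ElectrodeConfig
    mesh: TriangleMesh
    potentials: list[ph.PotentialField]
    currents: list[ph.CurrentDensityField]
    bz: list[np.ndarray]
    valid: np.ndarray


def simulate_case(n: int, ellipses, dx: float = 2e-3,
                  max_area_px: float = 0.5) -> SimCase:
    grid = SliceGrid(n, n, dx, dx, dx)
    phantom = ph.make_shepp_logan(grid, ellipses)
    poly0 = ph.domain_polygon(phantom)
    electrodes = ph.default_electrodes(poly0)
    poly = ph.electrode_polygon(phantom, electrodes)
    mesh = triangulate(poly, max_area_px * grid.dx * grid.dy)
    pots = [ph.solve_forward_2d(phantom, electrodes, j, mesh) for j in (1, 2)]
    currents = [ph.current_density(phantom, p) for p in pots]
    bz = [ph.biot_savart_bz(J) for J in currents]
    valid = currents[0].valid & currents[1].valid & phantom.domain_mask
    return SimCase(grid, phantom, poly, electrodes, mesh, pots, currents, bz, valid)


HOMOGENEOUS_DISK = [ph.EllipseSpec((0, 0), (0.85, 0.85), 0.0, 1.0)]
LOW_CONTRAST = [
    ph.EllipseSpec((0, 0), (0.85, 0.85), 0.0, 1.0),
    ph.EllipseSpec((-0.3, 0.15), (0.28, 0.2), 0.2, 0.8),
    ph.EllipseSpec((0.3, -0.25), (0.2, 0.26), 0.0, 1.2),
]


@pytest.fixture(scope="session")
def disk64():
    """Homogeneous disk, 64x64."""
    return simulate_case(64, HOMOGENEOUS_DISK)


@pytest.fixture(scope="session")
def low_contrast64():
    """Two-anomaly low-contrast phantom (sigma in {0.8, 1, 1.2}), 64x64."""
    return simulate_case(64, LOW_CONTRAST)


@pytest.fixture(scope="session")
def disk128():
    """Homogeneous disk, 128x128 (used by the recovery checks)."""
    return simulate_case(128, HOMOGENEOUS_DISK)


@pytest.fixture(scope="session")
def low_contrast128():
    return simulate_case(128, LOW_CONTRAST)


@pytest.fixture(scope="session")
def shepp_logan64():
    """Default modified Shepp-Logan conductivity phantom simulation."""
    return simulate_case(64, None)


@pytest.fixture(scope="session")
def shepp_logan128():
    return simulate_case(128, None)
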