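"""P1 (piecewise-linear) finite elements on triangle meshes.

Both the forward conductivity solve and the inverse Poisson solve use the
standard P1 stiffness matrix with an element-wise constant coefficient and
a preconditioned conjugate-gradient solver.  Dirichlet constraints are
applied by reduction to the free degrees of freedom, which preserves
symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from .errors import SolverError, ValidationError
from .geometry import TriangleMesh


@dataclass
class FemSystem:
    """Assembled sparse P1 system with optional Dirichlet constraints."""

    mesh: TriangleMesh
    stiffness: sparse.csr_matrix
    load: np.ndarray
    constraints: list[tuple[int, float]] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return len(self.mesh.vertices)


def element_gradients(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-element shape-function gradients.

    Returns ``(grads, areas)`` where ``grads`` has shape (nt, 3, 2):
    ``grads[e, i]`` is the constant gradient of the hat function of local
    vertex i on element e.
    """
    v = mesh.vertices
    t = mesh.triangles
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    det = ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
           - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))
    areas = 0.5 * det
    # grad of hat_i = rot90(opposite edge) / (2A)
    grads = np.empty((len(t), 3, 2))
    grads[:, 0, 0] = (b[:, 1] - c[:, 1]) / det
    grads[:, 0, 1] = (c[:, 0] - b[:, 0]) / det
    grads[:, 1, 0] = (c[:, 1] - a[:, 1]) / det
    grads[:, 1, 1] = (a[:, 0] - c[:, 0]) / det
    grads[:, 2, 0] = (a[:, 1] - b[:, 1]) / det
    grads[:, 2, 1] = (b[:, 0] - a[:, 0]) / det
    return grads, areas


def assemble_p1(mesh: TriangleMesh, coefficient: np.ndarray | float = 1.0) -> FemSystem:
    """Assemble the P1 stiffness matrix with element-wise constant coefficient.

    ``coefficient`` is a scalar or an array of one positive value per element.
    The load vector is initialized to zero.
    """
    nt = len(mesh.triangles)
    coeff = np.broadcast_to(np.asarray(coefficient, dtype=float), (nt,))
    if np.any(coeff <= 0):
        raise ValidationError("element coefficients must be positive")
    grads, areas = element_gradients(mesh)
    if np.any(areas <= 0):
        raise ValidationError("mesh has non-positive element areas")
    # local 3x3 blocks: coeff * A * grad_i . grad_j
    local = np.einsum("e,e,eid,ejd->eij", coeff, areas, grads, grads)
    t = mesh.triangles
    rows = np.repeat(t, 3, axis=1).ravel()           # i index
    cols = np.tile(t, (1, 3)).ravel()                # j index
    K = sparse.coo_matrix((local.ravel(), (rows, cols)),
                          shape=(len(mesh.vertices),) * 2).tocsr()
    return FemSystem(mesh, K, np.zeros(len(mesh.vertices)))


def divergence_load(mesh: TriangleMesh, flux_per_element: np.ndarray) -> np.ndarray:
    """Weak-form load for a divergence source ``div F``.

    For the problem ``lap u = div F`` the weak form reads
    ``int grad u . grad phi = int F . grad phi``; this returns the right-hand
    side vector for an element-wise constant ``F`` of shape (nt, 2).
    """
    grads, areas = element_gradients(mesh)
    contrib = np.einsum("e,eid,ed->ei", areas, grads, flux_per_element)
    b = np.zeros(len(mesh.vertices))
    np.add.at(b, mesh.triangles.ravel(), contrib.ravel())
    return b


def solve_cg(system: FemSystem, tol: float = 1e-8) -> np.ndarray:
    """Solve the constrained system by Jacobi-preconditioned CG.

    Dirichlet constraints are eliminated symmetrically; the returned vector
    carries the constraint values exactly.  Raises :class:`SolverError` with
    the residual if CG does not reach ``tol`` within ``10 * n`` iterations.
    """
    n = system.n_vertices
    K = system.stiffness
    b = system.load.copy()
    u = np.zeros(n)
    if system.constraints:
        c_idx = np.array([i for i, _ in system.constraints], dtype=int)
        c_val = np.array([v for _, v in system.constraints])
        u[c_idx] = c_val
        free = np.setdiff1d(np.arange(n), c_idx)
        if len(free) == 0:
            return u
        b_f = b[free] - K[free][:, c_idx] @ c_val
        K_ff = K[free][:, free]
    else:
        free = np.arange(n)
        b_f = b
        K_ff = K

    diag = K_ff.diagonal()
    diag[diag <= 0] = 1.0
    M = sparse.diags(1.0 / diag)
    maxiter = max(200, 10 * n)
    x, info = cg(K_ff, b_f, rtol=tol, atol=0.0, maxiter=maxiter, M=M)
    resid = float(np.linalg.norm(K_ff @ x - b_f))
    bnorm = float(np.linalg.norm(b_f))
    if info != 0 and resid > tol * max(bnorm, 1e-300):
        raise SolverError(
            f"CG did not converge in {maxiter} iterations "
            f"(relative residual {resid / max(bnorm, 1e-300):.3e})",
            residual=resid)
    u[free] = x
    return u
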