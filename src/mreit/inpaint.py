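"""Detection and repair of MR signal-void ("defected") regions.

Where the MR magnitude is near zero the phase -- and hence Bz -- is
dominated by amplified noise.  Pixels below 10% of the maximum magnitude
are flagged automatically, Bz there is replaced by the solution of the
discrete Laplace equation with Dirichlet data from the surrounding valid
rim (the defected tissue is assumed conductivity-homogeneous, so
lap Bz = 0 there), and a short isotropic diffusion smooths the seam.
The whole repair is a pure function of (M, Bz, fraction): no interactive
input, hence no user dependence in the reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg, spsolve

from .denoise import _flux_step
from .errors import SolverError, ValidationError

__all__ = [
    "DefectMask",
    "detect_defected_region",
    "harmonic_inpaint",
    "isotropic_smooth_defect",
]


@dataclass
class DefectMask:
    """Boolean defect mask with the threshold that produced it."""

    mask: np.ndarray
    threshold_used: float
    fraction: float = 0.10


def detect_defected_region(M: np.ndarray, domain_mask: np.ndarray,
                           fraction: float = 0.10) -> DefectMask:
    """Threshold the MR magnitude at ``fraction`` of its in-domain maximum.

    Components touching the domain boundary are retained (voids can abut
    it).  Warns when more than half the domain is defected; a fully
    defected domain is an error.
    """
    M = np.asarray(M, dtype=float)
    domain_mask = np.asarray(domain_mask, dtype=bool)
    if np.any(M < 0):
        raise ValidationError("magnitude image must be nonnegative")
    if not np.any(domain_mask):
        raise ValidationError("empty domain mask")
    m_max = float(M[domain_mask].max())
    if m_max == 0:
        raise ValidationError("entire domain is defected (zero magnitude)")
    threshold = fraction * m_max
    mask = domain_mask & (M < threshold)
    frac_cover = mask.sum() / domain_mask.sum()
    if frac_cover >= 1.0:
        raise ValidationError("entire domain is defected")
    if frac_cover > 0.5:
        warnings.warn(
            f"defected region covers {frac_cover:.0%} of the domain; "
            "reconstruction reliability is reduced", stacklevel=2)
    return DefectMask(mask, threshold, fraction)


def _laplace_system(mask: np.ndarray, valid: np.ndarray, data: np.ndarray):
    """5-point Laplace system for unknowns on `mask` with Dirichlet data on
    `valid` neighbors; neighbors outside both are treated as no-flux."""
    idx = -np.ones(mask.shape, dtype=int)
    unknowns = np.argwhere(mask)
    idx[mask] = np.arange(len(unknowns))
    rows, cols, vals = [], [], []
    b = np.zeros(len(unknowns))
    ny, nx = mask.shape
    for k, (iy, ix) in enumerate(unknowns):
        deg = 0
        for jy, jx in ((iy - 1, ix), (iy + 1, ix), (iy, ix - 1), (iy, ix + 1)):
            if not (0 <= jy < ny and 0 <= jx < nx):
                continue
            if mask[jy, jx]:
                deg += 1
                rows.append(k)
                cols.append(idx[jy, jx])
                vals.append(-1.0)
            elif valid[jy, jx]:
                deg += 1
                b[k] += data[jy, jx]
        rows.append(k)
        cols.append(k)
        vals.append(float(max(deg, 1)))
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(len(unknowns),) * 2)
    return A, b, unknowns


def harmonic_inpaint(bz_slice: np.ndarray, defect: DefectMask,
                     valid_mask: np.ndarray | None = None,
                     tol: float = 1e-12) -> np.ndarray:
    """Replace Bz on the defect mask by the discrete-harmonic extension of
    the surrounding valid values; everything else is returned bit-identical.

    Defect components enclosed inside other defects are solved jointly, so
    islands without directly valid neighbors are handled naturally.
    """
    B = np.array(bz_slice, dtype=float)
    mask = np.asarray(defect.mask, dtype=bool)
    if not np.any(mask):
        return B
    if valid_mask is None:
        valid_mask = np.isfinite(B) & ~mask
    else:
        valid_mask = np.asarray(valid_mask, dtype=bool) & ~mask
    A, b, unknowns = _laplace_system(mask, valid_mask, np.where(valid_mask, B, 0.0))
    if not np.any(b):
        raise ValidationError("defected region has no valid boundary data")
    x, info = cg(A, b, rtol=tol, atol=0.0, maxiter=10 * len(b) + 100)
    if info != 0:
        x = spsolve(A.tocsc(), b)
    resid = np.linalg.norm(A @ x - b)
    if resid > 1e-8 * max(np.linalg.norm(b), 1e-300):
        raise SolverError("harmonic inpainting solve failed", residual=float(resid))
    B[unknowns[:, 0], unknowns[:, 1]] = x
    return B


def isotropic_smooth_defect(bz_slice: np.ndarray, defect: DefectMask,
                            duration: float = 2.0, dt: float = 0.2) -> np.ndarray:
    """Heat-equation smoothing of the one-ring-dilated defect region.

    Values outside the dilated region act as a Dirichlet clamp; the step
    count follows the same explicit scheme as the denoiser.  ``duration=0``
    is the identity.
    """
    if duration < 0:
        raise ValidationError("duration must be nonnegative")
    B = np.array(bz_slice, dtype=float)
    if duration == 0 or not np.any(defect.mask):
        return B
    struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    region = ndimage.binary_dilation(defect.mask, structure=struct)
    region &= np.isfinite(B)
    # Dirichlet clamp: diffuse on the dilated region plus its fixed rim
    rim = ndimage.binary_dilation(region, structure=struct) & ~region
    rim &= np.isfinite(B)
    active = region | rim
    ones = np.ones(B.shape)
    n_steps = int(np.ceil(duration / dt - 1e-12))
    for k in range(n_steps):
        step = min(dt, duration - k * dt)
        new = _flux_step(B, ones, np.zeros_like(B), ones, active, step)
        new[rim] = B[rim]          # clamp
        B[region] = new[region]
    return B
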