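"""From complex MR images to unwrapped Bz.

The measured quantity is the phase of M+ / M-, which equals
2 gamma Tc Bz modulo 2 pi; the systematic phase artifact delta cancels in
the division.  The wrapped phase is unwrapped with Goldstein's branch-cut
algorithm (residue detection, nearest-neighbor dipole cuts, flood-fill
integration that avoids the cuts) and scaled by 1 / (2 gamma Tc).  A
z-continuity report decides whether the 3D Laplacian may be used downstream.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import QualityError, ValidationError
from .phantom import GAMMA_HYDROGEN, BzVolume, KSpaceData, KSPACE_CONVENTION

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# image formation
# ---------------------------------------------------------------------------

def kspace_to_image(s: np.ndarray, convention: str | None = None) -> np.ndarray:
    """Inverse 2D DFT of one k-space array under the stated convention.

    The convention must be given explicitly (no silent default on read).
    """
    if convention is None:
        raise ValidationError("k-space convention metadata missing")
    if convention != KSPACE_CONVENTION:
        raise ValidationError(f"unknown k-space convention {convention!r}")
    return np.fft.ifft2(np.fft.ifftshift(np.asarray(s)))


def kspace_pair_to_images(kdata: KSpaceData) -> tuple[np.ndarray, np.ndarray]:
    """Both complex images of a k-space pair."""
    return (kspace_to_image(kdata.s_plus, kdata.convention),
            kspace_to_image(kdata.s_minus, kdata.convention))


# ---------------------------------------------------------------------------
# wrapped phase
# ---------------------------------------------------------------------------

@dataclass
class WrappedPhaseSlice:
    """Wrapped phase arg(M+ conj(M-)) in (-pi, pi] with a magnitude mask."""

    phi: np.ndarray
    mask: np.ndarray


def extract_wrapped_bz(m_plus: np.ndarray, m_minus: np.ndarray,
                       magnitude_floor: float = 0.0) -> WrappedPhaseSlice:
    """Phase of the complex division; pixels whose magnitude product falls
    below ``magnitude_floor`` are masked out (they belong to the defected
    region handled by inpainting)."""
    m_plus = np.asarray(m_plus)
    m_minus = np.asarray(m_minus)
    if m_plus.shape != m_minus.shape:
        raise ValidationError("image pair must share a shape")
    phi = np.angle(m_plus * np.conj(m_minus))
    mask = np.abs(m_plus) * np.abs(m_minus) >= magnitude_floor
    if not np.any(mask):
        warnings.warn("all pixels fall below the magnitude floor", stacklevel=2)
    return WrappedPhaseSlice(phi, mask)


def wrap(phase: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phase), TWO_PI)


# ---------------------------------------------------------------------------
# Goldstein unwrapping
# ---------------------------------------------------------------------------

def phase_residues(phi: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Residue charge of every 2x2 loop (shape (ny-1, nx-1), 0 off-mask).

    The loop at (iy, ix) runs over pixels (iy,ix) -> (iy,ix+1) ->
    (iy+1,ix+1) -> (iy+1,ix); a nonzero wrapped-gradient circulation marks a
    +/-1 residue obstructing path-independent integration.
    """
    d1 = wrap(phi[:-1, 1:] - phi[:-1, :-1])      # right along top
    d2 = wrap(phi[1:, 1:] - phi[:-1, 1:])        # down right side
    d3 = wrap(phi[1:, :-1] - phi[1:, 1:])        # left along bottom
    d4 = wrap(phi[:-1, :-1] - phi[1:, :-1])      # up left side
    charge = np.rint((d1 + d2 + d3 + d4) / TWO_PI).astype(int)
    loop_ok = mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, :-1] & mask[1:, 1:]
    charge[~loop_ok] = 0
    return charge


def _branch_cut_pixels(phi_shape, residues) -> np.ndarray:
    """Pixels blocked by branch cuts (greedy nearest-opposite pairing).

    Residues live on pixel corners; each cut rasterizes the segment joining
    two paired residues (or a residue and the nearest frame border) onto the
    four-pixel neighborhood of the corner line.  Deterministic: scan order,
    ties by index.
    """
    ny, nx = phi_shape
    blocked = np.zeros(phi_shape, dtype=bool)
    pos = np.argwhere(residues != 0)
    if len(pos) == 0:
        return blocked
    charges = residues[pos[:, 0], pos[:, 1]]
    unpaired = np.ones(len(pos), dtype=bool)

    def block_segment(p, q):
        # corner (iy, ix) sits between pixels; block both pixel rows/cols
        n = int(max(abs(q[0] - p[0]), abs(q[1] - p[1]))) * 2 + 1
        ts = np.linspace(0.0, 1.0, n + 1)
        ys = np.clip(np.rint(p[0] + ts * (q[0] - p[0])).astype(int), 0, ny - 2)
        xs = np.clip(np.rint(p[1] + ts * (q[1] - p[1])).astype(int), 0, nx - 2)
        blocked[ys, xs + 1] = True
        blocked[ys + 1, xs + 1] = True

    for i in range(len(pos)):
        if not unpaired[i]:
            continue
        p = pos[i]
        # nearest frame border distance and projection point
        border_d = min(p[0] + 1, ny - 1 - p[0], p[1] + 1, nx - 1 - p[1])
        opp = np.where(unpaired & (charges == -charges[i]))[0]
        if len(opp):
            d = np.abs(pos[opp] - p).sum(axis=1)
            k = opp[int(np.argmin(d))]
            if d.min() <= border_d:
                block_segment(p, pos[k])
                unpaired[i] = unpaired[k] = False
                continue
        # ground to the nearest border
        tgt = p.copy()
        cands = [(p[0] + 1, (-1, p[1])), (ny - 1 - p[0], (ny - 1, p[1])),
                 (p[1] + 1, (p[0], -1)), (nx - 1 - p[1], (p[0], nx - 1))]
        tgt = min(cands)[1]
        block_segment(p, np.array(tgt))
        unpaired[i] = False
    return blocked


def goldstein_unwrap(wp: WrappedPhaseSlice,
                     max_residue_fraction: float = 0.10) -> np.ndarray:
    """Goldstein branch-cut unwrapping of one slice.

    Returns the unwrapped phase (NaN outside the mask), shifted by the
    2 pi multiple that brings the median over the mask's boundary ring
    closest to zero (Bz is physically near zero far from the current paths).
    Raises :class:`QualityError` when the residue density exceeds
    ``max_residue_fraction`` (denoise first).
    """
    phi = np.asarray(wp.phi, dtype=float)
    mask = np.asarray(wp.mask, dtype=bool)
    ny, nx = phi.shape
    if not np.any(mask):
        raise ValidationError("empty mask")
    residues = phase_residues(phi, mask)
    n_res = int(np.count_nonzero(residues))
    if n_res > max_residue_fraction * mask.sum():
        raise QualityError(
            f"residue density {n_res / mask.sum():.1%} exceeds "
            f"{max_residue_fraction:.0%}: denoise the phase first")
    blocked = _branch_cut_pixels(phi.shape, residues) & mask

    u = np.full(phi.shape, np.nan)
    visited = np.zeros(phi.shape, dtype=bool)
    free = mask & ~blocked
    order = np.argwhere(free)
    for seed in order:
        sy, sx = int(seed[0]), int(seed[1])
        if visited[sy, sx]:
            continue
        visited[sy, sx] = True
        u[sy, sx] = phi[sy, sx]
        queue = deque([(sy, sx)])
        while queue:
            iy, ix = queue.popleft()
            for jy, jx in ((iy - 1, ix), (iy + 1, ix), (iy, ix - 1), (iy, ix + 1)):
                if 0 <= jy < ny and 0 <= jx < nx and free[jy, jx] and not visited[jy, jx]:
                    visited[jy, jx] = True
                    u[jy, jx] = u[iy, ix] + wrap(phi[jy, jx] - phi[iy, ix])
                    queue.append((jy, jx))

    # fill cut pixels from any unwrapped neighbor (single wrapped step)
    todo = deque(map(tuple, np.argwhere(mask & blocked)))
    guard = 4 * len(todo) + 1
    while todo and guard:
        guard -= 1
        iy, ix = todo.popleft()
        done = False
        for jy, jx in ((iy - 1, ix), (iy + 1, ix), (iy, ix - 1), (iy, ix + 1)):
            if 0 <= jy < ny and 0 <= jx < nx and visited[jy, jx]:
                u[iy, ix] = u[jy, jx] + wrap(phi[iy, ix] - phi[jy, jx])
                visited[iy, ix] = True
                done = True
                break
        if not done:
            todo.append((iy, ix))

    # per-slice constant: boundary-ring median snapped to the nearest 0
    from .phantom import binary_erosion_4
    ring = mask & ~binary_erosion_4(mask)
    ring_vals = u[ring]
    ring_vals = ring_vals[np.isfinite(ring_vals)]
    if ring_vals.size:
        u -= TWO_PI * np.rint(np.median(ring_vals) / TWO_PI)
    return u


def phase_to_bz(unwrapped: np.ndarray, Tc: float,
                gamma: float = GAMMA_HYDROGEN) -> np.ndarray:
    """Scale unwrapped phase to Tesla: Bz = phase / (2 gamma Tc)."""
    if Tc <= 0 or gamma <= 0:
        raise ValidationError("Tc and gamma must be positive")
    return np.asarray(unwrapped, dtype=float) / (2.0 * gamma * Tc)


def bz_from_pair(m_plus: np.ndarray, m_minus: np.ndarray, Tc: float,
                 gamma: float = GAMMA_HYDROGEN, magnitude_floor: float = 0.0,
                 max_residue_fraction: float = 0.10
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Full chain divide -> unwrap -> scale for one slice; returns (Bz, mask)."""
    wp = extract_wrapped_bz(m_plus, m_minus, magnitude_floor)
    u = goldstein_unwrap(wp, max_residue_fraction)
    return phase_to_bz(u, Tc, gamma), wp.mask


# ---------------------------------------------------------------------------
# z-continuity
# ---------------------------------------------------------------------------

@dataclass
class ContinuityReport:
    """Per-slice-pair discontinuity statistic and the recommended Laplacian.

    The statistic is the median absolute inter-slice difference divided by
    the median absolute in-plane gradient magnitude of the pair; a 2 pi
    unwrapping jump between slices blows the ratio up.  Any failing pair
    forces the 2D Laplacian recommendation.
    """

    ratios: list[float] = field(default_factory=list)
    passes: list[bool] = field(default_factory=list)
    threshold: float = 5.0
    recommended_mode: str = "2d"

    def to_dict(self) -> dict:
        return {"ratios": [float(r) for r in self.ratios],
                "passes": [bool(p) for p in self.passes],
                "threshold": self.threshold,
                "recommended_mode": self.recommended_mode}


def verify_z_continuity(bz: BzVolume, injection: int = 0,
                        threshold: float = 5.0) -> ContinuityReport:
    """Check Bz continuity across adjacent slices of one injection."""
    vol = bz.bz[injection]
    mask = bz.valid_mask
    if vol.shape[0] < 2:
        return ContinuityReport(threshold=threshold, recommended_mode="2d")
    ratios, passes = [], []
    for k in range(vol.shape[0] - 1):
        a, b = vol[k], vol[k + 1]
        diff = np.abs(b - a)[mask]
        grads = []
        for s in (a, b):
            gy, gx = np.gradient(s, bz.grid.dy, bz.grid.dx)
            g = np.hypot(gx, gy)[mask] * min(bz.grid.dx, bz.grid.dy)
            grads.append(g)
        den = float(np.median(np.concatenate(grads)))
        num = float(np.median(diff))
        ratio = 0.0 if num == 0 else (np.inf if den == 0 else num / den)
        ratios.append(ratio)
        passes.append(ratio <= threshold)
    mode = "3d" if all(passes) else "2d"
    return ContinuityReport(ratios, passes, threshold, mode)
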