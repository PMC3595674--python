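"""Imaging-domain geometry: segmentation, electrode arcs, triangulation.

The imaging slice Omega_z is represented by a simple closed polygon
(counterclockwise, physical coordinates in meters) with electrode arcs
recorded as index ranges into the polyline.  Conforming triangle meshes
for the P1 finite-element solvers are produced by ear clipping followed
by Lawson edge flips (toward the constrained Delaunay triangulation) and
Rivara longest-edge bisection until the requested area bound holds.
Every boundary edge of the mesh lies on an original polygon segment, so
electrode markers propagate exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import MeshError, ValidationError
from .grids import SliceGrid

__all__ = [
    "DomainPolygon",
    "TriangleMesh",
    "LocalRegion",
    "ElectrodeArcSpec",
    "segment_domain",
    "attach_electrodes",
    "triangulate",
    "clip_local_region",
]


# ---------------------------------------------------------------------------
# polygon containers
# ---------------------------------------------------------------------------

def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class DomainPolygon:
    """Closed boundary of the imaging slice with electrode arc bookkeeping.

    ``vertices`` is an (n, 2) array of the closed polyline (last vertex
    implicitly connects to the first), counterclockwise.  ``electrode_arcs``
    maps ``(injection, polarity)`` -- polarity one of ``"+"``/``"-"`` -- to a
    vertex index range ``(i0, i1)``: the arc covers polyline segments
    ``i0, i0+1, ..., i1-1`` modulo n.
    """

    vertices: np.ndarray
    electrode_arcs: dict[tuple[int, str], tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValidationError("polygon needs an (n>=3, 2) vertex array")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if _signed_area(v) < 0:
            v = v[::-1].copy()
        if not ShapelyPolygon(v).is_valid:
            raise ValidationError("polygon must be simple (non-self-intersecting)")
        self.vertices = v

    @property
    def n(self) -> int:
        return len(self.vertices)

    def area(self) -> float:
        return _signed_area(self.vertices)

    def centroid(self) -> np.ndarray:
        c = ShapelyPolygon(self.vertices).centroid
        return np.array([c.x, c.y])

    def perimeter_params(self) -> np.ndarray:
        """Cumulative arclength of each vertex; last entry is the perimeter."""
        seg = np.linalg.norm(np.roll(self.vertices, -1, axis=0) - self.vertices, axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def arc_segments(self, injection: int, polarity: str) -> list[int]:
        """Segment indices covered by one electrode arc."""
        i0, i1 = self.electrode_arcs[(injection, polarity)]
        n = self.n
        if i1 >= i0:
            return list(range(i0, i1))
        return list(range(i0, n)) + list(range(0, i1))

    def segment_marker(self, seg: int) -> tuple:
        for key in self.electrode_arcs:
            if seg in self.arc_segments(*key):
                return ("electrode", *key)
        return ("boundary",)


@dataclass
class LocalRegion:
    """Simple polygon selecting a sub-region D of the slice for local
    reconstruction."""

    polygon: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.polygon, dtype=float)
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if _signed_area(v) < 0:
            v = v[::-1].copy()
        sp = ShapelyPolygon(v)
        if not sp.is_valid or sp.area <= 0:
            raise ValidationError("local region polygon must be simple with area > 0")
        self.polygon = v

    def area(self) -> float:
        return _signed_area(self.polygon)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_domain(M: np.ndarray, grid: SliceGrid, level_fraction: float = 0.10,
                   simplify_tol_pixels: float = 0.5) -> DomainPolygon:
    """Extract the slice boundary polygon from an MR magnitude image.

    Pixels with magnitude >= ``level_fraction * max(M)`` form the object;
    the largest connected component is contoured (marching squares) and the
    contour simplified to within ``simplify_tol_pixels`` of the original.
    Component ties are broken by smaller centroid row, then column.
    """
    from skimage import measure

    M = np.asarray(M, dtype=float)
    if M.min() < 0:
        raise ValidationError("magnitude image must be nonnegative")
    thr = level_fraction * M.max()
    binary = M >= thr
    labels, nlab = ndimage.label(binary)
    if nlab == 0:
        raise ValidationError("no super-threshold component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, nlab + 1))
    best = np.max(sizes)
    candidates = [i + 1 for i, s in enumerate(sizes) if s == best]
    if len(candidates) > 1:
        cents = ndimage.center_of_mass(binary, labels, candidates)
        order = sorted(range(len(candidates)), key=lambda k: (cents[k][0], cents[k][1]))
        label = candidates[order[0]]
    else:
        label = candidates[0]
    comp = (labels == label)

    padded = np.pad(comp.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValidationError("empty component contour")
    contour = max(contours, key=len) - 1.0  # undo padding; (row, col) coords
    tol = simplify_tol_pixels * min(grid.dx, grid.dy)
    # physical coords: x from columns, y from rows
    phys = np.column_stack([
        grid.origin[0] + contour[:, 1] * grid.dx,
        grid.origin[1] + contour[:, 0] * grid.dy,
    ])
    simplified = measure.approximate_polygon(phys, tolerance=tol)
    if np.allclose(simplified[0], simplified[-1]):
        simplified = simplified[:-1]
    if len(simplified) < 3:
        raise ValidationError("degenerate contour after simplification")
    return DomainPolygon(simplified)


# ---------------------------------------------------------------------------
# electrode arcs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeArcSpec:
    """One electrode arc: anchored at ``anchor_angle`` (radians, measured about
    the polygon centroid) and spanning ``length`` meters of perimeter,
    centered on the anchor."""

    injection: int
    polarity: str
    anchor_angle: float
    length: float


def _boundary_point_param(poly: DomainPolygon, angle: float) -> float:
    """Perimeter parameter of the boundary point closest in direction `angle`."""
    params = poly.perimeter_params()
    c = poly.centroid()
    # sample each segment finely
    best = (np.inf, 0.0)
    for i in range(poly.n):
        a = poly.vertices[i]
        b = poly.vertices[(i + 1) % poly.n]
        ts = np.linspace(0.0, 1.0, 17, endpoint=False)
        pts = a[None, :] + ts[:, None] * (b - a)[None, :]
        ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
        d = np.abs(np.angle(np.exp(1j * (ang - angle))))
        k = int(np.argmin(d))
        if d[k] < best[0]:
            best = (float(d[k]), float(params[i] + ts[k] * (params[i + 1] - params[i])))
    return best[1]


def attach_electrodes(poly: DomainPolygon,
                      arcs: list[ElectrodeArcSpec]) -> DomainPolygon:
    """Resample the polyline so each arc's endpoints are vertices and record
    the electrode index ranges.

    Arcs must be disjoint along the perimeter; zero or negative lengths and
    overlaps raise :class:`ValidationError`.
    """
    perim = float(poly.perimeter_params()[-1])
    intervals: dict[tuple[int, str], tuple[float, float]] = {}
    for spec in arcs:
        if spec.length <= 0:
            raise ValidationError(f"electrode arc length must be positive, got {spec.length}")
        if spec.length >= perim / 2:
            raise ValidationError("electrode arc longer than half the perimeter")
        t0 = _boundary_point_param(poly, spec.anchor_angle)
        intervals[(spec.injection, spec.polarity)] = (
            (t0 - spec.length / 2) % perim, (t0 + spec.length / 2) % perim)

    # overlap check on the circle
    def _pieces(lo, hi):
        return [(lo, hi)] if lo <= hi else [(lo, perim), (0.0, hi)]

    keys = list(intervals)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            for a0, a1 in _pieces(*intervals[keys[i]]):
                for b0, b1 in _pieces(*intervals[keys[j]]):
                    if max(a0, b0) < min(a1, b1):
                        raise ValidationError(
                            f"electrode arcs {keys[i]} and {keys[j]} overlap")

    # insert endpoint vertices
    params = poly.perimeter_params()
    endpoints = sorted({t for iv in intervals.values() for t in iv})
    new_vertices: list[np.ndarray] = []
    param_of_vertex: list[float] = []
    eps = 1e-9 * perim   # avoid near-duplicate vertices / ultra-short segments
    for i in range(poly.n):
        new_vertices.append(poly.vertices[i])
        param_of_vertex.append(float(params[i]))
        s0, s1 = float(params[i]), float(params[i + 1])
        a = poly.vertices[i]
        b = poly.vertices[(i + 1) % poly.n]
        for t in endpoints:
            if s0 + eps < t < s1 - eps:
                frac = (t - s0) / (s1 - s0)
                new_vertices.append(a + frac * (b - a))
                param_of_vertex.append(t)

    verts = np.array(new_vertices)
    pv = np.array(param_of_vertex)

    def _vertex_at(t: float) -> int:
        d = np.minimum(np.abs(pv - t), perim - np.abs(pv - t))
        return int(np.argmin(d))

    arcs_idx = {}
    for key, (lo, hi) in intervals.items():
        arcs_idx[key] = (_vertex_at(lo), _vertex_at(hi))
    return DomainPolygon(verts, electrode_arcs=arcs_idx)


# ---------------------------------------------------------------------------
# triangulation
# ---------------------------------------------------------------------------

@dataclass
class TriangleMesh:
    """Conforming P1 triangulation with boundary markers.

    ``boundary_markers`` holds one tuple per boundary edge: ``("boundary",)``
    or ``("electrode", injection, polarity)``.
    """

    vertices: np.ndarray            # (nv, 2) physical coords
    triangles: np.ndarray           # (nt, 3) CCW vertex indices
    boundary_edges: np.ndarray      # (ne, 2)
    boundary_markers: list[tuple]
    max_area: float = np.inf
    _mpl_tri: object = field(default=None, repr=False, compare=False)

    def areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
        return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                      - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))

    def boundary_vertices(self) -> np.ndarray:
        return np.unique(self.boundary_edges)

    def electrode_vertices(self, injection: int, polarity: str) -> np.ndarray:
        sel = [i for i, m in enumerate(self.boundary_markers)
               if m[0] == "electrode" and m[1] == injection and m[2] == polarity]
        if not sel:
            return np.array([], dtype=int)
        return np.unique(self.boundary_edges[sel])

    # --- point location ----------------------------------------------------
    def _triangulation(self):
        if self._mpl_tri is None:
            import matplotlib.tri as mtri
            self._mpl_tri = mtri.Triangulation(
                self.vertices[:, 0], self.vertices[:, 1], self.triangles)
        return self._mpl_tri

    def find_triangles(self, points: np.ndarray) -> np.ndarray:
        """Triangle index containing each point (-1 outside)."""
        finder = self._triangulation().get_trifinder()
        pts = np.asarray(points, dtype=float)
        return finder(pts[..., 0], pts[..., 1])

    def barycentric(self, points: np.ndarray, tri_idx: np.ndarray):
        """Barycentric coordinates of points w.r.t. their containing triangle."""
        t = self.triangles[np.clip(tri_idx, 0, None)]
        a, b, c = (self.vertices[t[..., 0]], self.vertices[t[..., 1]],
                   self.vertices[t[..., 2]])
        p = np.asarray(points, dtype=float)
        det = ((b[..., 0] - a[..., 0]) * (c[..., 1] - a[..., 1])
               - (b[..., 1] - a[..., 1]) * (c[..., 0] - a[..., 0]))
        l1 = ((p[..., 0] - a[..., 0]) * (c[..., 1] - a[..., 1])
              - (p[..., 1] - a[..., 1]) * (c[..., 0] - a[..., 0])) / det
        l2 = ((b[..., 0] - a[..., 0]) * (p[..., 1] - a[..., 1])
              - (b[..., 1] - a[..., 1]) * (p[..., 0] - a[..., 0])) / det
        return np.stack([1.0 - l1 - l2, l1, l2], axis=-1)

    def rasterize_vertex_values(self, values: np.ndarray, grid: SliceGrid,
                                fill: float = np.nan) -> np.ndarray:
        """Linearly interpolate vertex values onto pixel centers of `grid`."""
        X, Y = grid.meshgrid()
        pts = np.stack([X.ravel(), Y.ravel()], axis=-1)
        idx = self.find_triangles(pts)
        lam = self.barycentric(pts, idx)
        t = self.triangles[np.clip(idx, 0, None)]
        vals = np.sum(lam * values[t], axis=-1)
        vals[idx < 0] = fill
        return vals.reshape(grid.shape)


def _point_in_tri(p, a, b, c, eps):
    d1 = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
    d2 = (c[0] - b[0]) * (p[1] - b[1]) - (c[1] - b[1]) * (p[0] - b[0])
    d3 = (a[0] - c[0]) * (p[1] - c[1]) - (a[1] - c[1]) * (p[0] - c[0])
    return d1 >= -eps and d2 >= -eps and d3 >= -eps


def _ear_clip(pts: np.ndarray):
    """Triangulate a simple CCW polygon by ear clipping.

    Returns ``(triangles, null_ears)``: exactly-collinear corners (e.g.
    electrode endpoints inserted on a straight contour run) cannot form
    positive-area ears; they are clipped as *null ears* (a, b, c) with b on
    segment a-c, to be re-attached by splitting the neighbor across (a, c).
    """
    n = len(pts)
    scale2 = float(np.max(np.ptp(pts, axis=0))) ** 2
    eps = 1e-13 * scale2
    idx = list(range(n))
    tris: list[tuple[int, int, int]] = []
    nulls: list[tuple[int, int, int]] = []

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def between(a, b, c):
        return np.dot(b - a, c - b) > 0

    while len(idx) > 3:
        m = len(idx)
        clipped = False
        # pass 1: degenerate (collinear) corners become null ears
        for k in range(m):
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            a, b, c = pts[i0], pts[i1], pts[i2]
            if abs(cross(a, b, c)) <= eps and between(a, b, c):
                nulls.append((i0, i1, i2))
                idx.pop(k)
                clipped = True
                break
        if clipped:
            continue
        # pass 2: ordinary positive-area ears
        for k in range(m):
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            a, b, c = pts[i0], pts[i1], pts[i2]
            if cross(a, b, c) <= eps:
                continue  # reflex or degenerate corner
            ok = True
            for q in idx:
                if q in (i0, i1, i2):
                    continue
                if _point_in_tri(pts[q], a, b, c, -eps):
                    ok = False
                    break
            if ok:
                tris.append((i0, i1, i2))
                idx.pop(k)
                clipped = True
                break
        if not clipped:
            raise MeshError("ear clipping failed: polygon may be degenerate")
    a, b, c = (pts[i] for i in idx)
    if abs(cross(a, b, c)) <= eps:
        # collinear remainder: record as a null ear around its middle vertex
        for k in range(3):
            i0, i1, i2 = idx[(k - 1) % 3], idx[k], idx[(k + 1) % 3]
            if between(pts[i0], pts[i1], pts[i2]):
                nulls.append((i0, i1, i2))
                break
        else:
            raise MeshError("degenerate polygon remainder")
        if not tris:
            raise MeshError("polygon has no area")
    else:
        tris.append((idx[0], idx[1], idx[2]))
    return tris, nulls


def _in_circumcircle(a, b, c, d) -> bool:
    """True if d is strictly inside the circumcircle of CCW triangle abc."""
    m = np.array([
        [a[0] - d[0], a[1] - d[1], (a[0] - d[0]) ** 2 + (a[1] - d[1]) ** 2],
        [b[0] - d[0], b[1] - d[1], (b[0] - d[0]) ** 2 + (b[1] - d[1]) ** 2],
        [c[0] - d[0], c[1] - d[1], (c[0] - d[0]) ** 2 + (c[1] - d[1]) ** 2],
    ])
    return float(np.linalg.det(m)) > 1e-12 * max(1.0, abs(m[0, 2]), abs(m[1, 2]))


class _MeshBuilder:
    """Mutable triangle store with edge adjacency for flips and bisection."""

    def __init__(self, pts: np.ndarray, tris: list[tuple[int, int, int]],
                 boundary_seg: dict[tuple[int, int], int]):
        self.pts: list[np.ndarray] = [np.asarray(p, dtype=float) for p in pts]
        self.tris: dict[int, tuple[int, int, int]] = {i: t for i, t in enumerate(tris)}
        self._next = len(tris)
        self.edge_tris: dict[tuple[int, int], set[int]] = {}
        for i, t in self.tris.items():
            for e in self._edges(t):
                self.edge_tris.setdefault(e, set()).add(i)
        # boundary edge -> original polygon segment index
        self.boundary_seg = dict(boundary_seg)
        self.midpoints: dict[tuple[int, int], int] = {}

    @staticmethod
    def _edges(t):
        return [tuple(sorted((t[0], t[1]))), tuple(sorted((t[1], t[2]))),
                tuple(sorted((t[2], t[0])))]

    def _add_tri(self, t):
        i = self._next
        self._next += 1
        self.tris[i] = t
        for e in self._edges(t):
            self.edge_tris.setdefault(e, set()).add(i)
        return i

    def _remove_tri(self, i):
        t = self.tris.pop(i)
        for e in self._edges(t):
            s = self.edge_tris.get(e)
            if s is not None:
                s.discard(i)
                if not s:
                    del self.edge_tris[e]

    def area(self, i) -> float:
        a, b, c = (self.pts[v] for v in self.tris[i])
        return 0.5 * ((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

    def _midpoint(self, e: tuple[int, int]) -> int:
        if e in self.midpoints:
            return self.midpoints[e]
        m = 0.5 * (self.pts[e[0]] + self.pts[e[1]])
        self.pts.append(m)
        vi = len(self.pts) - 1
        self.midpoints[e] = vi
        if e in self.boundary_seg:
            seg = self.boundary_seg.pop(e)
            self.boundary_seg[tuple(sorted((e[0], vi)))] = seg
            self.boundary_seg[tuple(sorted((vi, e[1])))] = seg
        return vi

    def _longest_edge(self, i) -> tuple[int, int]:
        t = self.tris[i]
        best = None
        best_key = None
        for e in self._edges(t):
            ln = float(np.linalg.norm(self.pts[e[0]] - self.pts[e[1]]))
            key = (ln, -e[0], -e[1])
            if best_key is None or key > best_key:
                best_key, best = key, e
        return best

    def _split_across(self, i, e, mid):
        """Replace triangle i by its two children across edge e (midpoint mid)."""
        t = self.tris[i]
        opp = [v for v in t if v not in e][0]
        k = t.index(e[0]) if (t.index(e[0]) + 1) % 3 == t.index(e[1]) else t.index(e[1])
        # preserve orientation: children (e_first, mid, opp) and (mid, e_second, opp)
        first, second = t[k], t[(k + 1) % 3]
        self._remove_tri(i)
        self._add_tri((first, mid, opp))
        self._add_tri((mid, second, opp))

    def bisect_rivara(self, i0: int):
        stack = [i0]
        while stack:
            i = stack[-1]
            if i not in self.tris:
                stack.pop()
                continue
            e = self._longest_edge(i)
            nbs = [j for j in self.edge_tris.get(e, ()) if j != i]
            if nbs:
                j = nbs[0]
                if self._longest_edge(j) != e:
                    stack.append(j)
                    continue
                mid = self._midpoint(e)
                self._split_across(i, e, mid)
                self._split_across(j, e, mid)
            else:
                mid = self._midpoint(e)
                self._split_across(i, e, mid)
            stack.pop()

    def lawson_flips(self, max_passes: int = 60, area_cap: float | None = None):
        for _ in range(max_passes):
            flipped = 0
            for e in sorted(self.edge_tris):
                ts = self.edge_tris.get(e)
                if ts is None or len(ts) != 2 or e in self.boundary_seg:
                    continue
                i, j = sorted(ts)
                ti, tj = self.tris[i], self.tris[j]
                oi = [v for v in ti if v not in e][0]
                oj = [v for v in tj if v not in e][0]
                a, b = e
                if not _in_circumcircle(*(self.pts[v] for v in ti), self.pts[oj]):
                    continue
                # candidate new triangles (oi, oj) diagonal
                cand1, cand2 = (oi, a, oj), (oj, b, oi)

                def _ar(t):
                    p, q, r = (self.pts[v] for v in t)
                    return 0.5 * ((q[0] - p[0]) * (r[1] - p[1])
                                  - (q[1] - p[1]) * (r[0] - p[0]))
                a1, a2 = _ar(cand1), _ar(cand2)
                if a1 <= 0 or a2 <= 0:
                    continue
                if area_cap is not None and max(a1, a2) > area_cap:
                    continue
                self._remove_tri(i)
                self._remove_tri(j)
                self._add_tri(cand1)
                self._add_tri(cand2)
                flipped += 1
            if flipped == 0:
                break

    def extract(self, poly: DomainPolygon, max_area: float) -> TriangleMesh:
        order = sorted(self.tris)
        tri_arr = np.array([self.tris[i] for i in order], dtype=int)
        pts = np.array(self.pts)
        # compact unused vertices (none expected, but keep indices tight)
        boundary_edges = []
        markers = []
        for e, tset in sorted(self.edge_tris.items()):
            if len(tset) == 1:
                seg = self.boundary_seg.get(e)
                boundary_edges.append(e)
                markers.append(poly.segment_marker(seg) if seg is not None
                               else ("boundary",))
        return TriangleMesh(pts, tri_arr, np.array(boundary_edges, dtype=int),
                            markers, max_area=max_area)


def triangulate(poly: DomainPolygon, max_area: float) -> TriangleMesh:
    """Triangulate the domain polygon with all element areas <= ``max_area``.

    Deterministic: ear clipping, Lawson flips to (constrained) Delaunay,
    then longest-edge bisection of oversize elements with conformity, and a
    final area-capped flip pass for element quality.
    """
    if max_area <= 0:
        raise ValidationError("max_area must be positive")
    pts = poly.vertices
    if poly.area() <= 0:
        raise MeshError("degenerate polygon")
    tris, nulls = _ear_clip(pts)
    boundary_seg = {tuple(sorted((i, (i + 1) % poly.n))): i for i in range(poly.n)}
    mb = _MeshBuilder(pts, tris, boundary_seg)
    # re-attach collinear boundary vertices: split the triangle across (a, c)
    # at the in-between vertex b so edges (a, b) and (b, c) become mesh edges
    for a, b, c in reversed(nulls):
        e = tuple(sorted((a, c)))
        owners = sorted(mb.edge_tris.get(e, ()))
        if not owners:
            raise MeshError("cannot re-attach collinear boundary vertex")
        mb._split_across(owners[0], e, b)
    mb.lawson_flips()
    for _ in range(200):
        oversize = [i for i in list(mb.tris) if mb.area(i) > max_area]
        if not oversize:
            break
        for i in oversize:
            if i in mb.tris and mb.area(i) > max_area:
                mb.bisect_rivara(i)
        mb.lawson_flips(max_passes=3, area_cap=max_area)
    else:
        raise MeshError("area refinement did not converge")
    mesh = mb.extract(poly, max_area)
    if np.any(mesh.areas() <= 0):
        raise MeshError("non-positive element produced")
    return mesh


# ---------------------------------------------------------------------------
# local regions
# ---------------------------------------------------------------------------

def clip_local_region(region: LocalRegion, poly: DomainPolygon,
                      grid: SliceGrid | None = None,
                      defect_mask: np.ndarray | None = None) -> LocalRegion:
    """Intersect a local region with the slice domain.

    Emits a warning (with the overlap area) if the clipped region overlaps
    the defect mask: local reconstruction assumes defect-free data in D.
    """
    sp_region = ShapelyPolygon(region.polygon)
    sp_domain = ShapelyPolygon(poly.vertices)
    inter = sp_region.intersection(sp_domain)
    if inter.is_empty or inter.area <= 0:
        raise ValidationError("local region does not intersect the imaging domain")
    if inter.geom_type == "MultiPolygon":
        inter = max(inter.geoms, key=lambda g: g.area)
    clipped = LocalRegion(np.array(inter.exterior.coords))

    if defect_mask is not None and grid is not None and np.any(defect_mask):
        from matplotlib.path import Path

        X, Y = grid.meshgrid()
        pts = np.stack([X.ravel(), Y.ravel()], axis=-1)
        inside = Path(clipped.polygon).contains_points(pts).reshape(grid.shape)
        overlap = int(np.sum(inside & defect_mask))
        if overlap:
            warnings.warn(
                f"local region overlaps the defected region on {overlap} pixels "
                f"({overlap * grid.dx * grid.dy:.3e} m^2); local reconstruction "
                "assumes defect-free data", stacklevel=2)
    return clipped
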