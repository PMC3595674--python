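"""End-to-end orchestration: simulate -> phase -> denoise -> inpaint ->
mesh -> reconstruct, driven by one strict-schema configuration.

Every stage is a pure function of (container contents, parameters, seed);
re-running a stage with identical inputs reproduces identical arrays, which
the run manifest records as content hashes.
"""

from __future__ import annotations

import copy
import json
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, binary_fill_holes

from . import denoise as dn
from . import geometry as geo
from . import inpaint as inp
from . import phantom as ph
from . import phase as phs
from . import recon as rc
from .container import Case
from .errors import ValidationError
from .grids import SliceGrid

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "grid": {"nx": 128, "ny": 128, "dx": 2e-3, "dy": 2e-3, "dz": 2e-3, "nz": 1},
    "phantom": {"ellipses": "shepp-logan"},
    "electrodes": {"arc_fraction": 0.10, "current": 1e-3, "pulse_width": 30e-3},
    "signal": {"background_magnitude": 1.0, "noise_sd": 0.0,
               "delta_coefficients": [0.0, 0.0, 0.0], "voids": [],
               "void_magnitude_factor": 0.02},
    "mesh": {"max_area_pixels": 0.5, "boundary_vertices": 180,
             "level_fraction": 0.10},
    "phase": {"magnitude_floor_fraction": 0.10, "max_residue_fraction": 0.10,
              "continuity_threshold": 5.0},
    "denoise": {"enabled": False, "t1": 1.0, "t2": 2.0, "dt": 0.2, "s": 1.0,
                "refresh_tensor": True},
    "inpaint": {"enabled": True, "fraction": 0.10, "duration": 2.0,
                "per_slice": True},
    "reconstruct": {"mode": "auto", "boundary": "dirichlet",
                    "det_threshold": 1e-3, "boundary_margin": 4,
                    "mu0_scaling": True, "local_region": None,
                    "max_area_pixels": 0.5},
}

STAGES = ["simulate", "phase", "denoise", "inpaint", "mesh", "reconstruct"]


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    def merge(defaults, user, path):
        if not isinstance(user, dict):
            raise ValidationError(f"config section {path or '<root>'} must be a mapping")
        out = copy.deepcopy(defaults)
        for key, val in user.items():
            if key not in defaults:
                raise ValidationError(f"unknown config key {path + key!r}")
            if isinstance(defaults[key], dict):
                out[key] = merge(defaults[key], val, path + key + ".")
            else:
                out[key] = copy.deepcopy(val)
        return out

    return merge(DEFAULT_CONFIG, config or {}, "")


@dataclass
class RunManifest:
    """Per-stage provenance: parameters, content hashes, warnings, timing."""

    stages: list[dict] = field(default_factory=list)
    dirty: bool = False

    def record(self, name: str, params: dict, in_hash: str, out_hash: str,
               warns: list[str], seconds: float):
        self.stages.append({
            "stage": name, "params": params, "input_hash": in_hash,
            "output_hash": out_hash, "warnings": warns,
            "seconds": round(seconds, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        })

    def to_json(self) -> str:
        return json.dumps({"stages": self.stages, "dirty": self.dirty}, indent=1)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _phantom_from_config(cfg: dict, grid: SliceGrid) -> ph.ConductivityPhantom:
    spec = cfg["phantom"]["ellipses"]
    if spec == "shepp-logan":
        ells = None
    else:
        ells = [ph.EllipseSpec((e[0], e[1]), (e[2], e[3]), np.deg2rad(e[4]), e[5])
                for e in spec]
    return ph.make_shepp_logan(grid, ells)


def _electrodes_from_config(cfg: dict, poly: geo.DomainPolygon) -> ph.ElectrodeConfig:
    e = cfg["electrodes"]
    return ph.default_electrodes(poly, arc_fraction=e["arc_fraction"],
                                 current=e["current"],
                                 pulse_width=e["pulse_width"])


def _measured_magnitude(case: Case) -> np.ndarray:
    """Geometric-mean magnitude over polarities, averaged over injections."""
    mp = case.arrays["m_plus"]
    mm = case.arrays["m_minus"]
    return np.sqrt(np.abs(mp) * np.abs(mm)).mean(axis=0)   # (nz, ny, nx)


def _mesh_to_case(case: Case, mesh: geo.TriangleMesh):
    case.arrays["mesh_vertices"] = mesh.vertices
    case.arrays["mesh_triangles"] = mesh.triangles
    case.arrays["mesh_boundary_edges"] = mesh.boundary_edges
    case.attrs["mesh_boundary_markers"] = json.dumps(
        [list(m) for m in mesh.boundary_markers])
    case.attrs["mesh_max_area"] = mesh.max_area


def _mesh_from_case(case: Case) -> geo.TriangleMesh:
    markers = [tuple(m) for m in json.loads(case.attrs["mesh_boundary_markers"])]
    return geo.TriangleMesh(case.arrays["mesh_vertices"],
                            case.arrays["mesh_triangles"].astype(int),
                            case.arrays["mesh_boundary_edges"].astype(int),
                            markers,
                            max_area=float(case.attrs["mesh_max_area"]))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(case: Case, cfg: dict) -> Case:
    g = cfg["grid"]
    grid = SliceGrid(g["nx"], g["ny"], g["dx"], g["dy"], g["dz"])
    nz = int(g["nz"])
    phantom = _phantom_from_config(cfg, grid)
    poly0 = ph.domain_polygon(phantom, cfg["mesh"]["boundary_vertices"])
    electrodes = _electrodes_from_config(cfg, poly0)
    poly = geo.attach_electrodes(poly0, electrodes.arcs)
    mesh = geo.triangulate(poly, cfg["mesh"]["max_area_pixels"] * grid.dx * grid.dy)

    bz_true = np.empty((2, nz, grid.ny, grid.nx))
    valid = phantom.domain_mask.copy()
    for j in (1, 2):
        pot = ph.solve_forward_2d(phantom, electrodes, j, mesh)
        J = ph.current_density(phantom, pot)
        bz = ph.biot_savart_bz(J)          # z-invariant currents near the slice
        bz_true[j - 1, :] = bz[None]
        valid &= J.valid

    sig = cfg["signal"]
    M = np.full(grid.shape, float(sig["background_magnitude"]))
    M[~phantom.domain_mask] = 0.0
    xn, yn = ph._norm_coords(grid)
    for cx, cy, r in sig["voids"]:
        M[(xn - cx) ** 2 + (yn - cy) ** 2 <= r ** 2] *= sig["void_magnitude_factor"]
    a, b, c = sig["delta_coefficients"]
    X, Y = grid.meshgrid()
    delta = a + b * X / max(X.max(), 1e-300) + c * Y / max(Y.max(), 1e-300)

    rng = np.random.default_rng(int(cfg["seed"]))
    mp = np.empty((2, nz, grid.ny, grid.nx), dtype=complex)
    mm = np.empty_like(mp)
    for j in (0, 1):
        for k in range(nz):
            pair = ph.synthesize_complex_pair(
                M, delta, bz_true[j, k], electrodes.pulse_width,
                noise_sd=float(sig["noise_sd"]), rng=rng)
            mp[j, k] = pair.m_plus
            mm[j, k] = pair.m_minus

    case.set_grid(grid)
    case.attrs.update(
        nz=nz, Tc=electrodes.pulse_width, gamma=ph.GAMMA_HYDROGEN,
        current=electrodes.current, seed=int(cfg["seed"]),
        noise_sd=float(sig["noise_sd"]),
        kspace_convention=ph.KSPACE_CONVENTION,
        electrode_arcs=json.dumps(
            [[s.injection, s.polarity, s.anchor_angle, s.length]
             for s in electrodes.arcs]),
    )
    case.arrays.update(
        sigma=phantom.sigma, domain_mask=phantom.domain_mask,
        bz_true=bz_true, magnitude=M, delta=delta,
        m_plus=mp, m_minus=mm, sim_valid=valid,
    )
    return case


def stage_phase(case: Case, cfg: dict) -> Case:
    p = cfg["phase"]
    Tc = float(case.attrs["Tc"])
    gamma = float(case.attrs["gamma"])
    mp, mm = case.arrays["m_plus"], case.arrays["m_minus"]
    nj, nz = mp.shape[:2]
    grid = case.grid()

    Mmeas = _measured_magnitude(case)                       # (nz, ny, nx)
    bz = np.empty(mp.shape, dtype=float)
    masks = np.ones(mp.shape[1:], dtype=bool)
    for j in range(nj):
        for k in range(nz):
            mmax = float(Mmeas[k].max())
            floor = (p["magnitude_floor_fraction"] * mmax) ** 2
            b, mask = phs.bz_from_pair(
                mp[j, k], mm[j, k], Tc, gamma,
                magnitude_floor=floor,
                max_residue_fraction=p["max_residue_fraction"])
            bz[j, k] = np.nan_to_num(b)
            masks[k] &= mask

    domain = (case.arrays["domain_mask"].astype(bool)
              if "domain_mask" in case.arrays
              else binary_fill_holes(masks.all(axis=0)))
    valid = domain & masks.all(axis=0)
    case.arrays.update(bz_measured=bz, bz_valid=valid,
                       magnitude_measured=Mmeas)
    vol = ph.BzVolume(grid, bz, valid)
    reports = [phs.verify_z_continuity(vol, j, p["continuity_threshold"])
               for j in range(nj)]
    mode = "3d" if all(r.recommended_mode == "3d" for r in reports) else "2d"
    case.attrs["continuity_report"] = json.dumps(
        {"injections": [r.to_dict() for r in reports], "recommended_mode": mode})
    return case


def _defect(case: Case, cfg: dict, slice_index: int) -> inp.DefectMask:
    Mmeas = case.arrays["magnitude_measured"]
    domain = case.arrays["domain_mask"].astype(bool)
    M = Mmeas[slice_index] if cfg["inpaint"]["per_slice"] else Mmeas.max(axis=0)
    return inp.detect_defected_region(M, domain, cfg["inpaint"]["fraction"])


def stage_denoise(case: Case, cfg: dict) -> Case:
    d = cfg["denoise"]
    if not d["enabled"]:
        return case
    settings = dn.DiffusionSettings(T1=d["t1"], T2=d["t2"], dt=d["dt"],
                                    s=d["s"], refresh_tensor=d["refresh_tensor"])
    bz = case.arrays["bz_measured"].copy()
    valid = case.arrays["bz_valid"].astype(bool)
    for k in range(bz.shape[1]):
        defect = _defect(case, cfg, k)
        mask = valid & ~defect.mask
        for j in range(bz.shape[0]):
            bz[j, k] = dn.ramp_preserving_denoise(bz[j, k], settings, mask)
    case.arrays["bz_measured"] = bz
    return case


def stage_inpaint(case: Case, cfg: dict) -> Case:
    c = cfg["inpaint"]
    if not c["enabled"]:
        return case
    bz = case.arrays["bz_measured"].copy()
    valid = case.arrays["bz_valid"].astype(bool)
    domain = case.arrays["domain_mask"].astype(bool)
    defects = np.zeros(bz.shape[1:], dtype=bool)
    for k in range(bz.shape[1]):
        defect = _defect(case, cfg, k)
        defects[k] = defect.mask
        for j in range(bz.shape[0]):
            repaired = inp.harmonic_inpaint(bz[j, k], defect,
                                            valid_mask=valid | defect.mask)
            bz[j, k] = inp.isotropic_smooth_defect(repaired, defect,
                                                   duration=c["duration"])
    case.arrays["bz_measured"] = bz
    case.arrays["defect_mask"] = defects
    case.arrays["bz_valid"] = domain      # repaired: whole domain usable
    return case


def stage_mesh(case: Case, cfg: dict) -> Case:
    grid = case.grid()
    Mmeas = case.arrays["magnitude_measured"]
    poly = geo.segment_domain(Mmeas.max(axis=0), grid,
                              level_fraction=cfg["mesh"]["level_fraction"])
    arcs = [geo.ElectrodeArcSpec(int(j), pol, float(ang), float(ln))
            for j, pol, ang, ln in json.loads(case.attrs["electrode_arcs"])]
    poly = geo.attach_electrodes(poly, arcs)
    mesh = geo.triangulate(
        poly, cfg["mesh"]["max_area_pixels"] * grid.dx * grid.dy)
    _mesh_to_case(case, mesh)
    return case


def stage_reconstruct(case: Case, cfg: dict) -> Case:
    r = cfg["reconstruct"]
    grid = case.grid()
    mesh = _mesh_from_case(case)
    domain = case.arrays["domain_mask"].astype(bool)

    # sigma0 = 1 forward solves on the measured geometry
    sigma0 = ph.ConductivityPhantom(grid, np.ones(grid.shape), domain)
    arcs = [geo.ElectrodeArcSpec(int(j), pol, float(ang), float(ln))
            for j, pol, ang, ln in json.loads(case.attrs["electrode_arcs"])]
    electrodes = ph.ElectrodeConfig(arcs, current=float(case.attrs["current"]),
                                    pulse_width=float(case.attrs["Tc"]))
    pots = [ph.solve_forward_2d(sigma0, electrodes, j, mesh) for j in (1, 2)]
    J0 = [ph.current_density(sigma0, pot) for pot in pots]
    a_field = rc.build_a_matrix(*J0, det_threshold=r["det_threshold"])

    mode = r["mode"]
    if mode == "auto":
        rep = json.loads(case.attrs.get("continuity_report", "{}"))
        mode = rep.get("recommended_mode", "2d")

    valid = case.arrays["bz_valid"].astype(bool) & J0[0].valid & J0[1].valid
    if "defect_mask" in case.arrays:
        valid &= ~case.arrays["defect_mask"].any(axis=0)
    margin = int(r["boundary_margin"])
    if margin > 0:
        valid = binary_erosion(valid, iterations=margin)
    vol = ph.BzVolume(grid, case.arrays["bz_measured"], valid)

    nz = vol.nz
    sl = nz // 2 if mode == "3d" else 0
    log_raster = np.empty((nz, grid.ny, grid.nx))
    for k in range(nz):
        ks = min(max(k, 1), nz - 2) if mode == "3d" else k
        lap1 = rc.laplacian_bz(vol, ks, mode, injection=0, force=True)
        lap2 = rc.laplacian_bz(vol, ks, mode, injection=1, force=True)
        img = rc.harmonic_bz_reconstruct(
            mesh, a_field, lap1, lap2, grid,
            mu0_scaling=bool(r["mu0_scaling"]), boundary=r["boundary"])
        log_raster[k] = np.log(img.raster)
    case.arrays["log_sigma_raster"] = log_raster
    case.arrays["sigma_raster"] = np.exp(log_raster)

    if r["local_region"] is not None:
        xn_poly = np.asarray(r["local_region"], dtype=float)
        cx, cy = grid.center()
        half = 0.5 * max(grid.dx * (grid.nx - 1), grid.dy * (grid.ny - 1))
        region = geo.LocalRegion(np.column_stack(
            [cx + half * xn_poly[:, 0], cy + half * xn_poly[:, 1]]))
        defect = (case.arrays["defect_mask"].any(axis=0)
                  if "defect_mask" in case.arrays else None)
        local_raster = np.empty((nz, grid.ny, grid.nx))
        for k in range(nz):
            ks = min(max(k, 1), nz - 2) if mode == "3d" else k
            lap1 = rc.laplacian_bz(vol, ks, mode, injection=0, force=True)
            lap2 = rc.laplacian_bz(vol, ks, mode, injection=1, force=True)
            loc = rc.local_harmonic_bz(
                region, a_field, lap1, lap2, grid,
                max_area=r["max_area_pixels"] * grid.dx * grid.dy,
                defect_mask=defect, mu0_scaling=bool(r["mu0_scaling"]),
                boundary=r["boundary"])
            local_raster[k] = np.log(loc.raster)
        case.arrays["log_sigma_local"] = local_raster
    return case


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "phase": stage_phase,
    "denoise": stage_denoise,
    "inpaint": stage_inpaint,
    "mesh": stage_mesh,
    "reconstruct": stage_reconstruct,
}


def run_pipeline(config: dict, case: Case | None = None,
                 stages: list[str] | None = None) -> tuple[Case, RunManifest]:
    """Run the requested stages in order on a (possibly fresh) case.

    On a stage failure the exception is re-raised with the stage named and
    the partial case is flagged dirty in the manifest.
    """
    cfg = validate_config(config)
    if stages is None:
        stages = STAGES
    unknown = set(stages) - set(STAGE_FUNCS)
    if unknown:
        raise ValidationError(f"unknown stages {sorted(unknown)}")
    if case is None:
        case = Case()
    manifest = RunManifest()
    for name in stages:
        t0 = time.time()
        in_hash = case.content_hash()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                case = STAGE_FUNCS[name](case, cfg)
            except Exception as exc:
                manifest.dirty = True
                case.attrs["manifest"] = manifest.to_json()
                raise type(exc)(f"stage {name!r} failed: {exc}") from exc
        manifest.record(name, cfg.get(name, {}), in_hash, case.content_hash(),
                        [str(w.message) for w in caught], time.time() - t0)
    case.attrs["manifest"] = manifest.to_json()
    return case, manifest
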