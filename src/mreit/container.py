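"""Single-file named-array container for a whole MREIT case.

One HDF5 file accumulates every stage's output (phantom, simulated images,
measured Bz, masks, mesh, reconstruction) together with scalar metadata,
mirroring a single-project workflow.  Magnitude and reconstruction rasters
can additionally be exported as NIfTI volumes with the affine built from
the pixel spacings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import ValidationError
from .grids import SliceGrid

log = logging.getLogger(__name__)

SCHEMA_VERSION = 2

#: Renames applied when loading an older container (old key -> new key).
MIGRATIONS: dict[int, dict[str, str]] = {
    1: {"M": "magnitude", "bz": "bz_measured"},
}


@dataclass
class Case:
    """In-memory mirror of the container: named arrays plus scalar metadata."""

    arrays: dict[str, np.ndarray] = field(default_factory=dict)
    attrs: dict[str, object] = field(default_factory=dict)

    def grid(self) -> SliceGrid:
        a = self.attrs
        return SliceGrid(int(a["nx"]), int(a["ny"]), float(a["dx"]),
                         float(a["dy"]), float(a["dz"]),
                         tuple(json.loads(a.get("origin", "[0.0, 0.0]"))))

    def set_grid(self, grid: SliceGrid):
        self.attrs.update(nx=grid.nx, ny=grid.ny, dx=grid.dx, dy=grid.dy,
                          dz=grid.dz, origin=json.dumps(list(grid.origin)))

    def content_hash(self) -> str:
        """SHA-256 over all arrays and non-volatile metadata."""
        h = hashlib.sha256()
        for key in sorted(self.arrays):
            h.update(key.encode())
            arr = np.ascontiguousarray(self.arrays[key])
            h.update(str(arr.dtype).encode())
            h.update(str(arr.shape).encode())
            h.update(arr.tobytes())
        for key in sorted(self.attrs):
            if key in ("manifest",):
                continue
            h.update(key.encode())
            h.update(str(self.attrs[key]).encode())
        return h.hexdigest()


def save_case(case: Case, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for key, val in case.attrs.items():
            f.attrs[key] = val
        for key, arr in case.arrays.items():
            f.create_dataset(key, data=np.asarray(arr))


def load_case(path) -> Case:
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", 0))
        if version > SCHEMA_VERSION:
            raise ValidationError(
                f"container schema {version} is newer than supported "
                f"{SCHEMA_VERSION}; upgrade the package")
        arrays = {key: f[key][()] for key in f.keys()}
        attrs = {key: f.attrs[key] for key in f.attrs.keys()
                 if key != "schema_version"}
    while version < SCHEMA_VERSION:
        if version not in MIGRATIONS:
            raise ValidationError(
                f"no migration path from container schema {version}")
        renames = MIGRATIONS[version]
        log.info("migrating container schema %d -> %d (%d fields)",
                 version, version + 1, len(renames))
        for old, new in renames.items():
            if old in arrays:
                arrays[new] = arrays.pop(old)
        version += 1
    return Case(arrays, attrs)


def nifti_affine(grid: SliceGrid) -> np.ndarray:
    aff = np.diag([grid.dx, grid.dy, grid.dz, 1.0])
    aff[0, 3], aff[1, 3] = grid.origin
    return aff


def export_nifti(case: Case, key: str, path) -> None:
    """Write one (possibly multi-slice) array as a NIfTI volume."""
    import nibabel as nib

    if key not in case.arrays:
        raise ValidationError(f"array {key!r} not in container")
    arr = np.asarray(case.arrays[key], dtype=float)
    if arr.ndim == 2:
        arr = arr[..., None]
    elif arr.ndim == 3:            # (nz, ny, nx) -> (nx, ny, nz)
        arr = np.moveaxis(arr, 0, -1)
    arr = np.swapaxes(arr, 0, 1)   # (ny, nx, nz) -> (nx, ny, nz)
    nib.save(nib.Nifti1Image(arr, nifti_affine(case.grid())), str(path))


def import_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume back to (nz, ny, nx) with its spacings."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim == 2:
        data = data[..., None]
    data = np.moveaxis(np.swapaxes(data, 0, 1), -1, 0)
    zooms = img.header.get_zooms()[:3]
    return data, (float(zooms[0]), float(zooms[1]), float(zooms[2]))
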