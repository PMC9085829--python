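"""File I/O: TIFF stacks with spacing sidecars, PLY meshes, CSV tables.

Voxel spacing travels in a YAML sidecar (``<stack>.yaml``, key
``voxel_size_um: [z, y, x]``) next to each TIFF rather than in TIFF tags,
avoiding tag-dialect ambiguity; when both a sidecar and an explicit
override are given, the override wins.  All lengths are µm, volumes µm³.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh as _trimesh
import yaml

from .types import SurfaceMesh, VolumeStack

__all__ = [
    "read_stack", "write_stack",
    "read_mesh", "write_mesh",
    "read_labels", "write_labels",
    "write_features", "read_features",
    "write_json_sidecar",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_stack(path, volume: VolumeStack, dtype=np.uint16) -> None:
    """Write a multi-page TIFF (one page per z-plane) plus a spacing sidecar."""
    path = Path(path)
    data = volume.data
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        data = np.clip(np.rint(data), info.min, info.max).astype(dtype)
    else:
        data = data.astype(dtype)
    tifffile.imwrite(path, data)
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(
            {"voxel_size_um": list(volume.voxel_size), "provenance": volume.provenance},
            fh,
        )


def read_stack(path, spacing=None) -> VolumeStack:
    """Read a single-channel multi-page TIFF into a :class:`VolumeStack`.

    Spacing comes from the explicit ``spacing`` override (z, y, x µm) or
    from the YAML sidecar; with neither, the read is refused.  8/16-bit
    data are promoted losslessly to float32.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel z-stack, got array of ndim {data.ndim}"
        )
    provenance = str(path)
    if spacing is None:
        sc = _sidecar_path(path)
        if not sc.exists():
            raise ValueError(
                f"{path}: no voxel spacing available; provide a spacing override "
                f"or a sidecar {sc.name}"
            )
        with open(sc) as fh:
            meta = yaml.safe_load(fh)
        spacing = meta["voxel_size_um"]
        provenance = meta.get("provenance", provenance)
    return VolumeStack(data.astype(np.float32), tuple(spacing), provenance=provenance)


def write_labels(path, labels) -> None:
    path = Path(path)
    tifffile.imwrite(path, labels.labels.astype(np.int32))
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump({"voxel_size_um": list(labels.voxel_size)}, fh)


def read_labels(path, spacing=None):
    from .types import LabelMap

    path = Path(path)
    data = tifffile.imread(path)
    if spacing is None:
        with open(_sidecar_path(path)) as fh:
            spacing = yaml.safe_load(fh)["voxel_size_um"]
    return LabelMap(np.asarray(data, dtype=np.int32), tuple(spacing))


# ---------------------------------------------------------------------------
# PLY meshes
# ---------------------------------------------------------------------------

def _validate_ply_header(path: Path) -> str:
    """Light validation of a PLY header; returns the format string."""
    with open(path, "rb") as fh:
        head = fh.read(4096)
    lines = head.split(b"\n")
    if not lines or lines[0].strip() != b"ply":
        raise ValueError(f"{path}: line 1: not a PLY file (missing 'ply' magic)")
    fmt = None
    for i, ln in enumerate(lines[1:], start=2):
        s = ln.strip()
        if s.startswith(b"format"):
            parts = s.split()
            if len(parts) < 3 or parts[1] not in (
                b"ascii", b"binary_little_endian", b"binary_big_endian"
            ):
                raise ValueError(f"{path}: line {i}: malformed PLY format line {s!r}")
            fmt = parts[1].decode()
        if s == b"end_header":
            if fmt is None:
                raise ValueError(f"{path}: line {i}: header ended without a format line")
            return fmt
    raise ValueError(f"{path}: header has no end_header line")


def write_mesh(path, mesh: SurfaceMesh, encoding: str = "binary") -> None:
    """Write a mesh as PLY (``encoding`` 'ascii' or 'binary')."""
    if encoding not in ("ascii", "binary"):
        raise ValueError("encoding must be 'ascii' or 'binary'")
    tm = _trimesh.Trimesh(vertices=mesh.vertices[:, ::-1], faces=mesh.faces, process=False)
    data = tm.export(file_type="ply", encoding=encoding)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def read_mesh(path) -> SurfaceMesh:
    """Read an ascii or binary-little-endian PLY into a :class:`SurfaceMesh`.

    Vertices are mapped from the file's (x, y, z) to the package's
    (z, y, x) µm convention.  Non-triangular faces are refused.
    """
    path = Path(path)
    _validate_ply_header(path)
    tm = _trimesh.load(path, file_type="ply", process=False)
    faces = np.asarray(tm.faces)
    # trimesh triangulates quads silently; detect via the raw face counts
    raw = getattr(tm, "metadata", {}).get("_ply_raw", None)
    if raw is not None:
        try:
            vi = raw["face"]["data"]["vertex_indices"]
            if vi.dtype.names and "f0" in vi.dtype.names:
                counts = np.asarray(vi["f0"])
            else:  # object array of index lists (mixed polygon sizes)
                counts = np.array([len(f) for f in np.atleast_1d(vi)])
            if (counts != 3).any():
                raise ValueError(f"{path}: PLY contains non-triangular faces")
        except (KeyError, IndexError, TypeError, AttributeError):
            pass
    mesh = SurfaceMesh(np.asarray(tm.vertices)[:, ::-1], faces.astype(np.int64))
    mesh.closed = mesh.is_watertight()
    return mesh


# ---------------------------------------------------------------------------
# tables and sidecars
# ---------------------------------------------------------------------------

def write_features(path, features: pd.DataFrame) -> None:
    """Feature CSV with the frozen header (id, volume_um3, ..., orientation)."""
    features.to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json_sidecar(path, params: dict) -> None:
    """Serialize effective run parameters next to an output for provenance."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, default=default)
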