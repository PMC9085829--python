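"""Core containers shared across the pipeline.

Conventions used throughout the package:

* Array axis order is ``(z, y, x)``, 0-based.
* World coordinates are in micrometres (µm); the world position of voxel
  ``(i, j, k)`` is ``(i*dz, j*dy, k*dx)`` where ``(dz, dy, dx)`` is the
  voxel spacing.  Volumes are µm³, lengths and diameters µm.
* Mesh vertices are stored in ``(z, y, x)`` µm world coordinates so that
  meshes and volumes share one frame; PLY I/O maps them to the
  conventional ``x, y, z`` properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeStack", "LabelMap", "SurfaceMesh"]


@dataclass
class VolumeStack:
    """A single-channel 3D intensity grid with anisotropic voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Non-negative intensities.
    voxel_size : tuple of float
        ``(dz, dy, dx)`` spacing in µm; all entries must be positive.
    provenance : str
        Free-text description of where the stack came from.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive values (z,y,x), got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent per axis, ``(n-1) * spacing``, in µm."""
        return tuple((n - 1) * s for n, s in zip(self.data.shape, self.voxel_size))

    def is_isotropic(self, rtol: float = 1e-6) -> bool:
        dz, dy, dx = self.voxel_size
        return abs(dz - dx) <= rtol * dx and abs(dy - dx) <= rtol * dx


@dataclass
class LabelMap:
    """Integer instance segmentation aligned voxel-for-voxel with a stack.

    ``0`` is background; instances are labelled with consecutive positive
    integers ``1..K``.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        vs = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be positive")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_instances(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def ids(self) -> np.ndarray:
        out = np.unique(self.labels)
        return out[out > 0]

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


@dataclass
class SurfaceMesh:
    """Triangulated surface for one object, vertices in (z, y, x) µm."""

    vertices: np.ndarray
    faces: np.ndarray
    closed: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must have shape (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be triangles, shape (m, 3)")
        if not np.isfinite(self.vertices).all():
            raise ValueError("vertex coordinates must be finite")
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.closed, dict(self.metadata))

    def edges(self) -> np.ndarray:
        """All directed edges (3 per face), shape (3m, 2)."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]], axis=0)

    def boundary_edges(self) -> np.ndarray:
        """Undirected edges that belong to exactly one face."""
        e = np.sort(self.edges(), axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def is_watertight(self) -> bool:
        """True when every undirected edge is shared by exactly two faces."""
        if len(self.faces) == 0:
            return False
        e = np.sort(self.edges(), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool((counts == 2).all())

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    @property
    def area(self) -> float:
        return float(self.triangle_areas().sum())
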