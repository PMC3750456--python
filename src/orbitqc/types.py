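"""Core domain containers for orbital volumetry and shape analysis.

All physical coordinates are millimetres in a single fixed patient-space
convention: +x toward the patient's right, +y anterior, +z superior
(RAS-like). Readers are responsible for reorienting header conventions into
this frame. A voxel is a cell of size ``spacing`` centred at
``origin + index * spacing``; masks refer to cell centers, so
volume = count x cell volume exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

__all__ = [
    "VolumeImage",
    "OrbitMask",
    "SurfaceMesh",
    "LandmarkSet",
    "RigidTransform",
    "Plane",
    "SliceThicknessWarning",
]

#: maximum axial slice thickness (mm) before a data-quality warning is raised
MAX_SLICE_THICKNESS_MM = 1.0


class SliceThicknessWarning(UserWarning):
    """Volume slice spacing exceeds the supported maximum of 1 mm."""


@dataclass
class VolumeImage:
    """A 3-D scalar image on a regular grid.

    Parameters
    ----------
    data
        Intensity array indexed ``[i, j, k]`` along (x, y, z). HU-like for
        CT; arbitrary units for CBCT.
    spacing
        Voxel edge lengths ``(sx, sy, sz)`` in mm. Strictly positive.
    origin
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)
    axis_convention: str = "RAS"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise ValueError(
                f"volume data must be 3-D with shape >= 2 per axis, got {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        if self.spacing[2] > MAX_SLICE_THICKNESS_MM:
            warnings.warn(
                f"slice thickness {self.spacing[2]:.3g} mm exceeds the supported "
                f"maximum of {MAX_SLICE_THICKNESS_MM} mm; volumetry accuracy degrades",
                SliceThicknessWarning,
                stacklevel=2,
            )

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def index_to_world(self, idx) -> np.ndarray:
        """World coordinates (mm) of voxel center(s) ``idx`` (…, 3)."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, xyz) -> np.ndarray:
        """Fractional voxel index of world point(s) ``xyz`` (…, 3)."""
        return (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains(self, xyz) -> np.ndarray:
        """True where world point(s) fall inside the gridded domain."""
        idx = self.world_to_index(xyz)
        shp = np.asarray(self.data.shape)
        return np.all((idx >= -0.5) & (idx <= shp - 0.5), axis=-1)


@dataclass
class OrbitMask:
    """Binary voxel mask of one orbital cavity, congruent with a VolumeImage."""

    mask: np.ndarray
    side: str
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)
    clipped: bool = False

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("orbit mask must be 3-D")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (mm) of all set voxel centers, (n, 3)."""
        idx = np.argwhere(self.mask)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass
class SurfaceMesh:
    """Triangulated surface with vertices in mm.

    ``scalars`` is an optional per-vertex channel (e.g. signed deviation in
    mm); ``colors`` an optional per-vertex RGB array (float in [0, 1] or
    uint8).
    """

    vertices: np.ndarray
    faces: np.ndarray
    scalars: Optional[np.ndarray] = None
    colors: Optional[np.ndarray] = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("faces index out of vertex range")
        if self.scalars is not None:
            self.scalars = np.asarray(self.scalars, dtype=float)
            if self.scalars.shape[0] != len(self.vertices):
                raise ValueError("scalar channel length must match vertex count")
        if self.colors is not None:
            self.colors = np.asarray(self.colors)
            if self.colors.shape[0] != len(self.vertices):
                raise ValueError("color channel length must match vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(n_faces, 3, 3) triangle vertex coordinates."""
        return self.vertices[self.faces]

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        if normalize:
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            n = n / norm
        return n

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(normalize=False), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def signed_volume(self) -> float:
        """Enclosed volume (mm^3) by the divergence theorem.

        Positive for a closed mesh with outward-oriented faces.
        """
        tri = self.triangles()
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric (one-third) vertex area weights, (n_vertices,)."""
        fa = self.face_areas() / 3.0
        va = np.zeros(len(self.vertices))
        for c in range(3):
            np.add.at(va, self.faces[:, c], fa)
        return va

    def drop_degenerate_faces(self, min_area: float = 1e-12) -> "SurfaceMesh":
        keep = self.face_areas() > min_area
        return SurfaceMesh(self.vertices, self.faces[keep], self.scalars, self.colors)

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, tm) -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64))


@dataclass
class LandmarkSet:
    """Named anatomical landmarks (mm) used for clipping and mirroring.

    ``sides`` maps ``'left'``/``'right'`` to dicts holding at least the rim
    points ``L`` (lateral orbital rim) and ``M`` (medial orbital rim), and
    optionally ``apex``. ``midline`` holds >= 3 points near the midsagittal
    plane for mirror-plane estimation.
    """

    sides: Dict[str, Dict[str, np.ndarray]] = field(default_factory=dict)
    midline: Optional[np.ndarray] = None

    def __post_init__(self):
        for side, pts in self.sides.items():
            if side not in ("left", "right"):
                raise ValueError(f"unknown side label {side!r}")
            for name, p in pts.items():
                pts[name] = np.asarray(p, dtype=float).reshape(3)
            if "L" in pts and "M" in pts and np.allclose(pts["L"], pts["M"]):
                raise ValueError(f"L and M coincide on side {side!r}")
        if self.midline is not None:
            self.midline = np.asarray(self.midline, dtype=float).reshape(-1, 3)

    def require(self, side: str, names=("L", "M")) -> None:
        if side not in self.sides:
            raise ValueError(f"no landmarks for side {side!r}")
        for n in names:
            if n not in self.sides[side]:
                raise ValueError(f"{n}_{side} required")

    def require_midline(self, minimum: int = 3) -> None:
        if self.midline is None or len(self.midline) < minimum:
            raise ValueError(
                f"at least {minimum} midline points required for mirror-plane estimation"
            )

    def validate_bounds(self, volume: VolumeImage) -> None:
        pts = [p for d in self.sides.values() for p in d.values()]
        if self.midline is not None:
            pts.extend(self.midline)
        if pts and not bool(np.all(volume.contains(np.asarray(pts)))):
            raise ValueError("landmark outside volume bounds")


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R x + t (rotation + translation, mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal (RtR != I at 1e-9)")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class Plane:
    """Oriented plane given by a unit normal and a point on the plane (mm)."""

    normal: np.ndarray
    point: np.ndarray

    def __post_init__(self):
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise ValueError("plane normal must be nonzero")
        if abs(n - 1.0) > 1e-12:
            self.normal = self.normal / n
        self.point = np.asarray(self.point, dtype=float).reshape(3)

    def signed_distance(self, points) -> np.ndarray:
        """Signed distance (mm); positive on the side the normal points to."""
        return (np.asarray(points, dtype=float) - self.point) @ self.normal

    def reflect(self, points) -> np.ndarray:
        """Mirror point(s) across the plane."""
        d = self.signed_distance(points)
        return np.asarray(points, dtype=float) - 2.0 * np.multiply.outer(d, self.normal)

    def flipped(self) -> "Plane":
        return Plane(-self.normal, self.point)
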