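"""Mirror-template construction and ROI-restricted rigid surface registration.

The unaffected orbit is extracted as a surface, reflected across the
estimated midsagittal plane, and rigidly aligned to the reconstructed side
with a trimmed point-to-plane iterative closest point (ICP) scheme whose
correspondences are restricted to an ROI of unaffected bone (orbital roof
and intact walls). Restricting the ROI prevents the matcher from absorbing
the reconstruction deviation into the alignment, which would mask exactly
the error the deviation map is meant to show.

Registration is rigid only — the template is the patient's own mirrored
anatomy, so scaling or deformation would destroy its meaning — and fully
deterministic: no randomized correspondence sampling, and exact nearest-
triangle ties resolve to the smallest triangle index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .distance import SurfaceDistanceQuery
from .types import LandmarkSet, OrbitMask, Plane, RigidTransform, SurfaceMesh

__all__ = [
    "RegistrationParams",
    "RoiSelector",
    "extract_surface",
    "estimate_midsagittal",
    "reflect_mesh",
    "landmark_prealign",
    "icp_register",
]


@dataclass
class RegistrationParams:
    """Trimmed point-to-plane ICP parameters.

    ``trim_fraction`` drops that fraction of worst correspondences each
    iteration; ``max_correspondence_mm`` additionally rejects pairs farther
    than this. ``max_points`` caps the number of ROI vertices used
    (deterministic uniform stride).
    """

    max_iterations: int = 100
    convergence_tol_mm: float = 1e-4
    trim_fraction: float = 0.1
    max_correspondence_mm: float = 5.0
    max_points: int = 4000

    def __post_init__(self):
        if not (0.0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.convergence_tol_mm <= 0 or self.max_correspondence_mm <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class RoiSelector:
    """Per-vertex inclusion mask on the template mesh (True = match)."""

    include: np.ndarray
    min_vertices: int = 100

    def __post_init__(self):
        self.include = np.asarray(self.include, dtype=bool)
        if self.include.sum() < self.min_vertices:
            raise ValueError(
                f"ROI keeps only {int(self.include.sum())} vertices "
                f"(minimum {self.min_vertices}); registration would be unstable"
            )

    @classmethod
    def from_labels(cls, labels: np.ndarray, exclude=("rim", "unassigned"),
                    exclude_walls=("floor",), min_vertices: int = 100) -> "RoiSelector":
        """Keep roof and unaffected-wall vertices; drop reconstructed walls.

        ``exclude_walls`` names walls whose nine-region labels are all
        excluded (e.g. ``('floor',)`` drops floor_anterior/central/posterior).
        """
        labels = np.asarray(labels)
        keep = ~np.isin(labels, list(exclude))
        for wall in exclude_walls:
            keep &= ~np.char.startswith(labels.astype(str), wall + "_")
        return cls(include=keep, min_vertices=min_vertices)


def extract_surface(mask: OrbitMask, spacing=None, origin=None,
                    smooth_sigma_vox: float = 0.0) -> SurfaceMesh:
    """Triangulated isosurface of a binary mask (marching cubes at 0.5).

    ``smooth_sigma_vox`` optionally Gaussian-smooths the indicator field
    before extraction, giving sub-voxel surface accuracy on smooth anatomy
    at the cost of rounding features smaller than ~2 voxels. Faces are
    oriented outward (positive enclosed volume).
    """
    from scipy.ndimage import gaussian_filter
    from skimage.measure import marching_cubes

    if not mask.mask.any():
        raise ValueError("cannot extract a surface from an empty mask")
    spacing = mask.spacing if spacing is None else spacing
    origin = mask.origin if origin is None else origin
    field3 = np.pad(mask.mask, 2).astype(np.float32)
    if smooth_sigma_vox > 0:
        field3 = gaussian_filter(field3, smooth_sigma_vox)
    verts, faces, _, _ = marching_cubes(field3, level=0.5, spacing=tuple(spacing))
    verts = verts - 2 * np.asarray(spacing) + np.asarray(origin)
    mesh = SurfaceMesh(vertices=verts, faces=faces).drop_degenerate_faces()
    if mesh.signed_volume() < 0:
        mesh = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def estimate_midsagittal(landmarks: LandmarkSet) -> Plane:
    """Least-squares plane through the midline landmarks.

    Requires >= 3 non-collinear midline points; the normal is oriented
    left-to-right (+x).
    """
    landmarks.require_midline(3)
    pts = landmarks.midline
    centroid = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - centroid)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("midline points are collinear; plane is undetermined")
    normal = vt[2]
    if normal[0] < 0:
        normal = -normal
    return Plane(normal=normal, point=centroid)


def reflect_mesh(mesh: SurfaceMesh, plane: Plane) -> SurfaceMesh:
    """Mirror a mesh across a plane, flipping winding to stay outward."""
    verts = plane.reflect(mesh.vertices)
    faces = mesh.faces[:, ::-1]
    return SurfaceMesh(vertices=verts, faces=faces, scalars=mesh.scalars,
                       colors=mesh.colors)


def landmark_prealign(source_pts, target_pts) -> RigidTransform:
    """Closed-form least-squares rigid fit mapping paired landmarks.

    Kabsch algorithm (rotation + translation, no scaling); needs >= 3
    non-degenerate point pairs.
    """
    src = np.asarray(source_pts, dtype=float).reshape(-1, 3)
    dst = np.asarray(target_pts, dtype=float).reshape(-1, 3)
    if len(src) != len(dst) or len(src) < 3:
        raise ValueError("need >= 3 paired landmarks")
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rotation=r, translation=dc - r @ sc)


def _solve_point_to_plane(p, q, n):
    """One linearized point-to-plane step: find (w, t) minimizing
    sum ((p + w x p + t - q) . n)^2."""
    c = np.cross(p, n)
    a = np.hstack([c, n])                     # (m, 6)
    b = np.einsum("ij,ij->i", q - p, n)
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    w, t = x[:3], x[3:]
    theta = np.linalg.norm(w)
    if theta < 1e-14:
        r = np.eye(3)
    else:
        k = w / theta
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        r = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)
    return RigidTransform(rotation=r, translation=t)


def icp_register(template: SurfaceMesh, roi: RoiSelector, target: SurfaceMesh,
                 params: RegistrationParams | None = None,
                 initial: RigidTransform | None = None):
    """ROI-restricted trimmed point-to-plane ICP.

    Finds the rigid transform aligning the template's ROI vertices to the
    target surface. Returns ``(transform, report)`` where ``report`` holds
    mean/RMS/max ROI distance, pair counts, iteration count, and a
    convergence flag. Emits a warning (and returns the best transform) on
    non-convergence.
    """
    params = params or RegistrationParams()
    initial = initial or RigidTransform.identity()
    if roi.include.shape[0] != template.n_vertices:
        raise ValueError("ROI mask length must match template vertex count")

    pts = template.vertices[roi.include]
    if len(pts) > params.max_points:
        stride = int(np.ceil(len(pts) / params.max_points))
        pts = pts[::stride]

    query = SurfaceDistanceQuery(target)
    transform = initial
    prev_mean = np.inf
    converged = False
    iterations = 0
    mean_d = rms_d = max_d = np.nan
    n_used = 0

    for iterations in range(1, params.max_iterations + 1):
        moved = transform.apply(pts)
        dist, closest, tidx, _ = query.query(moved)
        keep = dist <= params.max_correspondence_mm
        if params.trim_fraction > 0 and keep.sum() > 0:
            n_keep = int(np.ceil(keep.sum() * (1.0 - params.trim_fraction)))
            order = np.argsort(dist[keep], kind="stable")
            kept_idx = np.flatnonzero(keep)[order[:n_keep]]
        else:
            kept_idx = np.flatnonzero(keep)
        if len(kept_idx) < 6:
            raise ValueError("too few ICP correspondences within max_correspondence_mm")

        p = moved[kept_idx]
        q = closest[kept_idx]
        n = query.mesh.face_normals()[tidx[kept_idx]]
        mean_d = float(dist[kept_idx].mean())
        rms_d = float(np.sqrt((dist[kept_idx] ** 2).mean()))
        max_d = float(dist[kept_idx].max())
        n_used = int(len(kept_idx))
        if abs(prev_mean - mean_d) < params.convergence_tol_mm:
            converged = True
            break
        prev_mean = mean_d
        step = _solve_point_to_plane(p, q, n)
        transform = step @ transform

    if not converged:
        warnings.warn(
            f"ICP did not converge within {params.max_iterations} iterations "
            f"(last mean ROI distance {mean_d:.4f} mm); returning best transform",
            RuntimeWarning,
        )
    report = {
        "mean_mm": mean_d,
        "rms_mm": rms_d,
        "max_mm": max_d,
        "n_pairs": n_used,
        "iterations": iterations,
        "converged": bool(converged),
    }
    return transform, report
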