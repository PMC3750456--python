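"""Anatomical partitioning of the orbital surface and implant coverage.

The orbital walls are classified by angular sector around the rim-center
-> apex axis (floor inferior, medial toward the midsagittal plane, lateral
opposite, roof superior; 45-degree half-angles by default) and each wall is
subdivided into anterior, central and posterior thirds of normalized
orbital depth, yielding the nine wall regions used for deviation and
implant reporting. The medial-wall/floor transition zone — clinically the
critical reconstruction area — is additionally reported as a boundary band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .types import LandmarkSet, Plane, SurfaceMesh, VolumeImage

__all__ = [
    "RegionLabeling",
    "ImplantMask",
    "label_walls",
    "split_thirds",
    "label_regions",
    "segment_implant",
    "implant_coverage",
    "transition_zone_mask",
]


@dataclass
class RegionLabeling:
    """Per-vertex anatomical labels plus the frame they were derived in.

    After :func:`label_walls` the labels are wall-level (medial / floor /
    lateral / roof / rim); :func:`split_thirds` refines the three walls
    into nine depth regions (e.g. ``floor_anterior``). ``phi_deg`` is the
    angular coordinate around the orbital axis (0 = medial, +90 = roof),
    ``depth_norm`` the rim->apex normalized depth, ``radius_mm`` the
    distance from the axis.
    """

    labels: np.ndarray
    phi_deg: np.ndarray
    depth_norm: np.ndarray
    radius_mm: np.ndarray
    half_angle_deg: float
    rim_plane: Plane
    apex: np.ndarray

    def __len__(self):
        return len(self.labels)


def _orbit_frame(mesh: SurfaceMesh, landmarks: LandmarkSet, mirror_plane: Plane,
                 side: str, rim_plane: Optional[Plane]):
    from .segmentation import anterior_clip_plane

    landmarks.require(side)
    pts = landmarks.sides[side]
    if rim_plane is None:
        rim_plane = anterior_clip_plane(pts["L"], pts["M"])
    rim_center = 0.5 * (pts["L"] + pts["M"])
    if "apex" in pts:
        apex = pts["apex"]
    else:
        depth = -rim_plane.signed_distance(mesh.vertices)
        if depth.max() <= 0:
            raise ValueError("apex landmark missing and not derivable from the mesh")
        apex = mesh.vertices[int(np.argmax(depth))]
    axis = apex - rim_center
    norm = np.linalg.norm(axis)
    if norm <= 0:
        raise ValueError("degenerate rim-center -> apex axis")
    axis = axis / norm
    # medial: toward the midsagittal plane from this side
    side_sign = np.sign(mirror_plane.signed_distance(rim_center)) or 1.0
    med = -side_sign * mirror_plane.normal
    med = med - (med @ axis) * axis
    med = med / np.linalg.norm(med)
    up = np.array([0.0, 0.0, 1.0])
    up = up - (up @ axis) * axis - (up @ med) * med
    nu = np.linalg.norm(up)
    if nu < 1e-9:
        raise ValueError("superior direction degenerate with the orbital axis")
    up = up / nu
    return rim_plane, rim_center, apex, axis, med, up


def label_walls(mesh: SurfaceMesh, landmarks: LandmarkSet, mirror_plane: Plane,
                side: str, rim_plane: Optional[Plane] = None,
                half_angle_deg: float = 45.0,
                rim_band_mm: float = 1.0) -> RegionLabeling:
    """Wall-level labels: medial / floor / lateral / roof, plus rim.

    Vertices anterior to, or within ``rim_band_mm`` behind, the rim plane
    are labelled ``rim`` — this captures the flat anterior face that
    clipping leaves on the mesh; the rest are classified by angular sector
    around the orbital axis with the given sector half-angle.
    """
    rim_plane, rim_center, apex, axis, med, up = _orbit_frame(
        mesh, landmarks, mirror_plane, side, rim_plane)
    v = mesh.vertices - rim_center
    depth_mm = v @ axis
    apex_depth = float((apex - rim_center) @ axis)
    if apex_depth <= 0:
        raise ValueError("apex depth must be positive")
    radial = v - np.outer(depth_mm, axis)
    phi = np.degrees(np.arctan2(radial @ up, radial @ med))
    h = half_angle_deg
    wall = np.where(np.abs(phi) <= h, "medial",
                    np.where(np.abs(phi) >= 180 - h, "lateral",
                             np.where(phi > 0, "roof", "floor")))
    anterior = rim_plane.signed_distance(mesh.vertices) >= -rim_band_mm
    labels = np.where(anterior, "rim", wall).astype("U24")
    return RegionLabeling(
        labels=labels,
        phi_deg=phi,
        depth_norm=depth_mm / apex_depth,
        radius_mm=np.linalg.norm(radial, axis=1),
        half_angle_deg=half_angle_deg,
        rim_plane=rim_plane,
        apex=apex,
    )


def split_thirds(labeling: RegionLabeling, mesh: SurfaceMesh | None = None,
                 rim_plane: Optional[Plane] = None,
                 apex=None) -> RegionLabeling:
    """Subdivide each wall into anterior / central / posterior depth thirds.

    Normalized depth d = (distance behind the rim plane) / (apex depth);
    thirds are [0, 1/3), [1/3, 2/3), [2/3, inf) — a vertex exactly at a
    boundary goes to the deeper region.
    """
    d = labeling.depth_norm
    third = np.where(d < 1.0 / 3.0, "anterior",
                     np.where(d < 2.0 / 3.0, "central", "posterior"))
    labels = labeling.labels.copy()
    walls = np.isin(labels, ("medial", "floor", "lateral"))
    combined = np.char.add(np.char.add(labels[walls], "_"), third[walls])
    labels[walls] = combined
    return RegionLabeling(
        labels=labels.astype("U24"),
        phi_deg=labeling.phi_deg,
        depth_norm=labeling.depth_norm,
        radius_mm=labeling.radius_mm,
        half_angle_deg=labeling.half_angle_deg,
        rim_plane=labeling.rim_plane,
        apex=labeling.apex,
    )


def label_regions(mesh: SurfaceMesh, landmarks: LandmarkSet, mirror_plane: Plane,
                  side: str, rim_plane: Optional[Plane] = None,
                  half_angle_deg: float = 45.0) -> RegionLabeling:
    """Full nine-region labeling (walls then thirds) in one call."""
    return split_thirds(label_walls(mesh, landmarks, mirror_plane, side,
                                    rim_plane, half_angle_deg))


def transition_zone_mask(labeling: RegionLabeling, band_mm: float = 2.0) -> np.ndarray:
    """Vertices within ``band_mm`` of the medial-wall/floor sector boundary.

    The arc distance to the boundary (at phi = -half_angle) is approximated
    by angular offset times local radius.
    """
    boundary = -labeling.half_angle_deg
    dphi = (labeling.phi_deg - boundary + 180.0) % 360.0 - 180.0
    arc = np.abs(np.radians(dphi)) * labeling.radius_mm
    # restricting to the two adjoining sectors keeps the band off the roof
    # and lateral wall even near the apex, where every direction is within
    # a short arc of the boundary
    on_walls = np.array([str(l).split("_")[0] in ("medial", "floor")
                         for l in labeling.labels])
    return (arc <= band_mm) & on_walls


@dataclass
class ImplantMask:
    """High-intensity implant voxels in a post-operative volume."""

    mask: np.ndarray
    spacing: tuple
    origin: tuple
    n_components: int = 0
    component_sizes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    def voxel_centers(self) -> np.ndarray:
        idx = np.argwhere(self.mask)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


def segment_implant(volume: VolumeImage, implant_threshold: float,
                    min_voxels: int = 10) -> ImplantMask:
    """Threshold-segment radioopaque implant material (titanium mesh).

    The threshold must sit above bone intensity; connected components
    smaller than ``min_voxels`` are dropped as noise. An empty result
    yields a warning (no implant present), not an error. The component
    report lets a caller flag thresholds low enough to leak into bone
    (one huge component).
    """
    raw = volume.data >= implant_threshold
    # 26-connectivity: a voxel-thin sheet draped over a curved wall stays
    # one component even where it steps diagonally
    labels, n = ndimage.label(raw, structure=ndimage.generate_binary_structure(3, 3))
    if n == 0:
        warnings.warn("no implant voxels above threshold; returning empty mask")
        return ImplantMask(mask=np.zeros(volume.shape, dtype=bool),
                           spacing=volume.spacing, origin=volume.origin)
    sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1)).astype(int)
    keep = np.flatnonzero(sizes >= min_voxels) + 1
    mask = np.isin(labels, keep)
    if not mask.any():
        warnings.warn("all implant components below min_voxels; returning empty mask")
    return ImplantMask(mask=mask, spacing=volume.spacing, origin=volume.origin,
                       n_components=len(keep), component_sizes=np.sort(sizes)[::-1])


def implant_coverage(labeling: RegionLabeling, mesh: SurfaceMesh,
                     implant: ImplantMask, projection_distance_mm: float = 2.0,
                     transition_band_mm: float = 2.0,
                     surface_points=None) -> pd.DataFrame:
    """Fraction of each region's surface area covered by implant material.

    A vertex counts as covered when it lies within
    ``projection_distance_mm`` of an implant voxel center; fractions are
    area-weighted with barycentric vertex areas. When the labelled mesh is
    a template that deviates from the reconstructed anatomy, pass
    ``surface_points`` — the per-vertex foot points on the reconstructed
    surface — so coverage is measured where the implant actually sits.
    The medial-floor transition band is reported as an extra (overlapping)
    row.
    """
    from .phantom import WALL_REGIONS

    areas = mesh.vertex_areas()
    pts = mesh.vertices if surface_points is None else np.asarray(surface_points)
    if pts.shape != mesh.vertices.shape:
        raise ValueError("surface_points must be one point per mesh vertex")
    if implant.voxel_count:
        tree = cKDTree(implant.voxel_centers())
        d, _ = tree.query(pts)
        covered = d <= projection_distance_mm
    else:
        covered = np.zeros(mesh.n_vertices, dtype=bool)

    rows = []
    regions = list(WALL_REGIONS) + ["roof"]
    for region in regions:
        sel = labeling.labels == region
        area = float(areas[sel].sum())
        rows.append({
            "region": region,
            "area_mm2": area,
            "coverage_fraction": float(areas[sel & covered].sum() / area) if area > 0 else 0.0,
        })
    band = transition_zone_mask(labeling, transition_band_mm)
    area = float(areas[band].sum())
    rows.append({
        "region": "transition_medial_floor",
        "area_mm2": area,
        "coverage_fraction": float(areas[band & covered].sum() / area) if area > 0 else 0.0,
    })
    return pd.DataFrame(rows)
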