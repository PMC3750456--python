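"""Orbital cavity segmentation and voxel-count volumetry.

The bony orbit is segmented by thresholding bone, morphologically closing
small defects, and flood-filling the cavity from a seed inside it
(6-connectivity). The anterior border follows the rim convention: the
straight line through the lateral (L) and medial (M) orbital rim points,
swept along the axial slice axis, defines a clipping plane; voxels anterior
to it are removed. Volume is the exact voxel count times the cell volume,
reported in ml.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import LandmarkSet, OrbitMask, Plane, VolumeImage

__all__ = [
    "SegmentationParams",
    "SegmentationError",
    "LeakError",
    "threshold_bone",
    "segment_cavity",
    "anterior_clip_plane",
    "clip_anterior",
    "compute_volume",
    "per_slice_profile",
    "seed_from_landmarks",
]


class SegmentationError(RuntimeError):
    """Segmentation failed (empty mask, bad seed, …)."""


class LeakError(SegmentationError):
    """The cavity fill escaped through a wall defect.

    Raised when the filled region exceeds ``max_volume_ml``; increase
    ``closing_radius_mm`` to bridge the defect.
    """


@dataclass
class SegmentationParams:
    """Parameters of the cavity segmentation.

    ``bone_threshold`` is HU-like for CT (default 300); CBCT intensities are
    uncalibrated, so pass a modality-specific value. ``cavity_seed`` is a
    voxel index inside the orbit; if None it must be derived from landmarks
    (:func:`seed_from_landmarks`). ``closing_radius_mm`` closes fracture
    gaps in the bone mask before filling; ``max_volume_ml`` is the leak
    guard.
    """

    bone_threshold: float = 300.0
    cavity_seed: Optional[Tuple[int, int, int]] = None
    closing_radius_mm: float = 1.0
    max_volume_ml: float = 60.0

    def __post_init__(self):
        if self.closing_radius_mm < 0:
            raise ValueError("closing_radius_mm must be >= 0")
        if self.max_volume_ml <= 0:
            raise ValueError("max_volume_ml must be > 0")


def threshold_bone(volume: VolumeImage, params: SegmentationParams) -> np.ndarray:
    """Binary bone mask: intensity >= ``bone_threshold``. No morphology."""
    mask = volume.data >= params.bone_threshold
    if not mask.any():
        raise SegmentationError(
            f"no bone above threshold {params.bone_threshold}"
        )
    return mask


def _ellipsoidal_structure(radius_mm: float, spacing) -> Optional[np.ndarray]:
    """Structuring element covering a ball of ``radius_mm`` on this grid."""
    if radius_mm <= 0:
        return None
    r_vox = np.maximum(np.floor(radius_mm / np.asarray(spacing)).astype(int), 0)
    if not r_vox.any():
        return None
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in r_vox)]
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, spacing))
    return dist2 <= radius_mm ** 2 + 1e-9


def segment_cavity(volume: VolumeImage, bone_mask: np.ndarray,
                   params: SegmentationParams, side: str) -> OrbitMask:
    """Flood-fill the orbital cavity bounded by the (closed) bone mask.

    The fill is 6-connected from ``params.cavity_seed`` over non-bone
    voxels; the bone mask is first morphologically closed with a ball of
    ``closing_radius_mm`` so fracture gaps do not let the fill escape. A
    fill larger than ``max_volume_ml`` raises :class:`LeakError`.
    """
    seed = params.cavity_seed
    if seed is None:
        raise SegmentationError("cavity_seed is required (or derive from landmarks)")
    seed = tuple(int(s) for s in seed)
    if bone_mask[seed]:
        raise SegmentationError(f"cavity seed {seed} lies inside bone")

    structure = _ellipsoidal_structure(params.closing_radius_mm, volume.spacing)
    if structure is not None:
        pad = [(s // 2,) * 2 for s in structure.shape]
        closed = np.pad(bone_mask, pad, mode="constant")
        closed = ndimage.binary_closing(closed, structure=structure)
        closed = closed[tuple(slice(p, d + p) for (p, _), d in zip(pad, bone_mask.shape))]
    else:
        closed = bone_mask

    open_space = ~closed
    labels, _ = ndimage.label(open_space, structure=ndimage.generate_binary_structure(3, 1))
    lab = labels[seed]
    if lab == 0:
        raise SegmentationError(f"cavity seed {seed} lies inside the closed bone mask")
    fill = labels == lab
    filled_ml = fill.sum() * np.prod(volume.spacing) / 1000.0
    if filled_ml > params.max_volume_ml:
        raise LeakError(
            f"leak detected: fill reached {filled_ml:.1f} ml "
            f"(> max_volume_ml {params.max_volume_ml}); "
            f"increase closing_radius_mm (currently {params.closing_radius_mm} mm)"
        )
    return OrbitMask(mask=fill, side=side, spacing=volume.spacing,
                     origin=volume.origin, clipped=False)


def anterior_clip_plane(L, M, axial_direction=(0.0, 0.0, 1.0),
                        anterior_hint=(0.0, 1.0, 0.0)) -> Plane:
    """Plane through the L–M rim line, swept along the axial slice axis.

    The plane contains both rim points and the slice-axis direction; its
    normal is oriented anteriorly (positive component along
    ``anterior_hint``).
    """
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    axial = np.asarray(axial_direction, dtype=float)
    if np.allclose(L, M):
        raise ValueError("L and M coincide; rim line undefined")
    n = np.cross(M - L, axial)
    if np.linalg.norm(n) < 1e-12:
        raise ValueError("axial direction is parallel to the L-M line")
    n = n / np.linalg.norm(n)
    if np.dot(n, np.asarray(anterior_hint, dtype=float)) < 0:
        n = -n
    return Plane(normal=n, point=L)


def clip_anterior(mask: OrbitMask, plane: Plane) -> OrbitMask:
    """Remove voxels whose centers lie anterior to the rim plane.

    The plane normal must point anteriorly; voxel centers with positive
    (or zero) signed distance are removed. Errors out if nothing remains.
    """
    idx = np.argwhere(mask.mask)
    if len(idx) == 0:
        raise SegmentationError("cannot clip an empty mask")
    centers = np.asarray(mask.origin) + idx * np.asarray(mask.spacing)
    keep = plane.signed_distance(centers) < 0
    out = np.zeros_like(mask.mask)
    kept = idx[keep]
    if len(kept) == 0:
        raise SegmentationError("anterior clipping removed the entire mask")
    out[kept[:, 0], kept[:, 1], kept[:, 2]] = True
    return OrbitMask(mask=out, side=mask.side, spacing=mask.spacing,
                     origin=mask.origin, clipped=True)


def compute_volume(mask: OrbitMask, spacing=None) -> float:
    """Cavity volume in ml: exact voxel count x cell volume.

    Requires an anterior-clipped mask (1 ml = 1000 mm^3).
    """
    if not mask.clipped:
        raise ValueError("volume is defined on the anterior-clipped mask; clip first")
    spacing = mask.spacing if spacing is None else spacing
    return mask.voxel_count * float(np.prod(spacing)) / 1000.0


def per_slice_profile(mask: OrbitMask) -> pd.DataFrame:
    """Per-axial-slice areas and subvolumes.

    Returns a table over occupied z-slices with columns ``slice_index``,
    ``area_mm2``, ``subvolume_ml`` and ``cumulative_ml``; subvolumes sum
    exactly to :func:`compute_volume`.
    """
    if not mask.clipped:
        raise ValueError("profile is defined on the anterior-clipped mask; clip first")
    sx, sy, sz = mask.spacing
    counts = mask.mask.sum(axis=(0, 1))
    occupied = np.flatnonzero(counts)
    area = counts[occupied] * sx * sy
    sub = area * sz / 1000.0
    return pd.DataFrame({
        "slice_index": occupied,
        "area_mm2": area,
        "subvolume_ml": sub,
        "cumulative_ml": np.cumsum(sub),
    })


def seed_from_landmarks(volume: VolumeImage, landmarks: LandmarkSet, side: str,
                        depth_mm: float = 15.0,
                        anterior=(0.0, 1.0, 0.0)) -> Tuple[int, int, int]:
    """Derive a cavity seed: the L–M midpoint pushed posteriorly.

    ``depth_mm`` controls how far behind the rim the seed is placed; the
    default 15 mm lands well inside the cavity for adult orbits.
    """
    landmarks.require(side)
    pts = landmarks.sides[side]
    mid = 0.5 * (pts["L"] + pts["M"])
    world = mid - depth_mm * np.asarray(anterior, dtype=float)
    idx = np.round(volume.world_to_index(world)).astype(int)
    idx = np.clip(idx, 0, np.asarray(volume.shape) - 1)
    return tuple(int(i) for i in idx)
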