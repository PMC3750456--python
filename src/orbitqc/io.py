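"""Readers and writers for volumes (NIfTI/NRRD), meshes (STL/PLY), and landmarks.

Volumes are returned in the package's fixed patient-space convention (see
:mod:`orbitqc.types`): the array is indexed ``[x, y, z]`` and world
coordinates are ``origin + index * spacing``. NIfTI files are reoriented to
the closest canonical (RAS) orientation on read; oblique acquisitions are
rejected. NRRD files are read in their stated frame and must have an
axis-aligned direction matrix.
"""

from __future__ import annotations

import csv
import json
import os
from typing import Iterable, Optional

import numpy as np

from .types import LandmarkSet, SurfaceMesh, VolumeImage

__all__ = [
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
]


def _check_exists(path) -> str:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"cannot read {path!r}: no such file")
    return path


def read_volume(path) -> VolumeImage:
    """Load a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) volume.

    Raises an :class:`IOError` naming the path for unreadable files and a
    :class:`ValueError` when voxel spacing is absent or non-positive
    (volumetry is impossible without it).
    """
    path = _check_exists(path)
    low = path.lower()
    if low.endswith((".nii", ".nii.gz")):
        data, spacing, origin = _read_nifti(path)
    elif low.endswith(".nrrd"):
        data, spacing, origin = _read_nrrd(path)
    else:
        raise IOError(f"cannot read {path!r}: unsupported volume format")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"{path!r}: missing or invalid voxel spacing {spacing}")
    return VolumeImage(data=data, spacing=spacing, origin=origin)


def _read_nifti(path):
    import nibabel as nib

    try:
        img = nib.load(path)
    except Exception as e:  # pragma: no cover - nibabel error text varies
        raise IOError(f"cannot read {path!r}: {e}") from e
    img = nib.as_closest_canonical(img)
    aff = np.asarray(img.affine, dtype=float)
    rot = aff[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-4):
        raise ValueError(f"{path!r}: oblique volumes are not supported")
    spacing = tuple(np.diag(rot))
    origin = tuple(aff[:3, 3])
    data = np.asanyarray(img.dataobj)
    return data, spacing, origin


def _read_nrrd(path):
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(path)
    except Exception as e:
        raise IOError(f"cannot read {path!r}: {e}") from e
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-4):
        raise ValueError(f"{path!r}: non-axis-aligned NRRD direction is not supported")
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return data, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def write_volume(volume: VolumeImage, path) -> str:
    """Write a volume as NIfTI or NRRD, preserving spacing and origin."""
    path = os.fspath(path)
    low = path.lower()
    if low.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        aff = np.eye(4)
        aff[:3, :3] = np.diag(volume.spacing)
        aff[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.data, aff), path)
    elif low.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in volume.spacing))
        img.SetOrigin(tuple(float(o) for o in volume.origin))
        sitk.WriteImage(img, path)
    else:
        raise IOError(f"cannot write {path!r}: unsupported volume format")
    return path


def read_mesh(path) -> SurfaceMesh:
    """Load an STL or PLY mesh; STL triangle soup is welded to unique vertices."""
    import trimesh

    path = _check_exists(path)
    tm = trimesh.load_mesh(path, process=True)
    mesh = SurfaceMesh.from_trimesh(tm)
    colors = getattr(getattr(tm, "visual", None), "vertex_colors", None)
    if colors is not None and len(colors) == mesh.n_vertices:
        colors = np.asarray(colors)[:, :3]
        if colors.size and not np.all(colors == colors[0]):
            mesh.colors = colors
    return mesh


def write_mesh(mesh: SurfaceMesh, path, with_colors: bool = False) -> str:
    """Write STL (geometry only) or PLY (optionally with per-vertex RGB)."""
    import trimesh

    path = os.fspath(path)
    low = path.lower()
    if low.endswith(".stl") and with_colors:
        raise ValueError("STL cannot carry per-vertex colors; write PLY instead")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if with_colors:
        if mesh.colors is None:
            raise ValueError("mesh has no color channel")
        colors = np.asarray(mesh.colors)
        if colors.dtype != np.uint8:
            colors = np.clip(np.asarray(colors, dtype=float), 0.0, 1.0)
            colors = (colors * 255).round().astype(np.uint8)
        rgba = np.column_stack([colors, np.full(len(colors), 255, dtype=np.uint8)])
        tm.visual.vertex_colors = rgba
    tm.export(path)
    return path


# --------------------------------------------------------------------------
# landmarks

_MIDLINE_PREFIX = "midline"


def _insert_point(sides: dict, midline: list, name: str, xyz) -> None:
    xyz = np.asarray(xyz, dtype=float).reshape(3)
    if name.lower().startswith(_MIDLINE_PREFIX):
        midline.append(xyz)
        return
    if "_" not in name:
        raise ValueError(f"landmark {name!r}: expected '<name>_<side>' or 'midline_*'")
    base, _, side = name.rpartition("_")
    side = side.lower()
    if side not in ("left", "right"):
        raise ValueError(f"landmark {name!r}: side must be 'left' or 'right'")
    sides.setdefault(side, {})[base] = xyz


def read_landmarks(path, require_sides: Optional[Iterable[str]] = None,
                   require_midline: bool = False) -> LandmarkSet:
    """Load named landmarks from JSON or CSV.

    JSON schema: ``{"landmarks": {"L_right": [x,y,z], ...},
    "midline": [[x,y,z], ...]}`` (midline points may equivalently appear as
    ``midline_1`` … inside ``landmarks``). CSV columns: ``name,x,y,z``.

    ``require_sides`` lists sides whose rim points L and M must be present;
    a missing point raises a :class:`ValueError` naming it (e.g.
    ``"M_left required"``).
    """
    path = _check_exists(path)
    sides: dict = {}
    midline: list = []
    if path.lower().endswith(".json"):
        with open(path) as fh:
            doc = json.load(fh)
        for name, xyz in doc.get("landmarks", {}).items():
            _insert_point(sides, midline, name, xyz)
        for xyz in doc.get("midline", []):
            midline.append(np.asarray(xyz, dtype=float).reshape(3))
    elif path.lower().endswith(".csv"):
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                _insert_point(sides, midline, row["name"],
                              [row["x"], row["y"], row["z"]])
    else:
        raise IOError(f"cannot read {path!r}: unsupported landmark format")
    lms = LandmarkSet(sides=sides, midline=np.asarray(midline) if midline else None)
    for side in (require_sides or ()):
        lms.require(side)
    if require_midline:
        lms.require_midline()
    return lms


def write_landmarks(landmarks: LandmarkSet, path) -> str:
    """Write landmarks as JSON (the package's canonical dialect)."""
    path = os.fspath(path)
    doc = {"landmarks": {}, "midline": []}
    for side, pts in landmarks.sides.items():
        for name, xyz in pts.items():
            doc["landmarks"][f"{name}_{side}"] = [float(v) for v in xyz]
    if landmarks.midline is not None:
        doc["midline"] = [[float(v) for v in p] for p in landmarks.midline]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
    return path
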