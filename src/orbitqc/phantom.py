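"""Synthetic head phantoms with paired unaffected / fractured / reconstructed states.

Each orbital cavity is modelled as an ellipsoid embedded in a bone shell
inside a soft-tissue block; the anterior half of the ellipsoid is removed
by the rim (L–M) clipping plane, so the clipped cavity volume is exactly
(2/3) pi a b c and defaults are calibrated to the clinically reported
~26.6 ml. A bone lid slightly anterior of the rim keeps the cavity closed
for flood filling (real orbits are open anteriorly; the rim plane is the
volumetric bound either way).

The fractured state displaces the affected wall (floor or medial wall)
outward by a smooth flat-top bulge whose footprint is solved so the added
cavity volume hits a requested target (clinical range ~0.3–3.4 ml), and
cuts a thin fracture gap around the displaced fragment so an unclosed bone
mask leaks. The reconstructed state restores the wall with a small
residual bulge (default 1.5 mm, the scale of reported worst-case
deviations) and an optional high-intensity implant sheet resting on the
floor.

All randomness (additive Gaussian noise per modality profile) flows
through a single seeded generator; identical specs give bit-identical
volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .types import LandmarkSet, Plane, VolumeImage

__all__ = [
    "FractureSpec",
    "ReconstructionSpec",
    "ModalityProfile",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomGeometryError",
    "generate_phantom",
    "generate_cohort",
    "WALL_REGIONS",
]

#: the nine wall regions: three walls x three depth thirds
WALL_REGIONS = tuple(
    f"{wall}_{third}"
    for wall in ("medial", "floor", "lateral")
    for third in ("anterior", "central", "posterior")
)


class PhantomGeometryError(ValueError):
    """Requested phantom geometry is unattainable."""


@dataclass
class FractureSpec:
    """Wall defect of the affected orbit.

    ``added_volume_ml`` is the target cavity enlargement (clinical range up
    to ~3.4 ml for posterior-ledge fractures); the bulge footprint is
    solved so the added volume hits it at the given
    ``bulge_amplitude_mm``. ``defect_gap_mm`` is the width of the fracture
    gap cut around the displaced fragment.
    """

    wall: str = "floor"            # 'floor' or 'medial'
    region: str = "posterior"      # 'anterior' | 'central' | 'posterior'
    defect_gap_mm: float = 1.0
    bulge_amplitude_mm: float = 8.0
    added_volume_ml: float = 3.4

    def __post_init__(self):
        if self.wall not in ("floor", "medial"):
            raise ValueError("fracture wall must be 'floor' or 'medial'")
        if self.region not in ("anterior", "central", "posterior"):
            raise ValueError("fracture region must be anterior/central/posterior")


@dataclass
class ReconstructionSpec:
    """Residual deviation and implant of the reconstructed orbit."""

    residual_amplitude_mm: float = 1.5
    residual_wall: str = "floor"
    residual_region: str = "anterior"
    implant: bool = True
    implant_thickness_mm: float = 1.0
    implant_coverage: str = "full_floor"  # or "half_floor"


@dataclass
class ModalityProfile:
    """Imaging modality stand-in: intensity scale and additive noise.

    CBCT intensities are uncalibrated: modelled as a global scale < 1 with
    higher noise. ``suggested_bone_threshold`` is the matching segmentation
    threshold.
    """

    name: str = "CT"
    intensity_scale: float = 1.0
    noise_sigma: float = 20.0

    @classmethod
    def ct(cls) -> "ModalityProfile":
        return cls("CT", 1.0, 20.0)

    @classmethod
    def cbct(cls) -> "ModalityProfile":
        return cls("CBCT", 0.6, 40.0)

    @property
    def suggested_bone_threshold(self) -> float:
        return 300.0 * self.intensity_scale


@dataclass
class PhantomSpec:
    """Full description of a paired phantom.

    ``semi_axes`` are (a, c, b): lateral half-width, depth, and half-height
    of the cavity ellipsoid in mm. The default depth is solved so the
    clipped cavity volume equals ``target_volume_ml`` (26.6 ml, the
    reported male mean). ``asymmetry`` scales the left cavity relative to
    the right.
    """

    spacing: float = 0.5
    target_volume_ml: float = 26.6
    semi_axes: Optional[Tuple[float, float, float]] = None
    asymmetry: float = 1.0
    affected_side: str = "right"
    fracture: Optional[FractureSpec] = field(default_factory=FractureSpec)
    reconstruction: Optional[ReconstructionSpec] = field(default_factory=ReconstructionSpec)
    intensity_air: float = -1000.0
    intensity_soft: float = 50.0
    intensity_bone: float = 1200.0
    intensity_implant: float = 3000.0
    shell_mm: float = 2.5
    lid_mm: float = 3.0
    margin_mm: float = 3.0
    center_offset_mm: float = 26.0
    modality_preop: ModalityProfile = field(default_factory=ModalityProfile.ct)
    modality_postop: ModalityProfile = field(default_factory=ModalityProfile.cbct)
    seed: int = 0

    def __post_init__(self):
        if self.semi_axes is None:
            a, b = 16.0, 17.0
            c = 3.0 * self.target_volume_ml * 1000.0 / (2.0 * math.pi * a * b)
            self.semi_axes = (a, c, b)
        if min(self.semi_axes) <= 0:
            raise ValueError("cavity semi-axes must be positive")
        if self.affected_side not in ("left", "right"):
            raise ValueError("affected_side must be 'left' or 'right'")

    def analytic_volume_ml(self, side: str) -> float:
        """Exact clipped (half-ellipsoid) cavity volume of one side."""
        a, c, b = self.semi_axes
        f = self.asymmetry if side == "left" else 1.0
        return (2.0 / 3.0) * math.pi * (a * f) * (b * f) * (c * f) / 1000.0


# depth position (fraction of cavity depth) and along-depth half-extent
# (fraction of the depth semi-axis) of a defect footprint per region; the
# posterior pattern spans most of the wall, matching complete fractures
# with posterior-ledge involvement
_REGION_FOOTPRINT = {
    "anterior": (1.0 / 6.0, 0.15),
    "central": (0.5, 0.15),
    "posterior": (0.55, 0.40),
    "anterior_central": (1.0 / 3.0, 0.30),
    "full": (0.5, 0.47),
}
_LATERAL_FRACTION = 0.78   # footprint half-extent across the wall, fraction of semi-axis
_FLAT_CORE = 0.6


def _bulge_profile(r: np.ndarray) -> np.ndarray:
    """Flat-top radial profile: 1 inside the core, cosine-squared taper to 0."""
    out = np.zeros_like(r)
    core = r <= _FLAT_CORE
    out[core] = 1.0
    taper = (~core) & (r < 1.0)
    out[taper] = np.cos(0.5 * np.pi * (r[taper] - _FLAT_CORE) / (1.0 - _FLAT_CORE)) ** 2
    return out


@dataclass
class _WallFrame:
    """Geometry of one displaceable wall of one cavity.

    ``u`` is the across-wall in-plane coordinate, ``y`` the depth
    coordinate, and ``w`` the displacement coordinate (the wall is
    displaced toward -w for the right-orbit floor, etc.).
    """

    wall: str
    center: np.ndarray            # (cx, y0, cz)
    axes: Tuple[float, float, float]   # (a, c, b)
    w_sign: float                 # outward displacement decreases (+1) or increases (-1) w

    @property
    def u_axis_len(self) -> float:
        a, c, b = self.axes
        return a if self.wall == "floor" else b

    @property
    def w_axis_len(self) -> float:
        a, c, b = self.axes
        return b if self.wall == "floor" else a

    @property
    def u_center(self) -> float:
        return self.center[0] if self.wall == "floor" else self.center[2]

    @property
    def w_center(self) -> float:
        return self.center[2] if self.wall == "floor" else self.center[0]


def _make_wall_frame(wall: str, side: str, center, axes) -> _WallFrame:
    if wall == "floor":
        w_sign = 1.0  # floor displaced downward (toward -z)
    else:
        # medial wall displaced toward the midsagittal plane
        w_sign = 1.0 if side == "right" else -1.0
    return _WallFrame(wall=wall, center=np.asarray(center, dtype=float),
                      axes=tuple(axes), w_sign=w_sign)


def _footprint(frame: _WallFrame, region: str, scale: float) -> dict:
    frac, ry_frac = _REGION_FOOTPRINT[region]
    c = frame.axes[1]
    return {
        "wall": frame.wall,
        "center_uy": (frame.u_center, frame.center[1] - frac * c),
        "ru_mm": _LATERAL_FRACTION * frame.u_axis_len * scale,
        "ry_mm": ry_frac * c * scale,
        "region": region,
    }


def _footprint_radius(us, ys, footprint, p: float = 2.0):
    fu, fy = footprint["center_uy"]
    ru, ry = footprint["ru_mm"], footprint["ry_mm"]
    if ru <= 0 or ry <= 0:
        return np.full((len(us), len(ys)), np.inf)
    return (np.abs((us[:, None] - fu) / ru) ** p
            + np.abs((ys[None, :] - fy) / ry) ** p) ** (1.0 / p)


def _bulge_height(us, ys, footprint, amplitude, p: float = 2.0):
    """(nu, ny) outward displacement field over the wall footprint."""
    return amplitude * _bulge_profile(_footprint_radius(us, ys, footprint, p))


def _shifted_coords(spec, xs, ys, zs, frame: _WallFrame, h2d, extra_shift_mm):
    cx, y0, cz = frame.center
    X = xs[:, None, None]
    Z = zs[None, None, :]
    Xs, Zs = X, Z
    if h2d is not None:
        if frame.wall == "floor":
            shift = (h2d + extra_shift_mm)[:, :, None] * frame.w_sign
            Zs = np.where(Z < cz, Z + shift, Z)
        else:
            shift = (h2d.T + extra_shift_mm)[None, :, :] * frame.w_sign
            if frame.w_sign > 0:   # right orbit: medial wall at x < cx
                Xs = np.where(X < cx, X + shift, X)
            else:
                Xs = np.where(X > cx, X + shift, X)
    return Xs, Zs


def _side_masks(spec, xs, ys, zs, frame: _WallFrame, h2d=None, extra_shift_mm=0.0):
    """Cavity and bone membership for one orbit, optionally wall-displaced.

    ``h2d`` is an outward wall displacement field in mm over (u, y); it is
    applied to the wall's half of the cavity only. The displaced bone
    fragment is additionally rasterized at the neighborhood-maximum
    displacement so steep displacement gradients cannot shear the shell
    open between adjacent voxel columns at coarse spacings.
    """
    from scipy.ndimage import maximum_filter

    cx, y0, cz = frame.center
    a, c, b = frame.axes
    t = spec.shell_mm
    Y = ys[None, :, None]

    def memberships(Xs, Zs):
        rho2 = ((Xs - cx) / a) ** 2 + ((Y - y0) / c) ** 2 + ((Zs - cz) / b) ** 2
        rho2_out = (((Xs - cx) / (a + t)) ** 2 + ((Y - y0) / (c + t)) ** 2
                    + ((Zs - cz) / (b + t)) ** 2)
        cavity = (rho2 <= 1.0) & (Y < y0 + spec.lid_mm)
        outer = (rho2_out <= 1.0) & (Y <= y0 + spec.lid_mm + t)
        return cavity, outer

    Xs, Zs = _shifted_coords(spec, xs, ys, zs, frame, h2d, extra_shift_mm)
    cavity, outer = memberships(Xs, Zs)
    if h2d is not None and np.any(h2d > 0):
        h_max = maximum_filter(h2d, size=3)
        Xs2, Zs2 = _shifted_coords(spec, xs, ys, zs, frame, h_max, extra_shift_mm)
        outer |= memberships(Xs2, Zs2)[1]
    bone = outer & ~cavity
    return cavity, bone


def _wall_coords(frame: _WallFrame, xs, zs):
    """In-plane (u) and displacement (w) coordinate arrays for the wall."""
    return (xs, zs) if frame.wall == "floor" else (zs, xs)


def _column_counts(frame: _WallFrame, us, ys, ws, h2d):
    """Voxels added to the cavity by an outward wall displacement ``h2d``.

    Counts, per (u, y) column, the cell centers along the displacement
    coordinate between the displaced and original wall surfaces.
    """
    cx, y0, cz = frame.center
    a, c, b = frame.axes
    g2 = (1.0 - ((us[:, None] - frame.u_center) / frame.u_axis_len) ** 2
          - ((ys[None, :] - y0) / c) ** 2)
    valid = (g2 > 0) & (h2d > 0) & (ys[None, :] < y0)
    g = np.sqrt(np.clip(g2, 0, None))
    w0, sw = ws[0], ws[1] - ws[0]
    n = len(ws)

    if frame.w_sign > 0:
        # wall surface at w_center - len*g, displaced to (surface - h)
        wsurf = frame.w_center - frame.w_axis_len * g

        def count_below(t):
            return np.clip(np.ceil((t - w0) / sw), 0, n)

        counts = count_below(wsurf) - count_below(wsurf - h2d)
    else:
        # wall surface at w_center + len*g, displaced to (surface + h)
        wsurf = frame.w_center + frame.w_axis_len * g

        def count_above(t):
            return np.clip(n - np.floor((t - w0) / sw) - 1, 0, n)

        counts = count_above(wsurf) - count_above(wsurf + h2d)
    return int(counts[valid].sum())


def _solve_footprint_scale(spec, frame, us, ys, ws, fracture):
    """Bisect the footprint scale so the bulge adds the target volume."""
    target_vox = fracture.added_volume_ml * 1000.0 / spec.spacing ** 3

    def added(scale):
        fp = _footprint(frame, fracture.region, scale)
        h = _bulge_height(us, ys, fp, fracture.bulge_amplitude_mm)
        return _column_counts(frame, us, ys, ws, h)

    hi = added(1.0)
    if hi < target_vox:
        attainable = hi * spec.spacing ** 3 / 1000.0
        raise PhantomGeometryError(
            f"target added volume {fracture.added_volume_ml} ml unattainable with "
            f"bulge amplitude {fracture.bulge_amplitude_mm} mm; attainable maximum "
            f"is {attainable:.2f} ml"
        )
    lo_s, hi_s = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo_s + hi_s)
        if added(mid) < target_vox:
            lo_s = mid
        else:
            hi_s = mid
    return hi_s


def _crack_mask(frame: _WallFrame, xs, ys, zs, footprint, gap_mm):
    """Thin gap around the displaced fragment, cut through the wall's half."""
    us, _ = _wall_coords(frame, xs, zs)
    fu, fy = footprint["center_uy"]
    ru, ry = footprint["ru_mm"], footprint["ry_mm"]
    du = us[:, None] - fu
    dy = ys[None, :] - fy
    r = np.sqrt((du / ru) ** 2 + (dy / ry) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_mm = np.where(r > 0, np.sqrt(du ** 2 + dy ** 2) / r, 0.0)
    ring = (r > 1.0) & ((r - 1.0) * r_mm <= gap_mm)
    if frame.wall == "floor":
        return ring[:, :, None] & (zs[None, None, :] < frame.center[2])
    ring3 = ring.T[None, :, :]
    if frame.w_sign > 0:
        return ring3 & (xs[:, None, None] < frame.center[0])
    return ring3 & (xs[:, None, None] > frame.center[0])


def _rasterize(spec, rng, bone_mask, implant_mask, profile):
    soft = spec.intensity_soft * profile.intensity_scale
    bone = spec.intensity_bone * profile.intensity_scale
    implant = spec.intensity_implant * profile.intensity_scale
    vol = np.full(bone_mask.shape, soft, dtype=np.float32)
    vol[bone_mask] = bone
    if implant_mask is not None:
        vol[implant_mask] = implant
    if profile.noise_sigma > 0:
        vol += rng.normal(0.0, profile.noise_sigma, size=vol.shape).astype(np.float32)
    return vol


def _grid(spec: PhantomSpec):
    """Symmetric voxel grid: x centers mirror exactly about x = 0."""
    s = float(spec.spacing)
    a, c, b = spec.semi_axes
    big = max(1.0, spec.asymmetry)
    # leave room for outward wall displacements (fracture bulge, residual)
    bulge = 0.0
    if spec.fracture is not None:
        bulge = max(bulge, spec.fracture.bulge_amplitude_mm)
    if spec.reconstruction is not None:
        bulge = max(bulge, spec.reconstruction.residual_amplitude_mm
                    + spec.reconstruction.implant_thickness_mm)
    half_x = spec.center_offset_mm + a * big + spec.shell_mm + spec.margin_mm + bulge
    nx = 2 * int(math.ceil(half_x / s))
    y_lo = -(c * big + spec.shell_mm + spec.margin_mm)
    y_hi = spec.lid_mm + spec.shell_mm + spec.margin_mm
    ny = int(math.ceil((y_hi - y_lo) / s))
    half_z = b * big + spec.shell_mm + spec.margin_mm + bulge
    nz = 2 * int(math.ceil(half_z / s))
    origin = ((0.5 - nx / 2) * s, y_lo + 0.5 * s, (0.5 - nz / 2) * s)
    xs = origin[0] + np.arange(nx) * s
    ys = origin[1] + np.arange(ny) * s
    zs = origin[2] + np.arange(nz) * s
    return origin, (nx, ny, nz), xs, ys, zs


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom."""

    spec: PhantomSpec
    origin: Tuple[float, float, float]
    shape: Tuple[int, int, int]
    mirror_plane: Plane
    rim_planes: Dict[str, Plane]
    landmarks: LandmarkSet
    seeds: Dict[str, Tuple[int, int, int]]
    centers: Dict[str, np.ndarray]
    axes: Dict[str, Tuple[float, float, float]]
    volumes_ml: Dict[str, float]
    analytic_volumes_ml: Dict[str, float]
    added_volume_ml: float
    residual_amplitude_mm: float
    bulge_footprint: Optional[dict]
    residual_footprint: Optional[dict]
    implant_indices: Optional[np.ndarray]
    #: clipped true cavity masks of the unaffected state, per side
    cavity_masks: Optional[Dict[str, np.ndarray]] = None

    def label_points(self, points: np.ndarray, side: str,
                     half_angle_deg: float = 45.0,
                     rim_band_mm: float = 1.0) -> np.ndarray:
        """Exact wall/third labels for points on the cavity surface.

        Uses the generator's own frame: angular sectors around the
        rim-center -> apex axis (floor inferior, medial toward the mirror
        plane, lateral opposite, roof superior) and equal normalized depth
        thirds. Points anterior to, or within ``rim_band_mm`` behind, the
        rim plane are labelled ``rim`` (the flat clip face is rim surface,
        not wall).
        """
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        cx, y0, cz = self.centers[side]
        _, c, _ = self.axes[side]
        med_x = -1.0 if cx > 0 else 1.0
        rm = (points[:, 0] - cx) * med_x
        rz = points[:, 2] - cz
        phi = np.degrees(np.arctan2(rz, rm))
        h = half_angle_deg
        wall = np.where(np.abs(phi) <= h, "medial",
                        np.where(np.abs(phi) >= 180 - h, "lateral",
                                 np.where(phi > 0, "roof", "floor")))
        d = (y0 - points[:, 1]) / c
        third = np.where(d < 1.0 / 3.0, "anterior",
                         np.where(d < 2.0 / 3.0, "central", "posterior"))
        labels = np.char.add(np.char.add(wall.astype("U16"), "_"), third.astype("U16"))
        labels = np.where(wall == "roof", "roof", labels)
        labels = np.where(d < rim_band_mm / c, "rim", labels)
        return labels.astype("U24")


def generate_phantom(spec: PhantomSpec):
    """Generate the three phantom states and their ground truth.

    Returns ``(unaffected, affected, reconstructed, truth)``: three
    :class:`VolumeImage` (unaffected and affected use the pre-operative
    modality profile, reconstructed the post-operative one) plus a
    :class:`PhantomTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    origin, shape, xs, ys, zs = _grid(spec)
    a, c, b = spec.semi_axes
    f = spec.asymmetry
    centers = {
        "right": np.array([spec.center_offset_mm, 0.0, 0.0]),
        "left": np.array([-spec.center_offset_mm, 0.0, 0.0]),
    }
    axes = {"right": (a, c, b), "left": (a * f, c * f, b * f)}
    aff = spec.affected_side
    una = "left" if aff == "right" else "right"

    base_frames = {s: _make_wall_frame("floor", s, centers[s], axes[s])
                   for s in ("right", "left")}
    cav = {}
    bone = {}
    for side in ("right", "left"):
        cav[side], bone[side] = _side_masks(spec, xs, ys, zs, base_frames[side])

    voxvol = spec.spacing ** 3 / 1000.0
    clip = ys[None, :, None] < 0.0

    volumes = {}
    for side in ("right", "left"):
        volumes[f"unaffected_{side}"] = float((cav[side] & clip).sum()) * voxvol

    # ---- fractured state -------------------------------------------------
    bulge_fp = None
    added_ml = 0.0
    cav_aff, bone_aff = dict(cav), dict(bone)
    if spec.fracture is not None:
        frac = spec.fracture
        frame = _make_wall_frame(frac.wall, aff, centers[aff], axes[aff])
        us, ws = _wall_coords(frame, xs, zs)
        scale = _solve_footprint_scale(spec, frame, us, ys, ws, frac)
        bulge_fp = _footprint(frame, frac.region, scale)
        h_frac = _bulge_height(us, ys, bulge_fp, frac.bulge_amplitude_mm)
        cav_f, bone_f = _side_masks(spec, xs, ys, zs, frame, h2d=h_frac)
        crack = _crack_mask(frame, xs, ys, zs, bulge_fp, frac.defect_gap_mm)
        bone_f = bone_f & ~crack
        cav_aff[aff], bone_aff[aff] = cav_f, bone_f
        added_ml = float((cav_f & clip).sum()) * voxvol - volumes[f"unaffected_{aff}"]
    for side in ("right", "left"):
        volumes[f"affected_{side}"] = float((cav_aff[side] & clip).sum()) * voxvol

    # ---- reconstructed state --------------------------------------------
    res_fp = None
    implant_mask = None
    res_amp = 0.0
    cav_rec, bone_rec = dict(cav), dict(bone)
    if spec.reconstruction is not None:
        rec = spec.reconstruction
        res_amp = rec.residual_amplitude_mm
        frame = _make_wall_frame(rec.residual_wall, aff, centers[aff], axes[aff])
        us, ws = _wall_coords(frame, xs, zs)
        res_fp = _footprint(frame, rec.residual_region, 0.8)
        h_res = _bulge_height(us, ys, res_fp, res_amp)
        cav_r, bone_r = _side_masks(spec, xs, ys, zs, frame, h2d=h_res)
        if rec.implant:
            floor_frame = _make_wall_frame("floor", aff, centers[aff], axes[aff])
            fus, _ = _wall_coords(floor_frame, xs, zs)
            cov = {"full_floor": "full", "half_floor": "anterior_central"}[rec.implant_coverage]
            imp_fp = _footprint(floor_frame, cov, 1.0)
            # near-rectangular footprint so coverage reaches the third ends
            in_fp = _footprint_radius(fus, ys, imp_fp, p=4.0) < 1.0
            if rec.residual_wall == "floor":
                h_floor = h_res
            else:
                h_floor = np.zeros((len(fus), len(ys)))
            cav_deep, _ = _side_masks(spec, xs, ys, zs, floor_frame, h2d=h_floor,
                                      extra_shift_mm=rec.implant_thickness_mm)
            cav_surface = cav_r if rec.residual_wall == "floor" else cav[aff]
            # keep the sheet inside the floor's 45-degree sector so it does
            # not climb the medial/lateral walls where the surface steepens
            floor_sector = (np.abs(xs[:, None, None] - centers[aff][0])
                            <= (centers[aff][2] - zs[None, None, :]))
            implant_mask = (cav_deep & ~cav_surface & in_fp[:, :, None]
                            & floor_sector & (ys[None, :, None] < 0.0))
            bone_r = bone_r & ~implant_mask
        cav_rec[aff], bone_rec[aff] = cav_r, bone_r
    for side in ("right", "left"):
        volumes[f"reconstructed_{side}"] = float((cav_rec[side] & clip).sum()) * voxvol

    # ---- rasterize -------------------------------------------------------
    vol_unaffected = VolumeImage(
        _rasterize(spec, rng, bone["right"] | bone["left"], None, spec.modality_preop),
        spacing=(spec.spacing,) * 3, origin=origin)
    vol_affected = VolumeImage(
        _rasterize(spec, rng, bone_aff["right"] | bone_aff["left"], None, spec.modality_preop),
        spacing=(spec.spacing,) * 3, origin=origin)
    vol_reconstructed = VolumeImage(
        _rasterize(spec, rng, bone_rec["right"] | bone_rec["left"], implant_mask,
                   spec.modality_postop),
        spacing=(spec.spacing,) * 3, origin=origin)

    # ---- landmarks and truth --------------------------------------------
    sides_lm = {}
    for side in ("right", "left"):
        cx, y0, cz = centers[side]
        aa, cc, bb = axes[side]
        lateral = 1.0 if side == "right" else -1.0
        sides_lm[side] = {
            "L": np.array([cx + lateral * aa, y0, cz]),
            "M": np.array([cx - lateral * aa, y0, cz]),
            "apex": np.array([cx, y0 - cc, cz]),
        }
    y_mid = min(5.0, ys[-1] - 1.0)
    midline = np.array([
        [0.0, y_mid, 0.6 * b],
        [0.0, -0.6 * c, 0.7 * b],
        [0.0, y_mid, -0.6 * b],
        [0.0, -0.9 * c, 0.0],
    ])
    landmarks = LandmarkSet(sides=sides_lm, midline=midline)

    seeds = {}
    for side in ("right", "left"):
        cx, y0, cz = centers[side]
        world = np.array([cx, y0 - axes[side][1] / 2.0, cz])
        idx = np.round((world - np.asarray(origin)) / spec.spacing).astype(int)
        seeds[side] = tuple(int(i) for i in idx)

    truth = PhantomTruth(
        spec=spec,
        origin=origin,
        shape=shape,
        mirror_plane=Plane(normal=(1.0, 0.0, 0.0), point=(0.0, 0.0, 0.0)),
        rim_planes={s: Plane(normal=(0.0, 1.0, 0.0), point=centers[s])
                    for s in ("right", "left")},
        landmarks=landmarks,
        seeds=seeds,
        centers=centers,
        axes=axes,
        volumes_ml=volumes,
        analytic_volumes_ml={s: spec.analytic_volume_ml(s) for s in ("right", "left")},
        added_volume_ml=added_ml,
        residual_amplitude_mm=res_amp,
        bulge_footprint=bulge_fp,
        residual_footprint=res_fp,
        implant_indices=np.argwhere(implant_mask) if implant_mask is not None else None,
        cavity_masks={s: cav[s] & clip for s in ("right", "left")},
    )
    return vol_unaffected, vol_affected, vol_reconstructed, truth


# --------------------------------------------------------------------------
# cohort simulation

_GENDER_P_MALE = 58 / 94
_CLASS_COUNTS = {
    "anterior_central_floor": 34,
    "posterior_ledge": 20,
    "complex_medial": 32,
    "complex_lateral": 4,
}
_VOLUME_PARAMS = {"male": (26.6, 2.8), "female": (25.2, 2.6)}
# enlargement (ml): mean, sd, clip ceiling per (class, gender); ceilings
# follow the reported maxima (3.4/3.2 posterior ledge, 1.9/3.1 complex)
_ENLARGEMENT = {
    ("anterior_central_floor", "male"): (0.25, 0.2, 0.9),
    ("anterior_central_floor", "female"): (0.25, 0.2, 0.9),
    ("posterior_ledge", "male"): (1.8, 0.8, 3.4),
    ("posterior_ledge", "female"): (1.8, 0.8, 3.2),
    ("complex_medial", "male"): (1.2, 0.5, 1.9),
    ("complex_medial", "female"): (1.6, 0.7, 3.1),
    ("complex_lateral", "male"): (1.2, 0.5, 1.9),
    ("complex_lateral", "female"): (1.2, 0.5, 1.9),
}
_REGION_DEV_MEAN = {
    "medial_anterior": -0.05, "floor_anterior": 0.27, "lateral_central": -0.23,
}


def generate_cohort(n: int = 94, seed: int = 0,
                    modality_bias_ml: float = 0.0,
                    modality_sd_ml: float = 0.8,
                    navi_residual_sd_ml: float = 0.6,
                    conv_correction: float = 0.7) -> pd.DataFrame:
    """Simulate a cohort of case records.

    Demographics follow the reported proportions (58:36 male:female,
    fracture classes 34/20/32/4, navigation for complex and posterior-ledge
    patterns); unaffected volumes are drawn from the gender-specific
    normals (26.6 +/- 2.8 ml male, 25.2 +/- 2.6 ml female). CBCT
    re-measurements add zero-mean modality noise by default. Reconstruction
    removes the enlargement completely in the navigation group and a
    fraction ``conv_correction`` of it conventionally.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    classes = list(_CLASS_COUNTS)
    probs = np.array(list(_CLASS_COUNTS.values()), dtype=float)
    probs /= probs.sum()

    rows = []
    for i in range(n):
        gender = "male" if rng.random() < _GENDER_P_MALE else "female"
        fclass = classes[int(rng.choice(len(classes), p=probs))]
        side = "right" if rng.random() < 52 / 94 else "left"
        if fclass == "anterior_central_floor":
            group = "Navi" if rng.random() < 4 / 34 else "conv"
        else:
            group = "Navi"
        mu, sd = _VOLUME_PARAMS[gender]
        una_ct = rng.normal(mu, sd)
        e_mu, e_sd, e_cap = _ENLARGEMENT[(fclass, gender)]
        enlargement = float(np.clip(rng.normal(e_mu, e_sd), 0.0, e_cap))
        aff_ct = una_ct + enlargement
        una_cbct = una_ct + rng.normal(modality_bias_ml, modality_sd_ml)
        if group == "Navi":
            reco = una_cbct + rng.normal(0.0, navi_residual_sd_ml)
        else:
            reco = una_cbct + (1.0 - conv_correction) * enlargement \
                + rng.normal(0.0, navi_residual_sd_ml)
        row = {
            "case_id": f"case_{i:03d}",
            "gender": gender,
            "side": side,
            "fracture_class": fclass,
            "group": group,
            "unaffected_CT": una_ct,
            "affected_CT": aff_ct,
            "unaffected_CBCT": una_cbct,
            "reconstructed_CBCT": reco,
        }
        for region in WALL_REGIONS:
            mu_r = _REGION_DEV_MEAN.get(region, 0.0)
            row[f"dev_mean_{region}"] = rng.normal(mu_r, 0.2)
            row[f"dev_sd_{region}"] = abs(rng.normal(0.7, 0.1))
        rows.append(row)
    return pd.DataFrame(rows)
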