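"""Signed minimal-perpendicular-distance deviation mapping.

For every template vertex the shortest distance to the compared
(reconstructed) surface is computed — closest points may fall on face
interiors, edges or vertices — and signed by the target surface's
pseudonormal at the foot point: positive means the reconstructed surface
lies outside the template cavity (toward bone, i.e. an enlarged orbit),
negative means inside (toward the globe). Vertices with no target triangle
within ``max_correspondence_mm`` are flagged missing rather than zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import SurfaceDistanceQuery
from .types import SurfaceMesh

__all__ = ["DeviationMap", "signed_distance", "colorize", "deviation_summary"]

_GREEN = np.array([0.0, 1.0, 0.0])
_RED = np.array([1.0, 0.0, 0.0])
_BLUE = np.array([0.0, 0.0, 1.0])
_GREY = np.array([0.5, 0.5, 0.5])


@dataclass
class DeviationMap:
    """Per-template-vertex signed deviation in mm.

    ``values`` is NaN where ``valid`` is False (no correspondence within
    range). ``clamp_mm`` is the display clamp used by :func:`colorize`.
    """

    values: np.ndarray
    valid: np.ndarray
    clamp_mm: float = 1.5

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have the same shape")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("valid deviations must be finite")

    @property
    def missing_fraction(self) -> float:
        return float(1.0 - self.valid.mean()) if len(self.valid) else 0.0


def signed_distance(template: SurfaceMesh, target: SurfaceMesh,
                    max_correspondence_mm: float = 5.0,
                    clamp_mm: float = 1.5, return_closest: bool = False):
    """Deviation map from template vertices to the target surface.

    Both meshes must already be in the same frame (apply the registration
    result to the template first). Positive values: target outside the
    template cavity. With ``return_closest`` the per-vertex foot points on
    the target are returned alongside the map.
    """
    query = SurfaceDistanceQuery(target)
    signed, closest, _ = query.signed(template.vertices)
    # signed > 0 means the template vertex lies outside the target surface,
    # i.e. the target is inside the template cavity -> negative deviation
    values = -signed
    valid = np.abs(values) <= max_correspondence_mm
    values = np.where(valid, values, np.nan)
    dev = DeviationMap(values=values, valid=valid, clamp_mm=clamp_mm)
    if return_closest:
        return dev, closest
    return dev


def colorize(dev: DeviationMap, clamp_mm: float | None = None) -> np.ndarray:
    """Symmetric diverging colormap over the deviation map.

    Green at zero deviation, pure red at +clamp, pure blue at -clamp,
    linear in between and saturated beyond; missing vertices grey. Returns
    float RGB in [0, 1], shape (n, 3).
    """
    clamp = dev.clamp_mm if clamp_mm is None else float(clamp_mm)
    if clamp <= 0:
        raise ValueError("clamp_mm must be positive")
    t = np.clip(np.nan_to_num(dev.values) / clamp, -1.0, 1.0)
    rgb = np.empty((len(t), 3))
    pos = t >= 0
    rgb[pos] = (1 - t[pos, None]) * _GREEN + t[pos, None] * _RED
    rgb[~pos] = (1 + t[~pos, None]) * _GREEN + (-t[~pos, None]) * _BLUE
    rgb[~dev.valid] = _GREY
    return rgb


def deviation_summary(dev: DeviationMap, labels, region_order=None) -> pd.DataFrame:
    """Per-region signed deviation statistics.

    ``labels`` is a per-vertex label array (or a RegionLabeling). Missing
    vertices are excluded from the moments and reported as a missing
    fraction; regions with no valid vertex get n = 0 and NaN moments
    rather than an error.
    """
    labels = np.asarray(getattr(labels, "labels", labels))
    if labels.shape[0] != dev.values.shape[0]:
        raise ValueError("labels must cover every template vertex")
    if region_order is None:
        from .phantom import WALL_REGIONS

        region_order = list(WALL_REGIONS)
        region_order += [r for r in np.unique(labels) if r not in region_order]
    rows = []
    for region in region_order:
        in_region = labels == region
        ok = in_region & dev.valid
        vals = dev.values[ok]
        rows.append({
            "region": region,
            "n_vertices": int(in_region.sum()),
            "n_valid": int(ok.sum()),
            "mean_mm": float(vals.mean()) if len(vals) else np.nan,
            "sd_mm": float(vals.std(ddof=1)) if len(vals) > 1 else (0.0 if len(vals) else np.nan),
            "max_abs_mm": float(np.abs(vals).max()) if len(vals) else np.nan,
            "missing_fraction": float(1.0 - ok.sum() / in_region.sum()) if in_region.any() else 0.0,
        })
    return pd.DataFrame(rows)
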