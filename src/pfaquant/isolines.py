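"""Isoline extraction and superlevel-set areas on 2-D field planes.

Contours are marching squares (``skimage.measure.find_contours``) with
linear interpolation along cell edges; saddle cells are disambiguated by
skimage's average-of-corners rule.  Superlevel areas are computed from
the oriented contour polygons, which is equivalent to counting cells with
fractional edge cells handled by the same linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .solver import FieldPlane


@dataclass
class IsolineSet:
    plane_axis: str
    offset: float
    levels: list[float]
    # one polyline list per level; vertices are (u_mm, v_mm)
    contours: dict[float, list[np.ndarray]]


def _index_to_mm(contour_rc: np.ndarray, plane: FieldPlane) -> np.ndarray:
    out = np.empty_like(contour_rc)
    out[:, 0] = plane.u[0] + contour_rc[:, 0] * plane.du
    out[:, 1] = plane.v[0] + contour_rc[:, 1] * plane.dv
    return out


def extract_isolines(plane: FieldPlane, levels: list[float]) -> IsolineSet:
    """Marching-squares contours of |E| at the given positive levels (V/cm).

    A level above the plane maximum simply yields an empty contour list.
    """
    levels = [float(lv) for lv in levels]
    if any(lv <= 0 for lv in levels):
        raise ValueError("isoline levels must be strictly positive")
    contours: dict[float, list[np.ndarray]] = {}
    for lv in levels:
        cs = measure.find_contours(plane.values, lv)
        contours[lv] = [_index_to_mm(c, plane) for c in cs]
    return IsolineSet(plane.plane_axis, plane.offset, levels, contours)


def superlevel_polygons(plane: FieldPlane, level: float) -> list[np.ndarray]:
    """Closed, oriented polygons bounding the region {|E| >= level}.

    The plane is padded with a far-below value so regions touching the
    boundary close along it; vertex coordinates are clipped back to the
    plane extent.  With ``positive_orientation='high'`` outer boundaries
    are counter-clockwise and holes clockwise, so signed shoelace areas
    sum to the region area.
    """
    vals = plane.values
    pad_val = float(min(vals.min(), level) - max(1.0, abs(level)))
    padded = np.pad(vals, 1, constant_values=pad_val)
    cs = measure.find_contours(padded, level, positive_orientation="high")
    polys = []
    for c in cs:
        c = c - 1.0  # undo pad offset
        c[:, 0] = np.clip(c[:, 0], 0, vals.shape[0] - 1)
        c[:, 1] = np.clip(c[:, 1], 0, vals.shape[1] - 1)
        polys.append(_index_to_mm(c, plane))
    return polys


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def superlevel_area(plane: FieldPlane, level: float) -> float:
    """Area (mm^2) of the superlevel set {|E| >= level}; non-increasing in level."""
    if level <= 0:
        raise ValueError("level must be > 0")
    if level <= plane.values.min():
        return plane.extent_area
    if level > plane.values.max():
        return 0.0
    # outer boundaries and holes carry opposite signed areas; a global
    # orientation flip only changes the overall sign, so take |sum|
    area = sum(_signed_area(p) for p in superlevel_polygons(plane, level))
    return float(abs(area))
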