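"""Similarity-scaled trapezoidal lesion volumetry.

One top-view photograph gives the surface lesion area A_top; one cut
view gives the lesion outline over depth.  Under the similarity
assumption — cross-sections at depth z are geometrically similar scaled
copies of the surface lesion, which holds when the field's equipotential
contours keep their shape with depth — the cross-sectional area is
A(z) = r(z)^2 * A_top, where r(z) is the ratio of the lesion chord at
depth z (parallel to the top cut line) to the top cut line length.  The
volume is V = integral_0^d A(z) dz, evaluated with the trapezoidal rule
on a uniform depth grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon

from .errors import GeometryError, MetricError
from .imaging import CutViewPolygon, measure_depth
from .isolines import superlevel_polygons
from .solver import FieldSolution, slice_field


@dataclass
class DepthProfile:
    """Uniform depth samples with their chord ratios and scaled areas."""

    z: np.ndarray                 # mm, 0..d inclusive
    ratio: np.ndarray             # r(z), dimensionless; r(0) = 1
    area: np.ndarray | None = None  # mm^2, filled by similarity_volume
    capped: bool = False          # True if any raw ratio exceeded the cap


@dataclass
class VolumeResult:
    volume: float                 # mm^3
    n_slices: int
    profile: DepthProfile
    similarity_assumed: bool = True


def _chord_length(poly: Polygon, p0: np.ndarray, line_dir: np.ndarray,
                  normal: np.ndarray, z: float, single_interval: bool) -> float:
    big = 1e4
    base = p0 + normal * z
    cut = LineString([base - line_dir * big, base + line_dir * big])
    inter = poly.intersection(cut)
    if inter.is_empty:
        return 0.0
    if single_interval:
        # span between the outermost crossings, ignoring interior gaps
        pts = []
        geoms = getattr(inter, "geoms", [inter])
        for g in geoms:
            pts.extend(np.asarray(g.coords))
        t = (np.asarray(pts) - base) @ line_dir
        return float(t.max() - t.min())
    return float(inter.length)


def width_ratio_profile(polygon: CutViewPolygon, n_slices: int = 101,
                        r_cap: float = 1.05,
                        single_interval: bool = False) -> DepthProfile:
    """Chord ratios r(z) on a uniform depth grid from 0 to the lesion depth.

    For non-convex sections the chord is the total covered interval
    length (sum of sub-chords); ``single_interval=True`` instead uses the
    span between the outermost boundary crossings.  Ratios above
    ``r_cap`` (surface digitization noise) are clipped and flagged;
    r(0) = 1 by construction.
    """
    if n_slices < 2:
        raise MetricError("need at least 2 depth samples")
    L0 = polygon.top_line_length
    if L0 <= 0:
        raise GeometryError("top cut line has zero length")
    d = measure_depth(polygon)
    z = np.linspace(0.0, d, n_slices)
    poly = polygon.shapely()
    p0 = np.asarray(polygon.top_line[0], float)
    line = polygon.top_line[1] - polygon.top_line[0]
    line_dir = line / L0
    normal = np.asarray(polygon.depth_direction, float)

    ratios = np.empty(n_slices)
    ratios[0] = 1.0
    eps = 1e-6 * max(d, 1.0)
    for i, zi in enumerate(z[1:], start=1):
        zq = min(zi, d - eps) if zi >= d else zi
        ratios[i] = _chord_length(poly, p0, line_dir, normal, zq, single_interval) / L0
    capped = bool((ratios > r_cap).any())
    if capped:
        import warnings

        warnings.warn(f"chord ratio exceeded cap {r_cap}; clipped", stacklevel=2)
    ratios = np.clip(ratios, 0.0, r_cap)
    return DepthProfile(z=z, ratio=ratios, capped=capped)


def similarity_volume(area_top: float, profile: DepthProfile) -> VolumeResult:
    """V = trapezoid of A(z) = r(z)^2 * A_top over the depth grid."""
    if area_top < 0:
        raise MetricError("top area must be >= 0")
    if len(profile.z) < 2:
        raise MetricError("need at least 2 depth samples")
    area = profile.ratio**2 * area_top
    volume = float(np.trapezoid(area, profile.z))
    prof = DepthProfile(z=profile.z, ratio=profile.ratio, area=area,
                        capped=profile.capped)
    return VolumeResult(volume=volume, n_slices=len(profile.z), profile=prof)


@dataclass
class SimilarityDiagnostic:
    """How well depth cross-sections are scaled copies of the top contour."""

    depths: np.ndarray
    discrepancy: np.ndarray      # per-depth normalized symmetric-difference area
    mean_discrepancy: float
    skipped_depths: list[float] = field(default_factory=list)


def _largest_contour_polygon(plane, level: float) -> Polygon | None:
    polys = [Polygon(p) for p in superlevel_polygons(plane, level) if len(p) >= 3]
    polys = [p.buffer(0) for p in polys if not p.is_empty]
    polys = [p for p in polys if p.area > 0]
    if not polys:
        return None
    return max(polys, key=lambda p: p.area)


def _normalize(poly: Polygon, axis_extent_fn) -> Polygon:
    from shapely import affinity

    w = axis_extent_fn(poly)
    if w <= 0:
        return poly
    c = poly.centroid
    moved = affinity.translate(poly, -c.x, -c.y)
    return affinity.scale(moved, 1.0 / w, 1.0 / w, origin=(0, 0))


def validate_similarity_assumption(field_solution: FieldSolution, level: float,
                                   depths: np.ndarray | None = None) -> SimilarityDiagnostic:
    """Quantify the similarity assumption for a solved scene.

    For each depth, the superlevel contour of |E| at ``level`` on the
    horizontal plane is normalized (centred, scaled to unit width along
    the electrode axis) and compared with the normalized top contour by
    the area of their symmetric difference over the union's area — 0 for
    exactly self-similar fields, approaching 1 for unrelated shapes.
    """
    h = field_solution.spacing
    z = field_solution.axis_coords(2)
    if depths is None:
        zmax = min(z[-1], 3.0)
        depths = np.linspace(h / 2, zmax, 6)

    top_plane = slice_field(field_solution, "z", h / 2)

    def x_extent(p: Polygon) -> float:
        x0, _, x1, _ = p.bounds
        return x1 - x0

    ref = _largest_contour_polygon(top_plane, level)
    if ref is None:
        raise MetricError(f"no contour at {level} V/cm on the top plane")
    ref_n = _normalize(ref, x_extent)

    vals, used, skipped = [], [], []
    for d in np.atleast_1d(depths):
        pl = slice_field(field_solution, "z", float(d))
        poly = _largest_contour_polygon(pl, level)
        if poly is None:
            skipped.append(float(d))
            continue
        pn = _normalize(poly, x_extent)
        union = ref_n.union(pn).area
        vals.append(ref_n.symmetric_difference(pn).area / union if union > 0 else 0.0)
        used.append(float(d))
    if not vals:
        raise MetricError("contour empty at every requested depth")
    vals = np.asarray(vals)
    return SimilarityDiagnostic(depths=np.asarray(used), discrepancy=vals,
                                mean_discrepancy=float(vals.mean()),
                                skipped_depths=skipped)
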