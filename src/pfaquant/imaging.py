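"""Lesion photograph analysis: calibration, segmentation, 2-D metrics.

Stained-lesion photographs (top view of the treated slice surface and a
cut view through the lesion) are segmented by brightness thresholding:
pixels whose Rec. 601 luma falls below the threshold are "stained".
Speck-sized connected components are dropped and holes filled, which
removes stray dye marks and glare while keeping lesions that split into
one stained lobe per electrode.  Areas are plain pixel counts times the
calibrated pixel area; lengths come from a two-point scale calibration.

Pixel model: a pixel is a unit square.  Length is the maximum Feret
(caliper) diameter of the pixel-centre set plus one pixel, width the
extent perpendicular to the length axis plus one pixel; a single pixel
therefore measures one pixel size in both directions.

Image coordinates: origin top-left, x right (columns), y down (rows);
in the cut view depth increases with y once the top cut line is placed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon
from skimage import measure

from .errors import GeometryError, MetricError


@dataclass(frozen=True)
class ImageCalibration:
    """Two reference points a known physical distance apart."""

    point_a: tuple[float, float]   # pixels (x, y)
    point_b: tuple[float, float]
    known_distance_mm: float
    mm_per_pixel: float

    def px_to_mm(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) * self.mm_per_pixel


def calibrate(image, point_a, point_b, known_distance_mm: float) -> ImageCalibration:
    """Derive mm/px from two points and their known separation."""
    pa, pb = np.asarray(point_a, float), np.asarray(point_b, float)
    d_px = float(np.hypot(*(pb - pa)))
    if d_px == 0:
        raise GeometryError("calibration points coincide")
    if d_px < 5:
        raise GeometryError(f"calibration points only {d_px:.1f} px apart (need >= 5)")
    if known_distance_mm <= 0:
        raise GeometryError("known distance must be > 0")
    return ImageCalibration(tuple(pa), tuple(pb), known_distance_mm,
                            known_distance_mm / d_px)


@dataclass
class LesionMask:
    view: str                 # "top" or "cut"
    mask: np.ndarray          # bool, aligned to the source image
    threshold: int
    calibration: ImageCalibration
    empty_warning: bool = False


def rec601_luma(image: np.ndarray) -> np.ndarray:
    """8-bit luma; grayscale images pass through."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img.astype(float)
    rgb = img[..., :3].astype(float)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def stained_pixels(image: np.ndarray, threshold: float) -> np.ndarray:
    """Raw stained-pixel set (luma < threshold), before cleanup.

    Monotone in the threshold: a higher threshold can only add pixels.
    """
    return rec601_luma(image) < threshold


def segment_stained(image, threshold: int, calibration: ImageCalibration,
                    view: str = "top", min_component_frac: float = 0.1) -> LesionMask:
    """Threshold, drop speck components, fill holes.

    Components smaller than ``min_component_frac`` of the largest one are
    treated as stray dye specks or glare artefacts and removed; larger
    ones are kept because lesions can legitimately split into one stained
    lobe per electrode.  An empty result is returned with a warning flag
    rather than raised, so batch runs proceed.
    """
    if not (0 <= threshold <= 255):
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    raw = stained_pixels(image, threshold)
    if not raw.any():
        warnings.warn(f"{view} view: no pixel below threshold {threshold}", stacklevel=2)
        return LesionMask(view, raw, threshold, calibration, empty_warning=True)
    lab, n = ndimage.label(raw)
    if n > 1:
        counts = np.bincount(lab.ravel())[1:]
        keep = np.nonzero(counts >= min_component_frac * counts.max())[0] + 1
        raw = np.isin(lab, keep)
    mask = ndimage.binary_fill_holes(raw)
    return LesionMask(view, mask, threshold, calibration)


def measure_area(mask: LesionMask) -> float:
    """Stained area in mm^2 = pixel count x pixel area."""
    return float(mask.mask.sum()) * mask.calibration.mm_per_pixel**2


def _feret_points(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return np.column_stack([xs, ys]).astype(float)


def measure_length_width(mask: LesionMask) -> tuple[float, float]:
    """(length, width) in mm.

    Length: maximum Feret diameter. Width: maximum extent perpendicular
    to the length axis.  Both use pixel centres plus one pixel so the
    degenerate single-pixel mask measures one pixel size each way.
    """
    pts = _feret_points(mask.mask)
    if len(pts) == 0:
        raise MetricError("length/width undefined for an empty mask")
    mpp = mask.calibration.mm_per_pixel
    if len(pts) == 1:
        return mpp, mpp
    try:
        hull = pts[ConvexHull(pts).vertices]
    except QhullError:  # collinear pixel set
        hull = pts
    # rotating-calipers-by-enumeration: hulls here are small
    d2 = np.sum((hull[:, None, :] - hull[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    length_px = math.sqrt(d2[i, j])
    axis = (hull[j] - hull[i]) / length_px
    normal = np.array([-axis[1], axis[0]])
    proj = hull @ normal
    width_px = float(proj.max() - proj.min())
    return (length_px + 1.0) * mpp, (width_px + 1.0) * mpp


@dataclass
class CutViewPolygon:
    """Lesion outline in the cut plane, with its surface reference line.

    Coordinates are physical mm in the cut plane.  ``top_line`` holds the
    two endpoints where the lesion meets the cut (surface) line; the
    depth axis is the perpendicular bisector of that line oriented toward
    the tissue side.
    """

    vertices: np.ndarray          # (n, 2) mm
    top_line: np.ndarray          # (2, 2) mm
    depth_direction: np.ndarray   # unit vector into the tissue

    def __post_init__(self):
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise GeometryError(f"cut polygon is not simple: {poly.buffer(0).geom_type}")

    @property
    def top_line_length(self) -> float:
        return float(np.hypot(*(self.top_line[1] - self.top_line[0])))

    @property
    def top_line_midpoint(self) -> np.ndarray:
        return self.top_line.mean(axis=0)

    def shapely(self) -> Polygon:
        return Polygon(self.vertices)


def trace_cut_polygon(cut_mask: LesionMask, top_line_points,
                      simplify_px: float = 1.0) -> CutViewPolygon:
    """Automatic cut-view polygonization.

    The mask boundary is contoured (marching squares), simplified, and
    clipped to the tissue side of the user-supplied top cut line; the
    clipped boundary's intersection with that line becomes the polygon's
    top cut line and its perpendicular bisector the depth axis.
    ``top_line_points`` are two pixel-coordinate points on the surface.
    """
    if not cut_mask.mask.any():
        raise MetricError("cannot trace a polygon on an empty mask")
    cal = cut_mask.calibration
    mpp = cal.mm_per_pixel
    p0 = np.asarray(top_line_points[0], float) * mpp
    p1 = np.asarray(top_line_points[1], float) * mpp
    line_vec = p1 - p0
    line_len = float(np.hypot(*line_vec))
    if line_len == 0:
        raise GeometryError("top cut line has zero length")
    line_dir = line_vec / line_len
    normal = np.array([-line_dir[1], line_dir[0]])  # y-down: points into tissue if below line

    contours = measure.find_contours(cut_mask.mask.astype(float), 0.5)
    if not contours:
        raise MetricError("no boundary contour found")
    contour = max(contours, key=len)  # (row, col) = (y, x)
    verts_mm = np.column_stack([contour[:, 1], contour[:, 0]]) * mpp
    poly = Polygon(verts_mm).buffer(0).simplify(simplify_px * mpp)
    if poly.is_empty:
        raise MetricError("mask boundary degenerate after simplification")
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)

    # orient the normal toward the bulk of the lesion, then clip to that side
    centroid = np.asarray(poly.centroid.coords[0])
    if np.dot(centroid - p0, normal) < 0:
        normal = -normal
    big = 1e4
    half_plane = Polygon([
        p0 - line_dir * big,
        p0 + line_dir * big,
        p0 + line_dir * big + normal * big,
        p0 - line_dir * big + normal * big,
    ])
    clipped = poly.intersection(half_plane)
    if clipped.is_empty:
        raise GeometryError("lesion lies entirely above the top cut line")
    if clipped.geom_type == "MultiPolygon":
        clipped = max(clipped.geoms, key=lambda g: g.area)
    verts = np.asarray(clipped.exterior.coords[:-1])

    # vertices lying on the cut line delimit the polygon's top cut line
    signed = (verts - p0) @ normal
    on_line = np.abs(signed) <= 1.5 * mpp
    if on_line.sum() >= 2:
        t = (verts[on_line] - p0) @ line_dir
        a = p0 + line_dir * t.min()
        b = p0 + line_dir * t.max()
    else:  # lesion barely touches the line; fall back to the user points
        a, b = p0, p1
    return CutViewPolygon(vertices=verts, top_line=np.array([a, b]),
                          depth_direction=normal)


@dataclass
class LesionMetrics:
    """Per-slice lesion metrics; ``volume`` is filled by the volumetry stage."""

    area_top_mm2: float
    length_mm: float
    width_mm: float
    depth_mm: float
    volume_mm3: float | None = None
    condition: str = ""

    def __post_init__(self):
        vals = [self.area_top_mm2, self.length_mm, self.width_mm, self.depth_mm]
        if any(v < 0 for v in vals):
            raise MetricError(f"negative lesion metric: {vals}")


def measure_depth(polygon: CutViewPolygon) -> float:
    """Maximum vertex distance from the top cut line along the depth axis (mm)."""
    signed = (polygon.vertices - polygon.top_line[0]) @ polygon.depth_direction
    return float(max(signed.max(), 0.0))
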