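"""Ground-truthed synthetic lesions and rendered photograph pairs.

No public image dataset exists for stained-tuber PFA lesions, so every
pipeline stage is exercised against internally generated ground truth:

* parametric solids (half-ellipsoids and two-lobed "peanut" unions, the
  shapes stained lesions actually take) with closed-form or voxel-counted
  truth metrics;
* field-derived lesions: 3-D superlevel sets of a solved field at a
  chosen lethal threshold, the construction the threshold calibration
  must invert;
* rendered top/cut view images: dark stained lesion on a light tuber
  background with a linear illumination gradient, Gaussian sensor noise,
  a burned-in scale bar and electrode marks, plus a JSON truth sidecar.

Rendering is luma-only by design: segmentation is brightness
thresholding, so texture realism adds nothing to validity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from shapely.geometry import Polygon
from shapely.ops import unary_union
from skimage import draw

from .errors import GeometryError, MetricError
from .isolines import superlevel_polygons
from .solver import FieldSolution, slice_field


@dataclass
class GroundTruthLesion:
    kind: str                      # "half_ellipsoid" | "peanut" | "field_superlevel"
    params: dict
    area_top_mm2: float
    depth_mm: float
    volume_mm3: float
    # outer boundary of every stained lobe; most lesions have one lobe but
    # field superlevel sets can split into one lobe per electrode
    top_polygons: list[np.ndarray]   # (n, 2) mm, scene (x, y)
    cut_polygons: list[np.ndarray]   # (n, 2) mm, cut plane (x, z), z >= 0


@dataclass
class RenderSpec:
    """Deterministic photograph renderer parameters (luma units 0-255)."""

    mm_per_pixel: float = 0.05
    x_range_mm: tuple[float, float] = (-12.0, 12.0)
    y_range_mm: tuple[float, float] = (-9.0, 9.0)    # top view
    z_range_mm: tuple[float, float] = (-2.0, 7.0)    # cut view (depth)
    background_luma: int = 220
    above_surface_luma: int = 245
    lesion_luma: int = 40
    gradient_amplitude: float = 15.0   # linear left-right illumination drift
    noise_sigma: float = 8.0
    scale_bar_mm: float = 10.0
    fiducial_luma: int = 150   # above stain thresholds so fiducials never segment
    seed: int = 0

    def __post_init__(self):
        for v in (self.background_luma, self.lesion_luma, self.above_surface_luma):
            if not (0 <= v <= 255):
                raise ValueError(f"luma {v} outside [0, 255]")


def _ellipse_polygon(a: float, b: float, n: int = 256) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(t), b * np.sin(t)])


def _half_ellipse_polygon(a: float, c: float, n: int = 129) -> np.ndarray:
    """Half ellipse in the (x, z) cut plane, z >= 0, closed along z = 0."""
    t = np.linspace(0.0, np.pi, n)
    arc = np.column_stack([a * np.cos(t), c * np.sin(t)])
    return arc[::-1]  # from (-a, 0) over the apex to (a, 0)


def voxel_volume(inside_fn, bounds, voxel_mm: float = 0.05) -> float:
    """Brute-force voxel-counted volume of {(x,y,z): inside_fn} in mm^3."""
    (x0, x1), (y0, y1), (z0, z1) = bounds
    x = np.arange(x0 + voxel_mm / 2, x1, voxel_mm)
    y = np.arange(y0 + voxel_mm / 2, y1, voxel_mm)
    z = np.arange(z0 + voxel_mm / 2, z1, voxel_mm)
    total = 0
    for zi in z:  # slab-wise to bound memory
        X, Y = np.meshgrid(x, y, indexing="ij")
        total += int(inside_fn(X, Y, zi).sum())
    return total * voxel_mm**3


def make_parametric_lesion(kind: str, params: dict,
                           slab_height_mm: float = 20.0) -> GroundTruthLesion:
    """Analytic lesion solids.

    ``half_ellipsoid``: semi-axes a (x), b (y), c (depth); truth
    area = pi*a*b, depth = c, volume = (2/3)*pi*a*b*c.
    ``peanut``: union of two half-ellipsoids with centres offset by
    +-``offset`` along x; truth volume by voxel counting (0.05 mm).
    """
    if kind == "half_ellipsoid":
        a, b, c = (float(params[k]) for k in ("a", "b", "c"))
        if min(a, b, c) <= 0:
            raise GeometryError("semi-axes must be > 0")
        if c > slab_height_mm:
            raise GeometryError(f"lesion depth {c} mm exceeds slab height {slab_height_mm} mm")
        return GroundTruthLesion(
            kind=kind, params={"a": a, "b": b, "c": c},
            area_top_mm2=np.pi * a * b, depth_mm=c,
            volume_mm3=2.0 / 3.0 * np.pi * a * b * c,
            top_polygons=[_ellipse_polygon(a, b)],
            cut_polygons=[_half_ellipse_polygon(a, c)],
        )
    if kind == "peanut":
        a, b, c = (float(params[k]) for k in ("a", "b", "c"))
        off = float(params.get("offset", a / 2))
        if min(a, b, c) <= 0 or off < 0:
            raise GeometryError("semi-axes must be > 0 and offset >= 0")
        if c > slab_height_mm:
            raise GeometryError(f"lesion depth {c} mm exceeds slab height {slab_height_mm} mm")

        def inside(X, Y, z):
            if z >= c:
                return np.zeros(X.shape, bool)
            s = 1.0 - (z / c) ** 2
            lobe1 = ((X - off) ** 2 / a**2 + Y**2 / b**2) <= s
            lobe2 = ((X + off) ** 2 / a**2 + Y**2 / b**2) <= s
            return lobe1 | lobe2

        vol = voxel_volume(inside, ((-off - a, off + a), (-b, b), (0, c)))
        lobes = [Polygon(_ellipse_polygon(a, b) + np.array([off, 0.0])),
                 Polygon(_ellipse_polygon(a, b) + np.array([-off, 0.0]))]
        top = unary_union(lobes)
        top_poly = np.asarray(top.exterior.coords[:-1])
        cuts = unary_union([
            Polygon(_half_ellipse_polygon(a, c) + np.array([off, 0.0])).buffer(0),
            Polygon(_half_ellipse_polygon(a, c) + np.array([-off, 0.0])).buffer(0),
        ])
        if cuts.geom_type == "MultiPolygon":
            cuts = max(cuts.geoms, key=lambda g: g.area)
        cut_poly = np.asarray(cuts.exterior.coords[:-1])
        return GroundTruthLesion(
            kind=kind, params={"a": a, "b": b, "c": c, "offset": off},
            area_top_mm2=float(top.area), depth_mm=c, volume_mm3=vol,
            top_polygons=[top_poly], cut_polygons=[cut_poly],
        )
    raise ValueError(f"unknown lesion kind {kind!r}")


def make_field_lesion(solution: FieldSolution, threshold_v_per_cm: float) -> GroundTruthLesion:
    """Lesion as the 3-D superlevel set {|E| >= threshold} inside the tissue.

    Truth area/depth/volume by voxel counting on the solver grid; the top
    mask is the tissue-surface slice, the cut polygon the mid-electrode
    (y = 0) vertical plane slice.
    """
    z = solution.axis_coords(2)
    tissue = z > 0
    e = solution.e_magnitude[:, :, tissue]
    if threshold_v_per_cm > e.max():
        raise MetricError(
            f"threshold {threshold_v_per_cm} V/cm above tissue field maximum {e.max():.1f}"
        )
    vox = e >= threshold_v_per_cm
    if not vox.any():
        raise MetricError("empty superlevel set")
    h = solution.spacing
    volume = float(vox.sum()) * h**3
    area_top = float(vox[:, :, 0].sum()) * h**2
    z_t = z[tissue]
    depth = float(z_t[np.nonzero(vox.any(axis=(0, 1)))[0][-1]] + h / 2)

    top_plane = slice_field(solution, "z", h / 2)
    top_polygons = _outer_lobes(superlevel_polygons(top_plane, threshold_v_per_cm))
    if not top_polygons:
        raise MetricError("no top-surface contour at the requested threshold")

    cut_plane = slice_field(solution, "y", 0.0)   # axes (x, z)
    cut_polys = _outer_lobes(superlevel_polygons(cut_plane, threshold_v_per_cm))
    if not cut_polys:
        raise MetricError("no cut-plane contour at the requested threshold")
    half = Polygon([(-1e4, 0.0), (1e4, 0.0), (1e4, 1e4), (-1e4, 1e4)])
    cut_polygons = []
    for p in cut_polys:
        clipped = Polygon(p).buffer(0).intersection(half)
        geoms = clipped.geoms if clipped.geom_type == "MultiPolygon" else [clipped]
        for g in geoms:
            if not g.is_empty and g.area > 0:
                cut_polygons.append(np.asarray(g.exterior.coords[:-1]))
    if not cut_polygons:
        raise MetricError("superlevel set does not reach into the tissue on the cut plane")

    return GroundTruthLesion(
        kind="field_superlevel",
        params={"threshold_v_per_cm": float(threshold_v_per_cm),
                "applied_voltage": solution.applied_voltage,
                "spacing_mm": h},
        area_top_mm2=area_top, depth_mm=depth, volume_mm3=volume,
        top_polygons=top_polygons, cut_polygons=cut_polygons,
    )


def _outer_lobes(polys: list[np.ndarray], min_frac: float = 0.01) -> list[np.ndarray]:
    """Keep outer boundaries (majority orientation) above an area floor."""
    if not polys:
        return []
    areas = [_poly_area(p) for p in polys]
    dominant = np.sign(areas[int(np.argmax(np.abs(areas)))])
    amax = max(abs(a) for a in areas)
    return [p for p, a in zip(polys, areas)
            if np.sign(a) == dominant and abs(a) >= min_frac * amax]


def _poly_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# rendering

def _mm_to_px(pts_mm: np.ndarray, origin_mm, mpp: float) -> np.ndarray:
    """Scene mm -> image (x_px, y_px), origin at the canvas top-left corner."""
    p = np.asarray(pts_mm, float)
    return (p - np.asarray(origin_mm)) / mpp - 0.5


def _render_canvas(shape, spec: RenderSpec, rng) -> np.ndarray:
    ny, nx = shape
    base = np.full((ny, nx), float(spec.background_luma))
    ramp = np.linspace(-1.0, 1.0, nx)[None, :]
    base += spec.gradient_amplitude * ramp
    if spec.noise_sigma > 0:
        base = base + rng.normal(0.0, spec.noise_sigma, size=(ny, nx))
    return base


def _burn_polygon(canvas: np.ndarray, poly_px: np.ndarray, luma: float) -> None:
    # scanline fill is pixel-count unbiased for smooth shapes
    rr, cc = draw.polygon(poly_px[:, 1], poly_px[:, 0], shape=canvas.shape)
    canvas[rr, cc] = luma


def _finish(canvas: np.ndarray) -> Image.Image:
    arr = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    return Image.fromarray(np.repeat(arr[:, :, None], 3, axis=2), mode="RGB")


def render_views(lesion: GroundTruthLesion, spec: RenderSpec,
                 electrode_marks_mm: np.ndarray | None = None):
    """Render the top and cut view photographs plus the truth sidecar.

    Returns ``(top_image, cut_image, sidecar_dict)``; the sidecar holds
    every ground-truth value and the render transform (canvas origin and
    mm/px), the burned scale-bar endpoints and electrode-mark pixel
    positions.  The same seed reproduces the images byte-exactly; the
    seed perturbs only the noise, never the truth values.
    """
    mpp = spec.mm_per_pixel
    x0, x1 = spec.x_range_mm
    y0, y1 = spec.y_range_mm
    z0, z1 = spec.z_range_mm
    nx = int(round((x1 - x0) / mpp))
    ny = int(round((y1 - y0) / mpp))
    nz = int(round((z1 - z0) / mpp))

    for tp in lesion.top_polygons:
        if (tp[:, 0].min() < x0 or tp[:, 0].max() > x1
                or tp[:, 1].min() < y0 or tp[:, 1].max() > y1):
            raise GeometryError("lesion exceeds the top-view canvas")
    for cp in lesion.cut_polygons:
        if cp[:, 0].min() < x0 or cp[:, 0].max() > x1 or cp[:, 1].max() > z1:
            raise GeometryError("lesion exceeds the cut-view canvas")

    rng = np.random.default_rng(spec.seed)

    # --- top view: scene (x, y) -> pixel (col, row)
    top = _render_canvas((ny, nx), spec, rng)
    for tp in lesion.top_polygons:
        _burn_polygon(top, _mm_to_px(tp, (x0, y0), mpp), spec.lesion_luma)

    # --- cut view: (x, z) -> pixel; rows above the surface line are bath/air
    cut = _render_canvas((nz, nx), spec, rng)
    surface_row = int(round(-z0 / mpp))
    cut[:surface_row, :] = spec.above_surface_luma
    for cp in lesion.cut_polygons:
        _burn_polygon(cut, _mm_to_px(cp, (x0, z0), mpp), spec.lesion_luma)

    # --- burned-in fiducials (after noise: crisp, deterministic)
    bar_row = ny - 20
    bar_c0 = 10
    bar_c1 = bar_c0 + int(round(spec.scale_bar_mm / mpp))
    top[bar_row - 2:bar_row + 3, bar_c0:bar_c1 + 1] = spec.fiducial_luma
    cut_bar_row = nz - 12
    cut[cut_bar_row - 2:cut_bar_row + 3, bar_c0:bar_c1 + 1] = spec.fiducial_luma

    if electrode_marks_mm is None:
        electrode_marks_mm = np.array([[-1.0, 0.0], [1.0, 0.0]])
    marks_px = _mm_to_px(np.asarray(electrode_marks_mm, float), (x0, y0), mpp)
    for mx, my in marks_px:
        # contact punctures are dark; inside the stained area they are
        # invisible to thresholding, outside they are specks the
        # largest-component cleanup removes
        rr, cc = draw.disk((my, mx), 2.5, shape=top.shape)
        top[rr, cc] = spec.lesion_luma

    sidecar = {
        "kind": lesion.kind,
        "params": lesion.params,
        "truth": {
            "area_top_mm2": lesion.area_top_mm2,
            "depth_mm": lesion.depth_mm,
            "volume_mm3": lesion.volume_mm3,
        },
        "render": {
            "mm_per_pixel": mpp,
            "top_origin_mm": [x0, y0],
            "cut_origin_mm": [x0, z0],
            "seed": spec.seed,
            "background_luma": spec.background_luma,
            "lesion_luma": spec.lesion_luma,
            "noise_sigma": spec.noise_sigma,
            "scale_bar_px": [[bar_c0, bar_row], [bar_c1, bar_row]],
            "scale_bar_mm": spec.scale_bar_mm,
            "cut_scale_bar_px": [[bar_c0, cut_bar_row], [bar_c1, cut_bar_row]],
            "electrode_marks_px": np.asarray(marks_px).tolist(),
            "electrode_marks_mm": np.asarray(electrode_marks_mm, float).tolist(),
            "surface_row": surface_row,
        },
        "top_polygons_mm": [tp.tolist() for tp in lesion.top_polygons],
        "cut_polygons_mm": [cp.tolist() for cp in lesion.cut_polygons],
    }
    return _finish(top), _finish(cut), sidecar


def write_views(lesion: GroundTruthLesion, spec: RenderSpec, out_dir: str | Path,
                electrode_marks_mm: np.ndarray | None = None) -> dict:
    """Render and write top.png, cut.png, truth.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    top, cut, sidecar = render_views(lesion, spec, electrode_marks_mm)
    top.save(out / "top.png")
    cut.save(out / "cut.png")
    (out / "truth.json").write_text(json.dumps(sidecar, indent=1))
    return sidecar
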