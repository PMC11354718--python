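"""End-to-end orchestration: simulate -> segment -> measure -> volume -> EFT.

Every run writes tidy per-slice metric rows (CSV), an EFT summary (CSV),
overlay figures, and a run manifest capturing the resolved config, input
digests, package version and seeds so outputs are reproducible.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import PfaQuantError
from .eft import (
    EFTEstimate,
    eft_by_area_match,
    eft_by_boundary_quantile,
    register_lesion,
)
from .imaging import (
    LesionMetrics,
    calibrate,
    measure_area,
    measure_depth,
    measure_length_width,
    segment_stained,
    trace_cut_polygon,
)
from .isolines import extract_isolines
from .scene import SceneConfig, rasterize_materials
from .solver import FieldSolution, slice_field, solve_potential
from .synth import RenderSpec, make_field_lesion, write_views
from .volumetry import similarity_volume, width_ratio_profile

DEFAULT_TOP_THRESHOLD = 120
DEFAULT_CUT_THRESHOLD = 120


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir: Path, command: str, config: SceneConfig,
                   inputs: list[Path], seed: int | None, extra: dict | None = None) -> Path:
    manifest = {
        "command": command,
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "config": config.to_dict(),
        "inputs": {str(p): _sha256(p) for p in inputs},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def load_image(path: str | Path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path))


@dataclass
class SliceAnalysis:
    metrics: LesionMetrics
    top_mask: object
    cut_polygon: object
    profile: object
    warnings: list[str]


def analyze_slice(top_image: np.ndarray, cut_image: np.ndarray,
                  top_calibration, cut_calibration,
                  top_line_points_px,
                  top_threshold: int = DEFAULT_TOP_THRESHOLD,
                  cut_threshold: int = DEFAULT_CUT_THRESHOLD,
                  n_slices: int = 101,
                  condition: str = "") -> SliceAnalysis:
    """Segment both views and compute area, length, width, depth, volume."""
    warns: list[str] = []
    top_mask = segment_stained(top_image, top_threshold, top_calibration, view="top")
    if top_mask.empty_warning:
        warns.append("empty top mask")
    cut_mask = segment_stained(cut_image, cut_threshold, cut_calibration, view="cut")
    if cut_mask.empty_warning:
        warns.append("empty cut mask")

    area = measure_area(top_mask)
    length, width = measure_length_width(top_mask)
    polygon = trace_cut_polygon(cut_mask, top_line_points_px)
    depth = measure_depth(polygon)
    profile = width_ratio_profile(polygon, n_slices=n_slices)
    if profile.capped:
        warns.append("chord ratio capped")
    vol = similarity_volume(area, profile)
    metrics = LesionMetrics(area_top_mm2=area, length_mm=length, width_mm=width,
                            depth_mm=depth, volume_mm3=vol.volume, condition=condition)
    return SliceAnalysis(metrics=metrics, top_mask=top_mask, cut_polygon=polygon,
                         profile=vol.profile, warnings=warns)


def estimate_thresholds(analysis: SliceAnalysis, solution: FieldSolution,
                        electrode_marks_px, scene: SceneConfig,
                        quantile: float = 0.5):
    """Area-match (primary) and boundary-quantile EFT estimates for one slice.

    Returns the two estimates and the registered lesion boundary (scene mm).
    """
    h = solution.spacing
    plane = slice_field(solution, "z", h / 2)
    est_area = eft_by_area_match(analysis.metrics.area_top_mm2, plane)
    est_area.condition = analysis.metrics.condition

    reg = register_lesion(analysis.top_mask, electrode_marks_px, scene)
    from skimage import measure as skmeasure

    contours = skmeasure.find_contours(analysis.top_mask.mask.astype(float), 0.5)
    boundary_px = max(contours, key=len)[:, ::-1]  # (x, y) pixels
    boundary_scene = reg.apply_px(boundary_px)
    est_bq = eft_by_boundary_quantile(boundary_scene, plane, quantile=quantile)
    est_bq.condition = analysis.metrics.condition
    est_bq.diagnostics["registration_residual_mm"] = reg.residual_mm
    return [est_area, est_bq], boundary_scene


def save_overlay(solution: FieldSolution, boundary_scene_mm: np.ndarray | None,
                 levels: list[float], out_path: Path) -> None:
    """Field heatmap with isolines and (optionally) the lesion outline."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plane = slice_field(solution, "z", solution.spacing / 2)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.pcolormesh(plane.u, plane.v, plane.values.T, shading="nearest",
                       cmap="inferno", vmax=np.percentile(plane.values, 99.5))
    fig.colorbar(im, ax=ax, label="|E| (V/cm)")
    iso = extract_isolines(plane, levels)
    for lv, cs in iso.contours.items():
        for c in cs:
            ax.plot(c[:, 0], c[:, 1], "c-", lw=1)
    if boundary_scene_mm is not None:
        ax.plot(boundary_scene_mm[:, 0], boundary_scene_mm[:, 1], "w--", lw=1.2,
                label="lesion edge")
        ax.legend(loc="upper right")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_aspect("equal")
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def metrics_to_frame(rows: list[LesionMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {"condition": m.condition, "area_mm2": m.area_top_mm2,
         "length_mm": m.length_mm, "width_mm": m.width_mm,
         "depth_mm": m.depth_mm, "volume_mm3": m.volume_mm3}
        for m in rows
    )


def export_condition_summary(metrics: pd.DataFrame,
                             grouping: list[str] = ("condition",)) -> pd.DataFrame:
    """Per-condition n / mean / SEM for every numeric metric column."""
    grouping = list(grouping)
    missing = [g for g in grouping if g not in metrics.columns]
    if missing:
        raise KeyError(f"grouping keys absent from table: {missing}")
    value_cols = [c for c in metrics.columns
                  if c not in grouping and pd.api.types.is_numeric_dtype(metrics[c])]
    gb = metrics.groupby(grouping)[value_cols]
    out = gb.agg(["count", "mean", lambda s: s.sem(ddof=1)])
    out.columns = [f"{c}_{'sem' if name.startswith('<lambda') else name}"
                   for c, name in out.columns]
    out = out.rename(columns={f"{c}_count": f"{c}_n" for c in value_cols})
    return out.reset_index()


def run_image_pipeline(config: SceneConfig, images_dir: str | Path,
                       out_dir: str | Path, spacing_mm: float | None = None,
                       n_slices: int = 101) -> dict:
    """Batch measurement of photographed slices.

    ``images_dir`` must contain ``slices.csv`` with one row per treated
    slice: top,cut image paths (relative to the directory), the two scale
    points and known distance, the cut-line points, the electrode marks
    and a condition label.  Writes metrics.csv and eft.csv.
    """
    images = Path(images_dir)
    listing = images / "slices.csv"
    if not listing.exists():
        raise FileNotFoundError(f"no inputs: {listing} not found")
    table = pd.read_csv(listing)
    if table.empty:
        raise ValueError(f"no inputs: {listing} lists no slices")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    mmap = rasterize_materials(config, spacing_mm)
    solution = solve_potential(mmap, config.recipe.amplitude)

    rows, estimates, inputs = [], [], []
    for _, r in table.iterrows():
        top_path, cut_path = images / r["top"], images / r["cut"]
        inputs.extend([top_path, cut_path])
        top_img, cut_img = load_image(top_path), load_image(cut_path)
        p1 = (r["scale_x1"], r["scale_y1"])
        p2 = (r["scale_x2"], r["scale_y2"])
        cal_top = calibrate(top_img, p1, p2, r["scale_mm"])
        cal_cut = calibrate(cut_img, p1, p2, r["scale_mm"])
        line = [(r["cut_line_x1"], r["cut_line_y1"]), (r["cut_line_x2"], r["cut_line_y2"])]
        try:
            analysis = analyze_slice(top_img, cut_img, cal_top, cal_cut, line,
                                     n_slices=n_slices,
                                     condition=str(r.get("condition", "")))
            marks = np.array([[r["mark_x1"], r["mark_y1"]], [r["mark_x2"], r["mark_y2"]]])
            ests, _ = estimate_thresholds(analysis, solution, marks, config)
        except PfaQuantError as exc:
            raise type(exc)(f"stage failure on slice {r['top']}: {exc}") from exc
        rows.append(analysis.metrics)
        estimates.extend(ests)

    metrics_to_frame(rows).to_csv(out / "metrics.csv", index=False)
    edf = pd.DataFrame(
        {"condition": e.condition, "method": e.method,
         "eft_V_per_cm": e.threshold_v_per_cm, "residual": e.residual,
         "out_of_range": e.out_of_range}
        for e in estimates
    )
    edf.to_csv(out / "eft.csv", index=False)
    write_manifest(out, "pipeline-images", config, inputs, None)
    return {"n_slices": len(rows), "out_dir": str(out)}


def run_synthetic_pipeline(config: SceneConfig, generating_threshold: float,
                           out_dir: str | Path, seed: int = 1,
                           noise_sigma: float = 8.0,
                           spacing_mm: float | None = None,
                           solution: FieldSolution | None = None,
                           n_slices: int = 101) -> dict:
    """Full determinism-controlled run on a field-derived synthetic lesion.

    Solves the configured scene, builds the lesion as the field
    superlevel set at ``generating_threshold`` (V/cm), renders the view
    pair, runs segmentation, metrics, volumetry and both EFT estimators,
    and writes metrics.csv, eft.csv, overlay.png and manifest.json.
    Returns a summary dict including the recovered thresholds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if solution is None:
        mmap = rasterize_materials(config, spacing_mm)
        solution = solve_potential(mmap, config.recipe.amplitude)
    lesion = make_field_lesion(solution, generating_threshold)

    spec = RenderSpec(noise_sigma=noise_sigma, seed=seed)
    s = config.geometry.electrode_center_distance / 2.0
    marks_mm = np.array([[-s, 0.0], [s, 0.0]])
    sidecar = write_views(lesion, spec, out, electrode_marks_mm=marks_mm)

    top_img = load_image(out / "top.png")
    cut_img = load_image(out / "cut.png")
    bar = np.asarray(sidecar["render"]["scale_bar_px"], float)
    cal_top = calibrate(top_img, bar[0], bar[1], sidecar["render"]["scale_bar_mm"])
    cbar = np.asarray(sidecar["render"]["cut_scale_bar_px"], float)
    cal_cut = calibrate(cut_img, cbar[0], cbar[1], sidecar["render"]["scale_bar_mm"])

    # the surface line in the cut view is horizontal at the known surface row
    srow = sidecar["render"]["surface_row"]
    top_line = [(0.0, float(srow) - 0.5), (float(top_img.shape[1]), float(srow) - 0.5)]

    condition = f"{config.recipe.amplitude:.0f}V_synth"
    analysis = analyze_slice(top_img, cut_img, cal_top, cal_cut, top_line,
                             n_slices=n_slices, condition=condition)
    marks_px = np.asarray(sidecar["render"]["electrode_marks_px"], float)
    estimates, boundary_scene = estimate_thresholds(analysis, solution, marks_px, config)

    mdf = metrics_to_frame([analysis.metrics])
    mdf.to_csv(out / "metrics.csv", index=False)
    edf = pd.DataFrame(
        {"condition": e.condition, "method": e.method,
         "eft_V_per_cm": e.threshold_v_per_cm, "residual": e.residual,
         "out_of_range": e.out_of_range}
        for e in estimates
    )
    edf.to_csv(out / "eft.csv", index=False)

    save_overlay(solution, boundary_scene, [generating_threshold], out / "overlay.png")

    write_manifest(out, "pipeline-synth", config,
                   [out / "top.png", out / "cut.png", out / "truth.json"], seed,
                   extra={"generating_threshold_v_per_cm": generating_threshold,
                          "noise_sigma": noise_sigma,
                          "warnings": analysis.warnings})
    area_match = next(e for e in estimates if e.method == "area_match")
    boundary = next(e for e in estimates if e.method == "boundary_quantile")
    return {
        "metrics": analysis.metrics,
        "estimates": estimates,
        "recovered_threshold_v_per_cm": area_match.threshold_v_per_cm,
        "boundary_threshold_v_per_cm": boundary.threshold_v_per_cm,
        "generating_threshold_v_per_cm": generating_threshold,
        "truth": sidecar["truth"],
        "out_dir": str(out),
    }
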