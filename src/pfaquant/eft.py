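"""Lethal electric-field-threshold (EFT) calibration.

The lesion's outer edge marks the minimum field magnitude that produces
irreversible electroporation.  Two estimators confront a measured lesion
with the simulated field:

* ``eft_by_area_match`` (primary): find the field level whose superlevel
  set has the same area as the measured lesion — bisection on the level,
  exploiting that superlevel area is non-increasing in the level.
* ``eft_by_boundary_quantile``: sample |E| along the registered lesion
  boundary and report a quantile (default the median; quantile 0 is the
  literal minimum-field reading).  The interquartile range doubles as a
  registration-quality diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import GeometryError, PlaneRangeError
from .imaging import LesionMask
from .isolines import superlevel_area
from .scene import SceneConfig
from .solver import FieldPlane


@dataclass
class ImageToSceneRegistration:
    """Rigid map (rotation + translation, scale from calibration) from
    top-view image mm coordinates to scene coordinates."""

    rotation: np.ndarray        # (2, 2)
    translation: np.ndarray     # (2,) mm, applied after rotation
    mm_per_pixel: float
    residual_mm: float          # electrode-mark fit residual

    def apply_mm(self, pts_mm: np.ndarray) -> np.ndarray:
        return np.asarray(pts_mm, float) @ self.rotation.T + self.translation

    def apply_px(self, pts_px: np.ndarray) -> np.ndarray:
        return self.apply_mm(np.asarray(pts_px, float) * self.mm_per_pixel)


def register_lesion(top_mask: LesionMask, electrode_marks,
                    scene: SceneConfig) -> ImageToSceneRegistration:
    """Rigid registration from the two electrode marks.

    The mark midpoint maps to the scene origin and the mark axis to the
    scene's inter-electrode (x) axis.  The residual is the distance of
    the mapped marks from the nominal electrode axis positions (+-s, 0).
    """
    marks = np.asarray(electrode_marks, float)
    if marks.shape != (2, 2):
        raise GeometryError("exactly two electrode marks are required")
    mpp = top_mask.calibration.mm_per_pixel
    m_mm = marks * mpp
    sep = float(np.hypot(*(m_mm[1] - m_mm[0])))
    if sep < 1.0:
        raise GeometryError(f"electrode marks only {sep:.2f} mm apart; cannot orient")

    mid = m_mm.mean(axis=0)
    axis = (m_mm[1] - m_mm[0]) / sep
    # rotation taking the mark axis onto +x
    rot = np.array([[axis[0], axis[1]], [-axis[1], axis[0]]])
    translation = -rot @ mid
    reg = ImageToSceneRegistration(rotation=rot, translation=translation,
                                   mm_per_pixel=mpp, residual_mm=0.0)
    s = scene.geometry.electrode_center_distance / 2.0
    nominal = np.array([[-s, 0.0], [s, 0.0]])
    mapped = reg.apply_mm(m_mm)
    resid = float(np.linalg.norm(mapped - nominal, axis=1).max())
    alt = float(np.linalg.norm(mapped - nominal[::-1], axis=1).max())
    reg.residual_mm = min(resid, alt)  # mark order is arbitrary (symmetric scene)
    return reg


@dataclass
class EFTEstimate:
    threshold_v_per_cm: float
    method: str                      # "area_match" | "boundary_quantile"
    quantile: float | None = None
    residual: float = 0.0            # area mismatch fraction or boundary IQR
    diagnostics: dict = field(default_factory=dict)
    out_of_range: bool = False
    condition: str = ""


def eft_by_area_match(lesion_area_mm2: float, plane: FieldPlane,
                      rel_tol: float = 0.005, max_iter: int = 60) -> EFTEstimate:
    """Invert superlevel area: find E* with area{|E| >= E*} = lesion area.

    Bisection on [1 V/cm, plane maximum]; converges when the relative
    area mismatch drops below ``rel_tol`` or after ``max_iter`` halvings.
    A lesion larger than the area at the lower bracket is flagged as an
    out-of-range (boundary) result rather than silently returned.
    """
    if lesion_area_mm2 <= 0:
        raise ValueError("lesion area must be > 0")
    if lesion_area_mm2 > plane.extent_area:
        raise ValueError("lesion area exceeds the field plane extent")
    lo, hi = 1.0, float(plane.values.max())
    a_lo = superlevel_area(plane, lo)
    if lesion_area_mm2 > a_lo:
        return EFTEstimate(lo, "area_match", residual=abs(a_lo - lesion_area_mm2) / lesion_area_mm2,
                           out_of_range=True,
                           diagnostics={"note": "lesion larger than area at minimum level"})
    if superlevel_area(plane, hi) >= lesion_area_mm2:
        return EFTEstimate(hi, "area_match", residual=0.0, out_of_range=True,
                           diagnostics={"note": "lesion smaller than area at plane maximum"})
    mid, mismatch = lo, np.inf
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        a = superlevel_area(plane, mid)
        mismatch = abs(a - lesion_area_mm2) / lesion_area_mm2
        if mismatch <= rel_tol and a > 0:
            break
        if a > lesion_area_mm2:
            lo = mid
        else:
            hi = mid
    return EFTEstimate(float(mid), "area_match", residual=float(mismatch),
                       diagnostics={"iterations": _ + 1, "area_mm2": lesion_area_mm2})


def eft_by_boundary_quantile(boundary_mm: np.ndarray, plane: FieldPlane,
                             quantile: float = 0.5) -> EFTEstimate:
    """Quantile of |E| sampled along a registered lesion boundary.

    ``boundary_mm`` is an (n, 2) polyline in the plane's (u, v)
    coordinates.  Quantile 0.5 (median) is the robust default; quantile
    0 reads off the literal minimum field on the edge.
    """
    if not (0.0 <= quantile <= 1.0):
        raise ValueError("quantile must be in [0, 1]")
    b = np.asarray(boundary_mm, float)
    interp = RegularGridInterpolator((plane.u, plane.v), plane.values,
                                     bounds_error=False, fill_value=np.nan)
    samples = interp(b)
    bad = np.nonzero(np.isnan(samples))[0]
    if bad.size:
        raise PlaneRangeError(
            f"{bad.size} boundary vertices outside the field domain "
            f"(first offenders: {b[bad[:5]].tolist()})"
        )
    q = float(np.quantile(samples, quantile))
    iqr = float(np.quantile(samples, 0.75) - np.quantile(samples, 0.25))
    return EFTEstimate(q, "boundary_quantile", quantile=quantile, residual=iqr,
                       diagnostics={"n_vertices": len(b),
                                    "min": float(samples.min()),
                                    "max": float(samples.max())})


def eft_batch_report(estimates: list[EFTEstimate],
                     allow_mixed_conditions: bool = False) -> pd.DataFrame:
    """Per-condition, per-method mean +- SEM summary table.

    A single estimate yields SEM = NaN (flagged undefined).  Estimates
    from different conditions must be explicitly allowed to mix.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    conditions = {e.condition for e in estimates}
    if len(conditions) > 1 and not allow_mixed_conditions:
        raise ValueError(
            f"estimates mix conditions {sorted(conditions)}; group explicitly "
            "or pass allow_mixed_conditions=True"
        )
    df = pd.DataFrame(
        {"condition": e.condition, "method": e.method,
         "eft_V_per_cm": e.threshold_v_per_cm}
        for e in estimates
    )
    out = (
        df.groupby(["condition", "method"])["eft_V_per_cm"]
        .agg(n="count", mean="mean", sem=lambda s: s.sem(ddof=1))
        .reset_index()
    )
    out["sem_defined"] = out["n"] > 1
    return out
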