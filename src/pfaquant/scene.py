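"""Physical scene description and rasterization.

The scene is the bench setup used for pulsed-field-ablation testing on
potato (Solanum tuberosum) slices: a glass dish filled with Tyrode
buffer, a tuber slab centred in the bath with its top surface a few mm
below the liquid surface, and a pair of parallel stainless-steel needle
electrodes whose tips touch the slab top surface.

Coordinate convention (right-handed): origin at the midpoint between the
two electrode axes on the slab top surface, x along the inter-electrode
axis, z increasing *downward* into the tissue.  All lengths in mm,
conductivities in S/m, exported fields in V/cm.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .errors import SceneValidationError, ResolutionError

REGION_BATH = 0
REGION_SLAB = 1
REGION_ELECTRODE_A = 2
REGION_ELECTRODE_B = 3

REGION_NAMES = {
    REGION_BATH: "bath",
    REGION_SLAB: "slab",
    REGION_ELECTRODE_A: "electrode_a",
    REGION_ELECTRODE_B: "electrode_b",
}


@dataclass(frozen=True)
class Material:
    """Linear isotropic material: conductivity in S/m, relative permittivity.

    The permittivity is parsed and stored for completeness but has no
    effect on the stationary (DC) conduction solve.
    """

    name: str
    conductivity: float
    relative_permittivity: float = 1.0

    def __post_init__(self):
        if not (math.isfinite(self.conductivity) and self.conductivity > 0):
            raise SceneValidationError(
                f"materials.{self.name}.conductivity",
                f"must be finite and > 0, got {self.conductivity!r}",
            )
        if self.relative_permittivity < 1:
            raise SceneValidationError(
                f"materials.{self.name}.relative_permittivity",
                f"must be >= 1, got {self.relative_permittivity!r}",
            )


@dataclass(frozen=True)
class SceneGeometry:
    """Dish, slab and electrode dimensions in mm."""

    dish_inner_diameter: float = 96.0
    dish_height: float = 30.0
    dish_wall_thickness: float = 2.0
    slab_length: float = 40.0
    slab_width: float = 40.0
    slab_height: float = 20.0
    slab_top_offset: float = 4.0  # depth of slab top below bath surface
    electrode_diameter: float = 0.63
    electrode_length: float = 8.0
    electrode_gap: float = 1.37  # inner boundary-to-boundary distance
    electrode_tip_contact: bool = True

    def __post_init__(self):
        for name in (
            "dish_inner_diameter", "dish_height", "dish_wall_thickness",
            "slab_length", "slab_width", "slab_height", "slab_top_offset",
            "electrode_diameter", "electrode_length", "electrode_gap",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise SceneValidationError(f"geometry.{name}", f"must be > 0, got {v!r}")
        if self.electrode_gap + self.electrode_diameter >= self.slab_length:
            raise SceneValidationError(
                "geometry.electrode_gap",
                "electrode pair does not fit on the slab "
                f"(gap {self.electrode_gap} + diameter {self.electrode_diameter} "
                f">= slab_length {self.slab_length})",
            )
        half_diag = math.hypot(self.slab_length, self.slab_width) / 2.0
        if half_diag > self.dish_inner_diameter / 2.0:
            raise SceneValidationError(
                "geometry.slab_length", "slab does not fit inside the dish footprint"
            )

    @property
    def electrode_center_distance(self) -> float:
        """Axis-to-axis distance = gap + diameter (mm)."""
        return self.electrode_gap + self.electrode_diameter


@dataclass(frozen=True)
class PulseRecipe:
    """Pulse-train metadata (no waveform simulation is performed).

    Defaults are the bench operating point: trains of 100 biphasic
    symmetrical rectangular pulses, 10 us per phase, 10 Hz repetition,
    500 ns interphase delay.
    """

    amplitude: float = 300.0        # V
    phase_duration_us: float = 10.0
    frequency_hz: float = 10.0
    pulse_count: int = 100
    interphase_delay_ns: float = 500.0
    polarity: str = "biphasic"

    def __post_init__(self):
        if self.amplitude <= 0:
            raise SceneValidationError("recipe.amplitude", f"must be > 0, got {self.amplitude!r}")
        if self.pulse_count < 1:
            raise SceneValidationError("recipe.pulse_count", f"must be >= 1, got {self.pulse_count!r}")
        if self.polarity not in ("biphasic", "monophasic"):
            raise SceneValidationError("recipe.polarity", f"unknown polarity {self.polarity!r}")

    @property
    def phases_per_pulse(self) -> int:
        return 2 if self.polarity == "biphasic" else 1

    @property
    def total_on_time_us(self) -> float:
        return self.pulse_count * self.phases_per_pulse * self.phase_duration_us


@dataclass(frozen=True)
class SolverOptions:
    """Discretization and domain-truncation options.

    The computational domain is a box centred on the electrode pair:
    x in [-half_extent_x, +half_extent_x], y likewise, z from the bath
    surface (-slab_top_offset) down to ``depth_mm`` into the tissue.
    Truncated faces carry the insulation (zero normal current) condition.
    """

    spacing_mm: float = 0.1
    tolerance: float = 1e-8
    half_extent_x_mm: float = 8.0
    half_extent_y_mm: float = 6.0
    depth_mm: float = 10.0
    electrode_model: str = "equipotential"  # or "volumetric"

    def __post_init__(self):
        if self.spacing_mm <= 0:
            raise SceneValidationError("solver.spacing_mm", "must be > 0")
        if not (0 < self.tolerance <= 1e-4):
            raise SceneValidationError("solver.tolerance", "must be in (0, 1e-4]")
        if self.electrode_model not in ("equipotential", "volumetric"):
            raise SceneValidationError("solver.electrode_model", f"unknown mode {self.electrode_model!r}")


def default_materials() -> dict[str, Material]:
    """Bench materials: Tyrode bath 1.8 S/m, tuber 0.04 S/m.

    The electrode material stores the printed 1.74 mS/m for provenance;
    the default equipotential electrode model never reads it.
    """
    return {
        "bath": Material("bath", 1.8, 1.0),
        "slab": Material("slab", 0.04, 1.0),
        "electrode_a": Material("electrode_a", 1.74e-3, 1.0),
        "electrode_b": Material("electrode_b", 1.74e-3, 1.0),
    }


@dataclass(frozen=True)
class SceneConfig:
    geometry: SceneGeometry = field(default_factory=SceneGeometry)
    materials: dict[str, Material] = field(default_factory=default_materials)
    recipe: PulseRecipe = field(default_factory=PulseRecipe)
    solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self):
        for region in ("bath", "slab", "electrode_a", "electrode_b"):
            if region not in self.materials:
                raise SceneValidationError(f"materials.{region}", "region has no material")

    def to_dict(self) -> dict:
        d = {
            "geometry": asdict(self.geometry),
            "recipe": asdict(self.recipe),
            "solver": asdict(self.solver),
            "materials": {
                k: {"conductivity": m.conductivity,
                    "relative_permittivity": m.relative_permittivity}
                for k, m in self.materials.items()
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        defaults = cls()
        geometry = replace(defaults.geometry, **d.get("geometry", {}))
        recipe = replace(defaults.recipe, **d.get("recipe", {}))
        solver = replace(defaults.solver, **d.get("solver", {}))
        materials = dict(defaults.materials)
        for name, spec in d.get("materials", {}).items():
            materials[name] = Material(name=name, **spec)
        return cls(geometry=geometry, materials=materials, recipe=recipe, solver=solver)


def paper_defaults() -> SceneConfig:
    """The built-in default bench scene."""
    return SceneConfig()


def load_scene_config(path: str | Path) -> SceneConfig:
    """Load a scene config from TOML or JSON; missing fields take defaults.

    An empty file yields the built-in default scene.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text) if text.strip() else {}
    else:
        raw = tomllib.loads(text)
    try:
        return SceneConfig.from_dict(raw)
    except TypeError as exc:  # unknown field name in the file
        raise SceneValidationError("schema", str(exc)) from exc


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return json.dumps(v)
    return repr(v)


def _toml_dumps(d: dict, prefix: str = "") -> str:
    scalars, tables = [], []
    for k, v in d.items():
        (tables if isinstance(v, dict) else scalars).append((k, v))
    out = []
    if scalars and prefix:
        out.append(f"[{prefix}]")
    out.extend(f"{k} = {_toml_value(v)}" for k, v in scalars)
    if scalars:
        out.append("")
    for k, v in tables:
        out.append(_toml_dumps(v, f"{prefix}.{k}" if prefix else k))
    return "\n".join(out)


def save_scene_config(config: SceneConfig, path: str | Path) -> None:
    """Serialize to TOML (default) or JSON by file extension; lossless round-trip."""
    path = Path(path)
    d = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(_toml_dumps(d))


@dataclass
class MaterialMap:
    """Region labels and conductivity on a uniform cell-centred grid.

    Arrays are indexed ``[ix, iy, iz]``; cell centres sit at
    ``origin + (index + 0.5) * spacing``.  ``dirichlet_a``/``dirichlet_b``
    flag the cells held at the applied voltage and at ground.
    """

    labels: np.ndarray        # uint8 region codes
    sigma: np.ndarray         # S/m per cell
    dirichlet_a: np.ndarray   # bool, cells at +V
    dirichlet_b: np.ndarray   # bool, cells at 0 V
    spacing: float            # mm, isotropic
    origin: tuple[float, float, float]  # mm, lower corner of cell (0,0,0)
    config: SceneConfig
    # electrode surface geometry for the solver's cut-cell boundary
    # correction (equipotential mode only): vertical cylinder axes (x, y),
    # radius, and the z of the tip surface
    electrode_axes: tuple[tuple[float, float], tuple[float, float]] | None = None
    electrode_radius: float | None = None
    electrode_tip_z: float | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Cell-centre coordinates (mm) along axis 0/1/2 = x/y/z."""
        n = self.labels.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing


def rasterize_materials(config: SceneConfig, spacing_mm: float | None = None) -> MaterialMap:
    """Label every grid cell with its region and emit the conductivity field.

    The electrode needles are rasterized as vertical cylinders whose tips
    touch the slab top surface (z = 0) and extend upward through the bath.
    In the default equipotential mode all electrode cells are flagged as
    Dirichlet cells; in volumetric mode only the topmost electrode layer
    (the feed point at the domain top) is flagged and the needle body is a
    conductor with its material's sigma.
    """
    g = config.geometry
    opt = config.solver
    h = float(spacing_mm if spacing_mm is not None else opt.spacing_mm)
    if h <= 0:
        raise SceneValidationError("spacing", "grid spacing must be > 0")
    if g.electrode_diameter / h < 3:
        raise ResolutionError(
            f"spacing {h} mm resolves the {g.electrode_diameter} mm electrode "
            f"with only {g.electrode_diameter / h:.1f} cells (need >= 3)"
        )

    z_top = -g.slab_top_offset  # bath surface
    z_bot = min(opt.depth_mm, g.slab_height)
    nx = int(round(2 * opt.half_extent_x_mm / h))
    ny = int(round(2 * opt.half_extent_y_mm / h))
    nz = int(round((z_bot - z_top) / h))
    origin = (-nx * h / 2.0, -ny * h / 2.0, z_top)

    x = origin[0] + (np.arange(nx) + 0.5) * h
    y = origin[1] + (np.arange(ny) + 0.5) * h
    z = origin[2] + (np.arange(nz) + 0.5) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    labels = np.full((nx, ny, nz), REGION_BATH, dtype=np.uint8)
    in_slab = (
        (np.abs(X) <= g.slab_length / 2.0)
        & (np.abs(Y) <= g.slab_width / 2.0)
        & (Z >= 0.0)
        & (Z <= g.slab_height)
    )
    labels[in_slab] = REGION_SLAB

    r = g.electrode_diameter / 2.0
    s = g.electrode_center_distance / 2.0
    elec_z = (Z < 0.0) & (Z >= -min(g.electrode_length, g.slab_top_offset))
    in_a = ((X + s) ** 2 + Y**2 <= r**2) & elec_z
    in_b = ((X - s) ** 2 + Y**2 <= r**2) & elec_z
    if not in_a.any() or not in_b.any():
        raise ResolutionError("electrode cylinders rasterized to zero cells")
    labels[in_a] = REGION_ELECTRODE_A
    labels[in_b] = REGION_ELECTRODE_B

    sigma = np.empty(labels.shape, dtype=np.float64)
    lut = {
        REGION_BATH: config.materials["bath"].conductivity,
        REGION_SLAB: config.materials["slab"].conductivity,
        REGION_ELECTRODE_A: config.materials["electrode_a"].conductivity,
        REGION_ELECTRODE_B: config.materials["electrode_b"].conductivity,
    }
    for code, s_val in lut.items():
        sigma[labels == code] = s_val

    if opt.electrode_model == "equipotential":
        dir_a, dir_b = in_a, in_b
    else:
        top_layer = np.zeros_like(in_a)
        top_layer[:, :, 0] = True
        dir_a, dir_b = in_a & top_layer, in_b & top_layer
        if not dir_a.any() or not dir_b.any():
            # needle does not reach the domain top; feed at its topmost layer
            ka = int(np.nonzero(in_a.any(axis=(0, 1)))[0][0])
            kb = int(np.nonzero(in_b.any(axis=(0, 1)))[0][0])
            dir_a = in_a & (np.arange(nz)[None, None, :] == ka)
            dir_b = in_b & (np.arange(nz)[None, None, :] == kb)

    equipotential = opt.electrode_model == "equipotential"
    return MaterialMap(
        labels=labels, sigma=sigma, dirichlet_a=dir_a, dirichlet_b=dir_b,
        spacing=h, origin=origin, config=config,
        electrode_axes=((-s, 0.0), (s, 0.0)) if equipotential else None,
        electrode_radius=r if equipotential else None,
        electrode_tip_z=0.0 if equipotential else None,
    )
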