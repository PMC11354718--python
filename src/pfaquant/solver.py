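"""Stationary conduction solver for the heterogeneous bench scene.

Solves div(sigma grad phi) = 0 with a seven-point finite-volume
discretization on the uniform cell-centred grid produced by
:func:`pfaquant.scene.rasterize_materials`.  Face conductivities are
harmonic means of the two adjacent cell conductivities — the standard
choice for flux continuity across discontinuous sigma.  Electrode cells
are Dirichlet cells (one set at the applied voltage, one at ground);
every outer domain face carries the insulation (zero normal current)
condition.  The electric-field magnitude is obtained from central
differences of phi (one-sided second-order at domain faces via
``np.gradient``) and reported in V/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, ConvergenceError, PlaneRangeError
from .scene import MaterialMap

V_PER_MM_TO_V_PER_CM = 10.0


@dataclass
class FieldSolution:
    """Gridded potential (V) and field magnitude (V/cm) with grid metadata."""

    potential: np.ndarray      # (nx, ny, nz), V
    e_magnitude: np.ndarray    # (nx, ny, nz), V/cm
    spacing: float             # mm
    origin: tuple[float, float, float]
    applied_voltage: float
    residual: float            # relative residual of the discrete system
    iterations: int
    material_map: MaterialMap | None = None

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.potential.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing


@dataclass
class FieldPlane:
    """A 2-D slice of |E| (V/cm) on an axis-aligned plane.

    ``values[i, j]`` is the field at ``(u[i], v[j])`` where (u, v) are the
    two in-plane axes in mm.
    """

    values: np.ndarray
    u: np.ndarray
    v: np.ndarray
    axes: tuple[str, str]
    plane_axis: str
    offset: float

    @property
    def du(self) -> float:
        return float(self.u[1] - self.u[0])

    @property
    def dv(self) -> float:
        return float(self.v[1] - self.v[0])

    @property
    def extent_area(self) -> float:
        """Area (mm^2) spanned by the plane's node lattice."""
        return (len(self.u) - 1) * self.du * (len(self.v) - 1) * self.dv


@dataclass
class ConservationReport:
    current_source: float   # A, total current leaving the driven electrode
    current_sink: float     # A, total current leaving the grounded electrode
    relative_mismatch: float

    def __str__(self):
        return (
            f"I_source={self.current_source:.6g} A, I_sink={self.current_sink:.6g} A, "
            f"mismatch={self.relative_mismatch:.3%}"
        )


def _lohi(axis: int):
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis] = slice(None, -1)
    hi[axis] = slice(1, None)
    return tuple(lo), tuple(hi)


def _face_conductances(mmap: MaterialMap) -> list[np.ndarray]:
    """Per-axis face conductances (units sigma*mm; multiply by 1e-3 for S).

    Interior faces use the harmonic mean of the adjacent cell
    conductivities.  Faces between an active cell and an equipotential
    electrode cell get a cut-cell correction: the Dirichlet value lives
    on the true cylinder surface, so the conductance is sigma_active *
    h / theta with theta the fractional centre-to-surface distance.
    Without this correction the staircase rasterization shifts the
    effective electrode radius by about half a cell.
    """
    sigma = mmap.sigma
    active = ~(mmap.dirichlet_a | mmap.dirichlet_b)
    h = mmap.spacing
    out = []
    coords = [mmap.axis_coords(a) for a in range(3)]
    for axis in range(3):
        lo, hi = _lohi(axis)
        s1, s2 = sigma[lo], sigma[hi]
        g = (2.0 * s1 * s2 / (s1 + s2)) * h
        if mmap.electrode_radius is not None:
            r = mmap.electrode_radius
            for dmask, (cx, cy) in zip((mmap.dirichlet_a, mmap.dirichlet_b),
                                       mmap.electrode_axes):
                for side in (0, 1):  # dirichlet neighbour on hi / lo side
                    if side == 0:
                        faces = active[lo] & dmask[hi]
                        s_act = s1
                        dx = 1.0
                    else:
                        faces = dmask[lo] & active[hi]
                        s_act = s2
                        dx = -1.0
                    if not faces.any():
                        continue
                    ii = np.nonzero(faces)
                    # index of the active cell for each flagged face
                    act_idx = list(ii)
                    if side == 1:
                        act_idx[axis] = act_idx[axis] + 1
                    x0 = coords[0][act_idx[0]]
                    y0 = coords[1][act_idx[1]]
                    z0 = coords[2][act_idx[2]]
                    if axis == 2:
                        # tip face: surface at electrode_tip_z
                        tip = mmap.electrode_tip_z
                        t = np.abs(z0 - tip) if tip is not None else np.full_like(z0, h)
                    else:
                        if axis == 0:
                            q, w = x0 - cx, y0 - cy
                        else:
                            q, w = y0 - cy, x0 - cx
                        rad = np.sqrt(np.clip(r**2 - w**2, 0.0, None))
                        t = -dx * q - rad
                    theta = np.clip(t / h, 0.1, 1.0)
                    g[ii] = s_act[ii] * h / theta
        out.append(g)
    return out


def _assemble(mmap: MaterialMap, applied_voltage: float):
    """Build the sparse SPD finite-volume system over non-Dirichlet cells."""
    sigma = mmap.sigma
    active = ~(mmap.dirichlet_a | mmap.dirichlet_b)
    n = int(active.sum())
    if not mmap.dirichlet_a.any() or not mmap.dirichlet_b.any():
        raise ConfigurationError("both a driven and a ground electrode are required")

    idx = np.full(sigma.shape, -1, dtype=np.int64)
    idx[active] = np.arange(n)
    phi_d = np.zeros(sigma.shape)
    phi_d[mmap.dirichlet_a] = applied_voltage

    diag = np.zeros(n)
    rhs = np.zeros(n)
    rows_all, cols_all, vals_all = [], [], []
    conductances = _face_conductances(mmap)
    for axis in range(3):
        lo, hi = _lohi(axis)
        g = conductances[axis]
        a1, a2 = active[lo], active[hi]
        i1, i2 = idx[lo], idx[hi]

        both = a1 & a2
        gi = g[both]
        rows_all.append(i1[both]); cols_all.append(i2[both]); vals_all.append(-gi)
        rows_all.append(i2[both]); cols_all.append(i1[both]); vals_all.append(-gi)
        np.add.at(diag, i1[both], gi)
        np.add.at(diag, i2[both], gi)

        b1 = a1 & ~a2  # active cell with Dirichlet neighbour on the + side
        np.add.at(diag, i1[b1], g[b1])
        np.add.at(rhs, i1[b1], g[b1] * phi_d[hi][b1])
        b2 = ~a1 & a2
        np.add.at(diag, i2[b2], g[b2])
        np.add.at(rhs, i2[b2], g[b2] * phi_d[lo][b2])

    A = sp.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n, n),
    ).tocsr()
    A += sp.diags(diag)
    return A, rhs, idx, active, phi_d, diag


def solve_potential(
    mmap: MaterialMap,
    applied_voltage: float,
    tolerance: float | None = None,
    maxiter: int = 40000,
) -> FieldSolution:
    """Solve the conduction problem; returns potential and |E| in V/cm.

    Jacobi-preconditioned conjugate gradients on the symmetric
    positive-definite finite-volume system; relative residual must fall
    below ``tolerance`` (default: the scene's solver option, 1e-8).
    """
    tol = float(tolerance if tolerance is not None else mmap.config.solver.tolerance)
    if not (0 < tol <= 1e-4):
        raise ConfigurationError(f"tolerance must be in (0, 1e-4], got {tol}")

    A, rhs, idx, active, phi_d, diag = _assemble(mmap, applied_voltage)
    bnorm = np.linalg.norm(rhs)
    if bnorm == 0.0:  # null excitation
        phi = phi_d.copy()
        e = _e_magnitude(phi, mmap.spacing)
        return FieldSolution(phi, e, mmap.spacing, mmap.origin, applied_voltage,
                             0.0, 0, mmap)

    M = sp.diags(1.0 / diag)
    history: list[float] = []

    def cb(xk):
        history.append(float(np.linalg.norm(rhs - A @ xk) / bnorm))

    x, info = spla.cg(A, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M)
    res = float(np.linalg.norm(rhs - A @ x) / bnorm)
    if info != 0 or res > tol * 10:
        # rerun with a history-collecting callback for diagnostics
        x, info = spla.cg(A, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M, callback=cb)
        res = float(np.linalg.norm(rhs - A @ x) / bnorm)
        if info != 0:
            raise ConvergenceError(
                f"CG did not converge within {maxiter} iterations (residual {res:.3e})",
                residual_history=history,
            )

    phi = phi_d.copy()
    phi[active] = x
    e = _e_magnitude(phi, mmap.spacing)
    return FieldSolution(phi, e, mmap.spacing, mmap.origin, applied_voltage,
                         res, len(history) or -1, mmap)


def _e_magnitude(phi: np.ndarray, spacing_mm: float) -> np.ndarray:
    gx, gy, gz = np.gradient(phi, spacing_mm)
    return np.sqrt(gx**2 + gy**2 + gz**2) * V_PER_MM_TO_V_PER_CM


def check_current_conservation(solution: FieldSolution, mmap: MaterialMap) -> ConservationReport:
    """Total current leaving each electrode and their relative mismatch.

    Discrete flux: sum over faces between an electrode cell and an active
    neighbour of G * (phi_neighbour - phi_electrode), with G in siemens
    (sigma in S/m, lengths converted from mm).
    """
    currents = []
    active = ~(mmap.dirichlet_a | mmap.dirichlet_b)
    phi = solution.potential
    conductances = _face_conductances(mmap)
    for dmask in (mmap.dirichlet_a, mmap.dirichlet_b):
        total = 0.0
        for axis in range(3):
            lo, hi = _lohi(axis)
            g = conductances[axis] * 1e-3  # sigma*mm -> siemens
            f1 = dmask[lo] & active[hi]
            total += float(np.sum(g[f1] * (phi[hi][f1] - phi[lo][f1])))
            f2 = dmask[hi] & active[lo]
            total += float(np.sum(g[f2] * (phi[lo][f2] - phi[hi][f2])))
        # current *leaving* the electrode = -inflow
        currents.append(-total)
    i_src, i_snk = currents
    denom = max(abs(i_src), abs(i_snk))
    mismatch = abs(i_src + i_snk) / denom if denom > 0 else 0.0
    return ConservationReport(i_src, i_snk, mismatch)


_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def slice_field(solution: FieldSolution, plane_axis: str, offset_mm: float) -> FieldPlane:
    """Interpolate |E| onto an axis-aligned plane at native resolution."""
    if plane_axis not in _AXIS_INDEX:
        raise ValueError(f"plane_axis must be one of x/y/z, got {plane_axis!r}")
    k = _AXIS_INDEX[plane_axis]
    coords = [solution.axis_coords(a) for a in range(3)]
    if not (coords[k][0] <= offset_mm <= coords[k][-1]):
        raise PlaneRangeError(
            f"plane {plane_axis}={offset_mm} mm outside solved range "
            f"[{coords[k][0]:.3f}, {coords[k][-1]:.3f}]"
        )
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(tuple(coords), solution.e_magnitude)
    rem = [a for a in range(3) if a != k]
    u, v = coords[rem[0]], coords[rem[1]]
    U, V = np.meshgrid(u, v, indexing="ij")
    pts = np.empty(U.shape + (3,))
    pts[..., k] = offset_mm
    pts[..., rem[0]] = U
    pts[..., rem[1]] = V
    values = interp(pts)
    names = ["x", "y", "z"]
    return FieldPlane(values=values, u=u, v=v,
                      axes=(names[rem[0]], names[rem[1]]),
                      plane_axis=plane_axis, offset=offset_mm)


def slice_potential(solution: FieldSolution, plane_axis: str, offset_mm: float) -> FieldPlane:
    """Same as :func:`slice_field` but for the potential (V)."""
    e_save = solution.e_magnitude
    try:
        solution.e_magnitude = solution.potential
        plane = slice_field(solution, plane_axis, offset_mm)
    finally:
        solution.e_magnitude = e_save
    return plane
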