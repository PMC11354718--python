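"""Shared fixtures: solved scenes at two resolutions and helper builders.

The default-scene solve at 0.1 mm spacing is expensive (~2 min) and is
shared session-wide by the physics and end-to-end recovery tests; most
unit tests use the cheap 0.2 mm solve or purpose-built tiny grids.
"""

from __future__ import annotations

import numpy as np
import pytest

import pfaquant as pq
from pfaquant.scene import MaterialMap


@pytest.fixture(scope="session")
def paper_config():
    return pq.paper_defaults()


@pytest.fixture(scope="session")
def coarse_solution(paper_config):
    """Default scene at 300 V, 0.2 mm spacing (fast)."""
    mmap = pq.rasterize_materials(paper_config, 0.2)
    return pq.solve_potential(mmap, 300.0)


@pytest.fixture(scope="session")
def coarse_map(paper_config):
    return pq.rasterize_materials(paper_config, 0.2)


@pytest.fixture(scope="session")
def fine_solution(paper_config):
    """Default scene at 300 V, 0.1 mm spacing (the reference operating point)."""
    mmap = pq.rasterize_materials(paper_config, 0.1)
    return pq.solve_potential(mmap, 300.0)


def build_twowire_map(spacing: float, half_extent: float = 6.0,
                      sigma: float = 1.0, nz: int = 3,
                      diameter: float = 0.63, gap: float = 1.37) -> MaterialMap:
    """Quasi-2-D homogeneous scene with two parallel cylinder electrodes.

    Three uniform z-layers with insulation above and below reproduce the
    plane (infinite-wire) problem that has a closed-form bi-cylindrical
    solution.
    """
    cfg = pq.paper_defaults()
    n = int(round(2 * half_extent / spacing))
    origin = (-half_extent, -half_extent, 0.0)
    x = origin[0] + (np.arange(n) + 0.5) * spacing
    X, Y = np.meshgrid(x, x, indexing="ij")
    r = diameter / 2.0
    s = (gap + diameter) / 2.0
    in_a2d = (X + s) ** 2 + Y**2 <= r**2
    in_b2d = (X - s) ** 2 + Y**2 <= r**2
    shape = (n, n, nz)
    labels = np.zeros(shape, dtype=np.uint8)
    sig = np.full(shape, sigma)
    dir_a = np.repeat(in_a2d[:, :, None], nz, axis=2)
    dir_b = np.repeat(in_b2d[:, :, None], nz, axis=2)
    labels[dir_a] = 2
    labels[dir_b] = 3
    return MaterialMap(labels=labels, sigma=sig, dirichlet_a=dir_a,
                       dirichlet_b=dir_b, spacing=spacing, origin=origin,
                       config=cfg, electrode_axes=((-s, 0.0), (s, 0.0)),
                       electrode_radius=r)


def twowire_midpoint_field(voltage: float, diameter: float = 0.63,
                           gap: float = 1.37) -> float:
    """Closed-form |E| (V/cm) at the midpoint between two parallel wires.

    Bi-cylindrical solution: with centre distance d and radius a, the
    image line charges sit at +-b, b = sqrt((d/2)^2 - a^2), and
    |E|(0) = V / (arccosh(d / 2a) * b).
    """
    a = diameter / 2.0
    d = gap + diameter
    b = np.sqrt((d / 2.0) ** 2 - a**2)
    e_v_per_mm = voltage / (np.arccosh(d / (2 * a)) * b)
    return e_v_per_mm * 10.0


@pytest.fixture
def radial_plane():
    """Analytic plane |E| = C / r with C = 100 V*mm/cm over +-10 mm."""
    u = np.linspace(-10, 10, 401)
    U, V = np.meshgrid(u, u, indexing="ij")
    R = np.sqrt(U**2 + V**2)
    R[R < 1e-9] = 1e-9
    return pq.FieldPlane(values=100.0 / R, u=u, v=u, axes=("x", "y"),
                         plane_axis="z", offset=0.0)
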