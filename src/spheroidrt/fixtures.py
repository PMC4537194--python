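"""Deterministic cell-arrangement fixtures.

Ball fixtures are FCC-like packings of cells used to (a) measure the
dense-packing density ``d_max`` that normalises the density-dependent
diffusivity (the "compressed cell mass" calibration), and (b) exercise the
transport solver and observables without running growth.
"""

from __future__ import annotations

import numpy as np

from .cells import Cell, CellState
from .transport import Grid, raw_density

#: centre-to-centre spacing over cell radius: touching for loose packing,
#: strongly compressed for the dense (d_max calibration) packing
SPACING_FACTOR = {"loose": 2.0, "dense": 1.6}


def fcc_positions(radius_um: float, nn_spacing_um: float,
                  centre: np.ndarray) -> np.ndarray:
    """FCC lattice points within a ball of ``radius_um`` around ``centre``."""
    if radius_um <= 0:
        return np.empty((0, 3))
    a = nn_spacing_um * np.sqrt(2.0)          # cubic lattice constant
    k = int(np.ceil(radius_um / a)) + 1
    base = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
    rng = np.arange(-k, k + 1)
    cube = np.array(np.meshgrid(rng, rng, rng)).reshape(3, -1).T
    pts = (cube[:, None, :] + base[None, :, :]).reshape(-1, 3) * a
    pts = pts[np.linalg.norm(pts, axis=1) <= radius_um]
    return pts + np.asarray(centre, dtype=float)


def make_ball_fixture(radius_um: float, packing: str = "loose",
                      cell_radius_um: float = 10.0,
                      centre: np.ndarray | None = None,
                      grid: Grid | None = None,
                      state: CellState = CellState.G1,
                      id_start: int = 0) -> list[Cell]:
    """Deterministic ball of cells of one state at FCC-like packing."""
    if packing not in SPACING_FACTOR:
        raise ValueError(f"packing must be one of {sorted(SPACING_FACTOR)}")
    if centre is None:
        g = grid or Grid()
        centre = np.full(3, g.size_um / 2.0)
    spacing = SPACING_FACTOR[packing] * cell_radius_um
    pts = fcc_positions(radius_um, spacing, np.asarray(centre, dtype=float))
    return [Cell(id=id_start + k, position=p.copy(), radius=cell_radius_um,
                 state=state) for k, p in enumerate(pts)]


def make_two_shell_fixture(n_inner: int, n_outer: int, pO2_inner: float,
                           pO2_outer: float, grid: Grid | None = None) -> list[Cell]:
    """Inner/outer shells of live cells with prescribed cached pO2 values."""
    g = grid or Grid()
    centre = np.full(3, g.size_um / 2.0)
    cells = []
    for k in range(n_inner):
        theta = 2 * np.pi * k / max(n_inner, 1)
        pos = centre + 50.0 * np.array([np.cos(theta), np.sin(theta), 0.0])
        cells.append(Cell(id=k, position=pos, radius=8.0, local_pO2=pO2_inner))
    for k in range(n_outer):
        theta = 2 * np.pi * k / max(n_outer, 1)
        pos = centre + 150.0 * np.array([np.cos(theta), 0.0, np.sin(theta)])
        cells.append(Cell(id=n_inner + k, position=pos, radius=8.0,
                          local_pO2=pO2_outer))
    return cells


def measure_dmax(grid: Grid, cell_radius_um: float = 10.0,
                 ball_radius_um: float | None = None) -> float:
    """Dense-packing density (full-grown cells per node volume).

    Deposits a compressed ball of full-grown cells and takes the median
    nodal occupancy well inside the ball, away from the surface layer.
    """
    if ball_radius_um is None:
        ball_radius_um = min(8 * grid.h, 0.4 * grid.size_um / 2)
    cells = make_ball_fixture(ball_radius_um, packing="dense",
                              cell_radius_um=cell_radius_um, grid=grid)
    rho = raw_density(cells, grid, r_full_um=cell_radius_um)
    centre = np.full(3, grid.size_um / 2.0)
    interior = grid.radius_field(centre) <= 0.5 * ball_radius_um
    return float(np.median(rho[interior]))
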