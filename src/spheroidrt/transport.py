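"""Nutrient transport on a regular nodal grid over the cubic domain.

Oxygen and glucose obey a reaction-diffusion equation with zero-order
sinks deposited by cells,

    dC/dt = div( D(x,t) grad C ) - Q(x,t),

where the local diffusion coefficient interpolates linearly between the
water value (cell-free space) and the tissue value (densely packed tissue)
as a function of the normalised cell density.  Nodes outside the tumour
that connect to the domain faces through cell-free space are held at the
arterial boundary concentration (an adaptive Dirichlet "blood" boundary);
cell-free pockets enclosed by tissue (e.g. a dissolved necrotic core) are
ordinary free nodes.  By default the field is re-solved to pseudo-steady
state on the biology update cadence; a Crank-Nicolson transient stepper is
kept for validation.

Zero-order sinks are limited node-wise so concentrations never go
negative: fully depleted nodes are pinned to C = 0 (an active-set obstacle
solve) and their realised consumption equals the diffusive inflow, which
is reported alongside the field.

Units: lengths um, concentrations mM, time s, diffusivities um^2/s, sinks
mM/s.  A node volume is h^3 um^3; a cell demand of ``r`` amol/s deposited
wholly on one node contributes r / h^3 mM/s (1 amol/um^3 = 1 mM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import bicgstab

from .cells import Cell, CellState, CellParameters, consumption_rate
from .config import SimulationConfig


class TransportError(RuntimeError):
    pass


@dataclass(frozen=True)
class Grid:
    """Cubic nodal grid: ``n`` nodes per dimension spanning [0, size]."""
    n: int = 71
    size_um: float = 1000.0

    @property
    def h(self) -> float:
        return self.size_um / (self.n - 1)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n, self.n, self.n)

    @property
    def node_volume(self) -> float:
        return self.h ** 3

    def axis_coords(self) -> np.ndarray:
        return np.linspace(0.0, self.size_um, self.n)

    def radius_field(self, centre: np.ndarray) -> np.ndarray:
        x = self.axis_coords()
        dx = x[:, None, None] - centre[0]
        dy = x[None, :, None] - centre[1]
        dz = x[None, None, :] - centre[2]
        return np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)


@dataclass(frozen=True)
class SpeciesTransport:
    name: str
    d_h2o: float          # um^2/s, diffusivity in cell-free medium
    d_tis: float          # um^2/s, diffusivity in dense tissue
    boundary_mM: float


@dataclass
class TransportParameters:
    oxygen: SpeciesTransport = field(default_factory=lambda: SpeciesTransport(
        "oxygen", 3300.0, 1750.0, 0.13))
    glucose: SpeciesTransport = field(default_factory=lambda: SpeciesTransport(
        "glucose", 690.0, 105.0, 5.0))
    d_max: float | None = None      # cells per node volume at dense packing
    update_interval_min: float = 10.0
    solver_tol: float = 1e-8
    solver_maxiter: int = 20000
    orientation: str = "narrative"  # diffusivity/density orientation

    @classmethod
    def from_config(cls, cfg: SimulationConfig) -> "TransportParameters":
        return cls(
            oxygen=SpeciesTransport("oxygen", cfg.d_h2o_oxygen,
                                    cfg.d_tis_oxygen, cfg.oxygen_boundary_mM),
            glucose=SpeciesTransport("glucose", cfg.d_h2o_glucose,
                                     cfg.d_tis_glucose, cfg.glucose_boundary_mM),
            update_interval_min=cfg.update_interval_min,
            solver_tol=cfg.solver_tol, solver_maxiter=cfg.solver_maxiter,
            orientation=cfg.diffusivity_orientation,
        )

    def species(self, name: str) -> SpeciesTransport:
        key = name.lower()
        if key in ("o2", "oxygen"):
            return self.oxygen
        if key in ("glucose", "glc"):
            return self.glucose
        raise ValueError(f"unknown species {name!r}")


# --------------------------------------------------------------- deposition --

def _trilinear_scatter(grid: Grid, positions: np.ndarray,
                       weights: np.ndarray) -> np.ndarray:
    """Scatter per-cell weights onto the 8 surrounding nodes."""
    out = np.zeros(grid.shape)
    if len(positions) == 0:
        return out
    frac = positions / grid.h
    if np.any(frac < 0) or np.any(frac > grid.n - 1):
        bad = int(np.flatnonzero((frac < 0).any(1) | (frac > grid.n - 1).any(1))[0])
        raise TransportError(
            f"cell at {positions[bad]} um lies outside the {grid.size_um} um cube")
    i0 = np.minimum(frac.astype(int), grid.n - 2)
    t = frac - i0
    n = grid.n
    flat = np.zeros(n ** 3)
    base = (i0[:, 0] * n + i0[:, 1]) * n + i0[:, 2]
    for dx in (0, 1):
        wx = t[:, 0] if dx else 1.0 - t[:, 0]
        for dy in (0, 1):
            wy = t[:, 1] if dy else 1.0 - t[:, 1]
            for dz in (0, 1):
                wz = t[:, 2] if dz else 1.0 - t[:, 2]
                idx = base + (dx * n + dy) * n + dz
                flat += np.bincount(idx, weights=weights * wx * wy * wz,
                                    minlength=n ** 3)
    return flat.reshape(grid.shape)


def _present(cells: list[Cell]) -> list[Cell]:
    return [c for c in cells if c.state is not CellState.DISSOLVED and c.radius > 0]


def raw_density(cells: list[Cell], grid: Grid, r_full_um: float) -> np.ndarray:
    """Cell-volume-weighted occupancy per node (full-grown-cell equivalents)."""
    live = _present(cells)
    positions = np.array([c.position for c in live], dtype=float).reshape(-1, 3)
    weights = np.array([(c.radius / r_full_um) ** 3 for c in live], dtype=float)
    return _trilinear_scatter(grid, positions, weights)


def density_field(cells: list[Cell], grid: Grid, r_full_um: float,
                  d_max: float) -> np.ndarray:
    """Normalised cell density rho/d_max, clipped to [0, 1]."""
    return np.clip(raw_density(cells, grid, r_full_um) / d_max, 0.0, 1.0)


def effective_diffusivity(density_norm: np.ndarray, species: SpeciesTransport,
                          orientation: str = "narrative") -> np.ndarray:
    """Density-dependent diffusivity, linear between water and tissue values.

    ``narrative``: D = D_H2O in cell-free space falling to D_Tis at dense
    packing (dissolving tissue becomes more permeable).  ``printed`` keeps
    the opposite endpoint assignment for exact-replication studies.
    """
    rho = np.clip(density_norm, 0.0, 1.0)
    if orientation == "narrative":
        return species.d_h2o - (species.d_h2o - species.d_tis) * rho
    if orientation == "printed":
        return species.d_tis + (species.d_h2o - species.d_tis) * rho
    raise ValueError(f"unknown orientation {orientation!r}")


def deposit_sinks(cells: list[Cell], grid: Grid, species_name: str,
                  params: CellParameters) -> np.ndarray:
    """Zero-order consumption field Q >= 0 in mM/s.

    The total deposited demand equals the sum of per-cell demands exactly:
    sum(Q) * h^3 [amol/s] == sum of cell rates.
    """
    live = _present(cells)
    positions = np.array([c.position for c in live], dtype=float).reshape(-1, 3)
    demands = np.array([consumption_rate(c, species_name, params) for c in live],
                       dtype=float)
    return _trilinear_scatter(grid, positions, demands) / grid.node_volume


def update_boundary(density_raw: np.ndarray) -> np.ndarray:
    """Adaptive blood boundary: True where the node is FIXED at the
    boundary concentration.

    Zero-density nodes 6-connected to the cube faces are blood; enclosed
    zero-density pockets stay free.  Face nodes are always blood.
    """
    empty = density_raw <= 0.0
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, _ = ndimage.label(empty, structure=structure)
    face_labels = np.unique(np.concatenate([
        labels[0].ravel(), labels[-1].ravel(),
        labels[:, 0].ravel(), labels[:, -1].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel()]))
    face_labels = face_labels[face_labels > 0]
    fixed = np.isin(labels, face_labels)
    fixed[0], fixed[-1] = True, True
    fixed[:, 0], fixed[:, -1] = True, True
    fixed[:, :, 0], fixed[:, :, -1] = True, True
    return fixed


# ------------------------------------------------------------------ operator --

def _face_arrays(D: np.ndarray, axis: int) -> np.ndarray:
    """Harmonic-mean face diffusivity between node pairs along ``axis``."""
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis] = slice(None, -1)
    hi[axis] = slice(1, None)
    d1, d2 = D[tuple(lo)], D[tuple(hi)]
    return 2.0 * d1 * d2 / (d1 + d2)


def _diffusion_matrix(D: np.ndarray, h: float) -> sparse.csr_matrix:
    """Discrete div(D grad .) operator with no-flux outer faces, 1/s units."""
    n = D.shape[0]
    size = D.size
    idx = np.arange(size).reshape(D.shape)
    rows, cols, vals = [], [], []
    diag = np.zeros(size)
    for axis in range(3):
        df = _face_arrays(D, axis) / h ** 2
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        a = idx[tuple(lo)].ravel()
        b = idx[tuple(hi)].ravel()
        w = df.ravel()
        rows.extend((a, b))
        cols.extend((b, a))
        vals.extend((w, w))
        np.add.at(diag, a, -w)
        np.add.at(diag, b, -w)
    rows = np.concatenate(rows + [np.arange(size)])
    cols = np.concatenate(cols + [np.arange(size)])
    vals = np.concatenate(vals + [diag])
    return sparse.csr_matrix((vals, (rows, cols)), shape=(size, size))


def _dirichlet_system(L: sparse.csr_matrix, rhs: np.ndarray,
                      dirichlet: np.ndarray, values: np.ndarray):
    """Replace Dirichlet rows of ``L x = rhs`` by identity rows ``x = value``."""
    size = L.shape[0]
    mask = dirichlet.ravel()
    scale = sparse.diags(np.where(mask, 0.0, 1.0))
    A = scale @ L + sparse.diags(mask.astype(float))
    b = np.where(mask, values.ravel(), rhs.ravel())
    return A.tocsr(), b


def _iterative_solve(A, b, x0, tol, maxiter):
    M = sparse.diags(1.0 / A.diagonal())
    x, info = bicgstab(A, b, x0=x0, rtol=tol, atol=0.0, maxiter=maxiter, M=M)
    if info != 0:
        res = np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300)
        raise TransportError(
            f"diffusion solve did not converge (info={info}, rel residual={res:.3e})")
    return x


@dataclass
class SteadyResult:
    C: np.ndarray               # concentration, mM, >= 0
    realised_Q: np.ndarray      # realised consumption, mM/s, <= requested
    limited: np.ndarray         # bool, nodes where sinks were limited
    passes: int


def solve_steady(D: np.ndarray, Q: np.ndarray, fixed: np.ndarray,
                 boundary_mM: float, grid: Grid,
                 tol: float = 1e-8, maxiter: int = 20000,
                 x0: np.ndarray | None = None,
                 limited0: np.ndarray | None = None,
                 max_passes: int = 20) -> SteadyResult:
    """Pseudo-steady solve of div(D grad C) = Q with sink limiting.

    ``fixed`` nodes are Dirichlet at ``boundary_mM``.  Fully depleted nodes
    are pinned to C = 0; their realised consumption is the diffusive inflow
    (never more than requested).  The active set is iterated to
    consistency (nodes released when supply exceeds demand).
    """
    L = _diffusion_matrix(D, grid.h)
    values = np.where(fixed, boundary_mM, 0.0)
    limited = (np.zeros_like(fixed) if limited0 is None
               else (limited0 & ~fixed))
    x = (x0.ravel().copy() if x0 is not None
         else np.full(Q.size, boundary_mM))
    neg_tol = -1e-12 * boundary_mM
    C = x
    for passno in range(1, max_passes + 1):
        dirichlet = fixed | limited
        A, b = _dirichlet_system(L, Q.ravel(), dirichlet, values)
        C = _iterative_solve(A, b, x, tol, maxiter)
        x = C
        Cg = C.reshape(Q.shape)
        inflow = (L @ C).reshape(Q.shape)  # div(D grad C); equals Q at free nodes
        neg = (~dirichlet) & (Cg < neg_tol)
        release = limited & (inflow > Q + 1e-12 * np.maximum(Q.max(), 1.0))
        if not neg.any() and not release.any():
            break
        limited = (limited | neg) & ~release
    Cg = np.maximum(C.reshape(Q.shape), 0.0)
    realised = Q.copy()
    realised[limited] = np.clip(inflow[limited], 0.0, Q[limited])
    return SteadyResult(C=Cg, realised_Q=realised, limited=limited, passes=passno)


def solve_transient(C0: np.ndarray, D: np.ndarray, Q: np.ndarray,
                    fixed: np.ndarray, boundary_mM: float, grid: Grid,
                    dt_s: float, tol: float = 1e-8, maxiter: int = 20000,
                    max_rel_change: float = 0.05) -> np.ndarray:
    """Crank-Nicolson step of the transient equation over ``dt_s`` seconds.

    Adaptive sub-stepping keeps the relative field change per substep below
    ``max_rel_change``; negative concentrations are removed by pinning
    depleted nodes to zero within the substep (same sink limiting as the
    steady solver).
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    L = _diffusion_matrix(D, grid.h)
    values = np.where(fixed, boundary_mM, 0.0)
    scale = max(boundary_mM, float(np.max(np.abs(C0))), 1e-300)
    C = C0.ravel().astype(float).copy()
    identity = sparse.identity(C.size, format="csr")
    remaining = dt_s
    sub = dt_s
    while remaining > 1e-12 * dt_s:
        sub = min(sub, remaining)
        limited = np.zeros_like(fixed)
        for _ in range(6):
            dirichlet = (fixed | limited).ravel()
            keep = sparse.diags(np.where(dirichlet, 0.0, 1.0))
            A = identity - (sub / 2.0) * (keep @ L)
            rhs = C + (sub / 2.0) * (keep @ (L @ C)) - sub * (
                np.where(dirichlet, 0.0, Q.ravel()))
            A, b = _dirichlet_system(A, rhs, dirichlet.reshape(fixed.shape),
                                     values)
            Cn = _iterative_solve(A, b, C, tol, maxiter)
            neg = (~dirichlet) & (Cn < -1e-12 * scale)
            if not neg.any():
                break
            limited = limited | neg.reshape(fixed.shape)
        rel = float(np.max(np.abs(Cn - C))) / scale
        if rel > max_rel_change and sub > dt_s / 1024.0:
            sub /= 2.0
            continue
        C = np.maximum(Cn, 0.0) if limited.any() else Cn
        remaining -= sub
        if rel < max_rel_change / 4.0:
            sub *= 2.0
    return C.reshape(C0.shape)


def sample(C: np.ndarray, positions: np.ndarray, grid: Grid) -> np.ndarray:
    """Trilinear interpolation of nodal values at off-grid points (um)."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    frac = pos / grid.h
    if np.any(frac < -1e-9) or np.any(frac > grid.n - 1 + 1e-9):
        raise TransportError("sample position outside the domain cube")
    frac = np.clip(frac, 0.0, grid.n - 1)
    out = ndimage.map_coordinates(C, frac.T, order=1, mode="nearest")
    return out if positions.ndim > 1 else out
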