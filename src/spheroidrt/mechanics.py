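"""Off-lattice cell mechanics: contacts, JKR forces, pressure, relaxation.

Neighbourhood is a pruned 3D Delaunay triangulation of cell centres.  The
pairwise interaction is the Johnson-Kendall-Roberts adhesive elastic
contact: Hertzian repulsion at positive overlap plus an adhesive neck that
produces a finite pull-off force ``-(3/2) pi gamma R*`` at small negative
overlap.  The equilibrium JKR branch is solved per contact; beyond the
detachment displacement the interaction is exactly zero.  Positions relax
by explicit overdamped (first-order) dynamics; inertia is neglected, as is
standard for cells in a viscous environment.

Internally forces are SI (N, Pa, m); positions and radii stay in um.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .cells import Cell, CellState
from .config import SimulationConfig

UM = 1e-6  # metres per micrometre

# dimensionless JKR branch constants: a_hat at the displacement-controlled
# detachment point, and the corresponding delta_hat
A_HAT_DETACH = 0.25 ** (2.0 / 3.0)
DELTA_HAT_DETACH = A_HAT_DETACH ** 2 - np.sqrt(A_HAT_DETACH)  # ~ -0.4725


@dataclass
class MechanicsParameters:
    youngs_modulus_pa: float = 1000.0
    poisson_ratio: float = 0.4
    adhesion_j_m2: float = 1e-3
    friction_ns_m: float = 1.0
    contact_cutoff_factor: float = 1.05
    max_disp_um: float = 0.1
    force_tol_n: float = 1e-11

    @classmethod
    def from_config(cls, cfg: SimulationConfig) -> "MechanicsParameters":
        return cls(
            youngs_modulus_pa=cfg.youngs_modulus_pa,
            poisson_ratio=cfg.poisson_ratio,
            adhesion_j_m2=cfg.adhesion_j_m2,
            friction_ns_m=cfg.friction_ns_m,
            contact_cutoff_factor=cfg.contact_cutoff_factor,
            max_disp_um=cfg.mech_max_disp_um,
            force_tol_n=cfg.mech_force_tol_n,
        )

    @property
    def e_star(self) -> float:
        """Effective contact modulus E* = E / (2 (1 - nu^2)), Pa."""
        return self.youngs_modulus_pa / (2.0 * (1.0 - self.poisson_ratio ** 2))


class Edge(NamedTuple):
    i: int                 # local index into graph members
    j: int
    dist_um: float
    overlap_um: float      # delta = r_i + r_j - dist
    contact_radius_um: float
    rstar_um: float        # r_i r_j / (r_i + r_j)


@dataclass
class NeighbourGraph:
    members: np.ndarray        # indices into the cell list passed to build
    i: np.ndarray              # local edge endpoints (members indexing)
    j: np.ndarray
    dist: np.ndarray           # um
    overlap: np.ndarray        # um
    contact_radius: np.ndarray  # um, spherical-cap geometric contact radius
    rstar: np.ndarray          # um

    @property
    def n_edges(self) -> int:
        return len(self.i)

    def edges(self) -> Iterator[Edge]:
        for k in range(self.n_edges):
            yield Edge(int(self.i[k]), int(self.j[k]), float(self.dist[k]),
                       float(self.overlap[k]), float(self.contact_radius[k]),
                       float(self.rstar[k]))


def _edge_geometry(positions: np.ndarray, radii: np.ndarray,
                   i: np.ndarray, j: np.ndarray):
    d = positions[i] - positions[j]
    dist = np.linalg.norm(d, axis=1)
    overlap = radii[i] + radii[j] - dist
    rstar = radii[i] * radii[j] / (radii[i] + radii[j])
    contact_radius = np.sqrt(np.maximum(overlap, 0.0) * rstar)
    return dist, overlap, rstar, contact_radius


def _candidate_pairs(positions: np.ndarray,
                     rng: np.random.Generator | None) -> tuple[np.ndarray, np.ndarray]:
    n = len(positions)
    if n < 5:
        iu, ju = np.triu_indices(n, k=1)
        return iu, ju
    pts = positions
    for attempt in range(3):
        try:
            tri = Delaunay(pts)
            break
        except QhullError:
            # degenerate/coincident inputs: tiny seeded jitter, logged upstream
            gen = rng if rng is not None else np.random.default_rng(0)
            pts = pts + gen.uniform(-1e-6, 1e-6, size=pts.shape)
    else:
        iu, ju = np.triu_indices(n, k=1)
        return iu, ju
    s = tri.simplices
    pairs = np.concatenate([s[:, [a, b]] for a in range(4) for b in range(a + 1, 4)])
    lo = pairs.min(axis=1)
    hi = pairs.max(axis=1)
    return lo, hi  # may contain duplicates; deduplicated after pruning


def build_neighbours(cells: list[Cell], params: MechanicsParameters,
                     rng: np.random.Generator | None = None) -> NeighbourGraph:
    """Pruned Delaunay contact graph over all non-dissolved cells."""
    members = np.array([k for k, c in enumerate(cells)
                        if c.state is not CellState.DISSOLVED and c.radius > 0],
                       dtype=int)
    if len(members) == 0:
        raise ValueError("need at least one live cell")
    positions = np.array([cells[k].position for k in members], dtype=float)
    radii = np.array([cells[k].radius for k in members], dtype=float)
    if not np.all(np.isfinite(positions)):
        raise ValueError("non-finite cell position")
    i, j = _candidate_pairs(positions, rng)
    if len(i):
        dist = np.linalg.norm(positions[i] - positions[j], axis=1)
        keep = dist <= params.contact_cutoff_factor * (radii[i] + radii[j])
        i, j = i[keep], j[keep]
        # deduplicate shared simplex edges (cheap after pruning)
        _, first = np.unique(i.astype(np.int64) * len(members) + j,
                             return_index=True)
        i, j = i[first], j[first]
        dist, overlap, rstar, a = _edge_geometry(positions, radii, i, j)
    else:
        dist = overlap = rstar = a = np.empty(0)
    return NeighbourGraph(members=members, i=i, j=j, dist=dist,
                          overlap=overlap, contact_radius=a, rstar=rstar)


def _solve_jkr_branch(delta_hat: np.ndarray) -> np.ndarray:
    """Largest root a_hat of a_hat^2 - sqrt(a_hat) = delta_hat (stable branch).

    Valid for delta_hat >= DELTA_HAT_DETACH; monotone Newton iteration.
    """
    d = np.asarray(delta_hat, dtype=float)
    a = np.maximum(np.sqrt(np.maximum(d, 0.0) + 1.0), A_HAT_DETACH + 0.05)
    for _ in range(60):
        f = a * a - np.sqrt(a) - d
        fp = 2.0 * a - 0.5 / np.sqrt(a)
        step = f / fp
        a = np.maximum(a - step, A_HAT_DETACH)
        if np.all(np.abs(step) < 1e-14 * np.maximum(a, 1.0)):
            break
    return a


def pair_forces(overlap_um: np.ndarray, rstar_um: np.ndarray,
                params: MechanicsParameters) -> np.ndarray:
    """Signed centre-line force per contact (N); positive = repulsive."""
    delta = np.asarray(overlap_um, dtype=float) * UM
    rstar = np.asarray(rstar_um, dtype=float) * UM
    e_star = params.e_star
    gamma = params.adhesion_j_m2
    if gamma == 0.0:
        return (4.0 / 3.0) * e_star * np.sqrt(rstar) * np.maximum(delta, 0.0) ** 1.5
    k = np.sqrt(2.0 * np.pi * gamma / e_star)
    scale = k ** (4.0 / 3.0) * rstar ** (1.0 / 3.0)  # delta scale, m
    delta_hat = delta / scale
    attached = delta_hat >= DELTA_HAT_DETACH
    force = np.zeros_like(delta)
    if np.any(attached):
        a_hat = _solve_jkr_branch(delta_hat[attached])
        force[attached] = (np.pi * gamma * rstar[attached]
                           * ((8.0 / 3.0) * a_hat ** 3 - 4.0 * a_hat ** 1.5))
    return force


def pair_force(edge: Edge, params: MechanicsParameters) -> float:
    """Scalar JKR force for a single contact (N; positive = repulsive)."""
    return float(pair_forces(np.array([edge.overlap_um]),
                             np.array([edge.rstar_um]), params)[0])


def jkr_pulloff_force(rstar_um: float, params: MechanicsParameters) -> float:
    """Closed-form maximum adhesion (pull-off) magnitude, N."""
    return 1.5 * np.pi * params.adhesion_j_m2 * rstar_um * UM


def pressures(cells: list[Cell], graph: NeighbourGraph,
              params: MechanicsParameters) -> np.ndarray:
    """Per-member compressive pressure (Pa): sum of repulsive contact forces
    over the cell surface area.  Adhesive (negative) contributions excluded."""
    radii = np.array([cells[k].radius for k in graph.members], dtype=float)
    total = np.zeros(len(graph.members))
    if graph.n_edges:
        f = pair_forces(graph.overlap, graph.rstar, params)
        rep = np.maximum(f, 0.0)
        n = len(graph.members)
        total += np.bincount(graph.i, weights=rep, minlength=n)
        total += np.bincount(graph.j, weights=rep, minlength=n)
    area = 4.0 * np.pi * (radii * UM) ** 2
    return total / area


def cell_pressure(cell: Cell, cells: list[Cell], graph: NeighbourGraph,
                  params: MechanicsParameters) -> float:
    """Pressure on one cell (Pa); convenience wrapper over :func:`pressures`."""
    p = pressures(cells, graph, params)
    where = np.flatnonzero(np.array([cells[k].id for k in graph.members]) == cell.id)
    if len(where) == 0:
        raise ValueError("cell not part of the neighbour graph")
    return float(p[where[0]])


def net_forces(positions: np.ndarray, radii: np.ndarray,
               graph: NeighbourGraph, params: MechanicsParameters) -> np.ndarray:
    """Net force vector (N) on each graph member at the given positions."""
    forces = np.zeros_like(positions)
    if graph.n_edges == 0:
        return forces
    i, j = graph.i, graph.j
    d = positions[i] - positions[j]
    dist = np.linalg.norm(d, axis=1)
    dist = np.maximum(dist, 1e-9)
    unit = d / dist[:, None]
    overlap = radii[i] + radii[j] - dist
    rstar = radii[i] * radii[j] / (radii[i] + radii[j])
    f = pair_forces(overlap, rstar, params)
    if not np.all(np.isfinite(f)):
        bad = int(np.flatnonzero(~np.isfinite(f))[0])
        raise FloatingPointError(
            f"non-finite contact force on edge ({i[bad]},{j[bad]}): "
            f"dist={dist[bad]:.6g} um overlap={overlap[bad]:.6g} um")
    fv = f[:, None] * unit
    n = len(positions)
    for ax in range(3):
        acc = np.bincount(i, weights=fv[:, ax], minlength=n)
        acc -= np.bincount(j, weights=fv[:, ax], minlength=n)
        forces[:, ax] = acc
    return forces


def relax_positions(cells: list[Cell], graph: NeighbourGraph,
                    params: MechanicsParameters, duration_s: float) -> None:
    """Overdamped position update x <- x + (F/eta) dt over ``duration_s``.

    Substeps are sized so no cell moves more than ``max_disp_um`` per
    substep; exits early once the largest net force drops below
    ``force_tol_n`` (near-equilibrium).  Dissolved cells are skipped
    (they are not graph members).  Positions are updated in place.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if graph.n_edges == 0:
        return
    positions = np.array([cells[k].position for k in graph.members], dtype=float)
    radii = np.array([cells[k].radius for k in graph.members], dtype=float)
    eta = params.friction_ns_m
    remaining = duration_s
    while remaining > 0:
        forces = net_forces(positions, radii, graph, params)
        fmax = np.max(np.linalg.norm(forces, axis=1))
        if fmax < params.force_tol_n:
            break
        vmax_um_s = fmax / eta / UM
        dt = min(remaining, params.max_disp_um / vmax_um_s)
        positions += forces / eta / UM * dt
        remaining -= dt
    for local, k in enumerate(graph.members):
        cells[k].position = positions[local]
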