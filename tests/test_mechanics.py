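"""Contact detection, JKR force law, pressure and overdamped relaxation."""

import numpy as np
import pytest
from scipy.optimize import brentq

from spheroidrt.cells import Cell
from spheroidrt.fixtures import fcc_positions, make_ball_fixture
from spheroidrt.mechanics import (MechanicsParameters, NeighbourGraph,
                                  build_neighbours, cell_pressure,
                                  jkr_pulloff_force, net_forces, pair_force,
                                  pair_forces, pressures, relax_positions)

PAR = MechanicsParameters()
HERTZ = MechanicsParameters(adhesion_j_m2=0.0)
UM = 1e-6


def cells_at(positions, radius=10.0):
    return [Cell(id=k, position=np.asarray(p, dtype=float), radius=radius)
            for k, p in enumerate(positions)]


def brute_force_graph(cells, params):
    """O(N^2) contact oracle with the same cutoff rule."""
    pos = np.array([c.position for c in cells])
    radii = np.array([c.radius for c in cells])
    i, j = np.triu_indices(len(cells), k=1)
    dist = np.linalg.norm(pos[i] - pos[j], axis=1)
    keep = dist <= params.contact_cutoff_factor * (radii[i] + radii[j])
    i, j, dist = i[keep], j[keep], dist[keep]
    overlap = radii[i] + radii[j] - dist
    rstar = radii[i] * radii[j] / (radii[i] + radii[j])
    return NeighbourGraph(members=np.arange(len(cells)), i=i, j=j, dist=dist,
                          overlap=overlap,
                          contact_radius=np.sqrt(np.maximum(overlap, 0) * rstar),
                          rstar=rstar)


class TestNeighbours:
    def test_single_cell_no_edges(self):
        g = build_neighbours(cells_at([[0, 0, 0]]), PAR)
        assert g.n_edges == 0

    def test_touching_pair_has_positive_overlap(self):
        g = build_neighbours(cells_at([[0, 0, 0], [15, 0, 0]]), PAR)
        assert g.n_edges == 1
        assert g.overlap[0] == pytest.approx(5.0)

    def test_far_pair_not_connected(self):
        g = build_neighbours(cells_at([[0, 0, 0], [50, 0, 0]]), PAR)
        assert g.n_edges == 0

    def test_matches_brute_force_on_random_ball(self):
        rng = np.random.default_rng(42)
        pos = rng.uniform(-60, 60, size=(50, 3))
        cells = cells_at(pos)
        delaunay = build_neighbours(cells, PAR)
        oracle = brute_force_graph(cells, PAR)
        got = {(int(a), int(b)) for a, b in zip(delaunay.i, delaunay.j)}
        want = {(int(a), int(b)) for a, b in zip(oracle.i, oracle.j)}
        assert got == want


class TestPairForce:
    def test_hertz_zero_at_zero_overlap(self):
        assert pair_forces(np.array([0.0]), np.array([5.0]), HERTZ)[0] == 0.0

    @pytest.mark.parametrize("delta", [0.1, 0.5, 1.0, 3.0])
    def test_hertz_closed_form(self, delta):
        rstar = 5.0
        got = pair_forces(np.array([delta]), np.array([rstar]), HERTZ)[0]
        e_star = 1000.0 / (2 * (1 - 0.4 ** 2))
        expected = (4.0 / 3.0) * e_star * np.sqrt(rstar * UM) * (delta * UM) ** 1.5
        assert got == pytest.approx(expected, rel=1e-12)

    def test_jkr_pulloff_closed_form(self):
        """Deepest adhesive force equals -(3/2) pi gamma R* within 1%."""
        rstar = np.full(8001, 5.0)
        deltas = np.linspace(-4.0, 4.0, 8001)
        forces = pair_forces(deltas, rstar, PAR)
        assert forces.min() == pytest.approx(-jkr_pulloff_force(5.0, PAR),
                                             rel=0.01)

    def test_zero_beyond_detachment(self):
        assert pair_forces(np.array([-5.0]), np.array([5.0]), PAR)[0] == 0.0

    def test_force_continuous_on_attached_branch(self):
        """F(delta) varies smoothly everywhere on the attached branch; the
        only jump is the finite detachment drop at the branch end."""
        rstar = np.full(8000, 5.0)
        deltas = np.linspace(-0.44, 2.0, 8000)  # inside the attached branch
        f = pair_forces(deltas, rstar, PAR)
        jumps = np.abs(np.diff(f))
        assert jumps.max() < 1e-2 * np.abs(f).max()

    def test_scalar_edge_wrapper(self):
        g = build_neighbours(cells_at([[0, 0, 0], [18, 0, 0]]), PAR)
        edge = next(g.edges())
        assert pair_force(edge, PAR) == pytest.approx(
            pair_forces(g.overlap, g.rstar, PAR)[0])


class TestPressure:
    def test_isolated_cell_zero(self):
        cells = cells_at([[0, 0, 0], [100, 0, 0]])
        g = build_neighbours(cells, PAR)
        assert cell_pressure(cells[0], cells, g, PAR) == 0.0

    def test_symmetric_pair_equal_pressure(self):
        cells = cells_at([[0, 0, 0], [13, 0, 0]])  # compressed past equilibrium
        g = build_neighbours(cells, PAR)
        p = pressures(cells, g, PAR)
        assert p[0] == pytest.approx(p[1], rel=1e-12)
        assert p[0] > 0

    def test_13_cell_packing_matches_hand_sum(self):
        """Centre cell of a 12-neighbour FCC shell: pressure equals the
        hand-summed Hertz forces over the surface area."""
        r = 10.0
        spacing = 1.8 * r  # overlap 0.2 r per contact
        shell = fcc_positions(spacing * 1.01, spacing, np.zeros(3))
        cells = cells_at(shell, radius=r)
        centre_idx = int(np.argmin(np.linalg.norm(shell, axis=1)))
        g = brute_force_graph(cells, HERTZ)
        delta = 2 * r - spacing
        e_star = HERTZ.e_star
        f_one = (4 / 3) * e_star * np.sqrt((r / 2) * UM) * (delta * UM) ** 1.5
        expected = 12 * f_one / (4 * np.pi * (r * UM) ** 2)
        got = pressures(cells, g, HERTZ)[centre_idx]
        assert got == pytest.approx(expected, rel=1e-9)

    def test_pressure_non_negative(self):
        rng = np.random.default_rng(3)
        cells = cells_at(rng.uniform(0, 80, size=(40, 3)))
        g = build_neighbours(cells, PAR)
        assert np.all(pressures(cells, g, PAR) >= 0)


class TestRelaxation:
    def test_no_contacts_positions_unchanged(self):
        cells = cells_at([[0, 0, 0], [100, 0, 0]])
        g = build_neighbours(cells, PAR)
        before = [c.position.copy() for c in cells]
        relax_positions(cells, g, PAR, 600.0)
        for b, c in zip(before, cells):
            assert np.array_equal(b, c.position)

    def test_pure_repulsion_separates_monotonically(self):
        cells = cells_at([[0, 0, 0], [15, 0, 0]])
        g = build_neighbours(cells, HERTZ)
        seps = [15.0]
        for _ in range(40):
            relax_positions(cells, g, HERTZ, 100.0)
            seps.append(np.linalg.norm(cells[0].position - cells[1].position))
        assert all(b >= a - 1e-12 for a, b in zip(seps, seps[1:]))
        assert seps[-1] >= 20.0 - 0.05  # overlap resolved to force tolerance

    def test_adhesive_pair_finds_equilibrium_overlap(self):
        """Relaxation converges to the root of the JKR force law."""
        delta_eq = brentq(
            lambda d: pair_forces(np.array([d]), np.array([5.0]), PAR)[0],
            -0.2, 8.0)
        cells = cells_at([[0, 0, 0], [19.5, 0, 0]])  # just past contact
        g = build_neighbours(cells, PAR)
        for _ in range(80):
            relax_positions(cells, g, PAR, 400.0)
        sep = np.linalg.norm(cells[0].position - cells[1].position)
        assert 20.0 - sep == pytest.approx(delta_eq, abs=0.02)

    def test_newtons_third_law(self):
        rng = np.random.default_rng(11)
        cells = cells_at(rng.uniform(0, 70, size=(60, 3)))
        g = build_neighbours(cells, PAR)
        pos = np.array([c.position for c in cells])[g.members]
        radii = np.array([c.radius for c in cells])[g.members]
        total = net_forces(pos, radii, g, PAR).sum(axis=0)
        assert np.allclose(total, 0.0, atol=1e-22)

    def test_energy_decreases_monotonically(self):
        """Overdamped relaxation of a random 100-cell cluster dissipates
        the Hertz interaction energy step by step."""
        rng = np.random.default_rng(21)
        cells = cells_at(rng.uniform(0, 90, size=(100, 3)))
        g = build_neighbours(cells, HERTZ)
        e_star = HERTZ.e_star

        def energy():
            pos = np.array([c.position for c in cells])[g.members]
            radii = np.array([c.radius for c in cells])[g.members]
            d = np.linalg.norm(pos[g.i] - pos[g.j], axis=1)
            delta = np.maximum(radii[g.i] + radii[g.j] - d, 0.0) * UM
            rstar = radii[g.i] * radii[g.j] / (radii[g.i] + radii[g.j]) * UM
            return np.sum((8 / 15) * e_star * np.sqrt(rstar) * delta ** 2.5)

        energies = [energy()]
        for _ in range(25):
            relax_positions(cells, g, HERTZ, 5.0)
            energies.append(energy())
        assert all(b <= a + 1e-30 for a, b in zip(energies, energies[1:]))
        assert energies[-1] < energies[0]

    def test_duration_must_be_positive(self):
        cells = cells_at([[0, 0, 0], [15, 0, 0]])
        g = build_neighbours(cells, PAR)
        with pytest.raises(ValueError):
            relax_positions(cells, g, PAR, 0.0)


class TestPruningOracle:
    def test_pressures_match_brute_force_on_500_cell_ball(self):
        """Delaunay+pruning and the O(N^2) contact oracle give identical
        per-cell pressures on a packed ball fixture."""
        cells = make_ball_fixture(70.0, packing="dense", centre=np.zeros(3))
        assert len(cells) >= 400
        p_fast = pressures(cells, build_neighbours(cells, PAR), PAR)
        p_slow = pressures(cells, brute_force_graph(cells, PAR), PAR)
        assert np.allclose(p_fast, p_slow, rtol=1e-12, atol=1e-15)

    def test_close_packing_pressure_scale(self):
        """Packing compressed past the adhesive equilibrium produces
        pressures on the 10^2 Pa scale, so the 200 Pa quiescence threshold
        is meaningful at close packing."""
        r = 10.0
        pos = fcc_positions(70.0, 1.35 * r, np.zeros(3))
        cells = cells_at(pos, radius=r)
        g = build_neighbours(cells, PAR)
        interior = np.linalg.norm(pos, axis=1) < 40.0
        p = pressures(cells, g, PAR)[interior]
        assert 50.0 < np.median(p) < 2000.0
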