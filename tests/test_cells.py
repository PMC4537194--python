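"""Cell-cycle state machine, growth law, consumption and death pathways."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spheroidrt.cells import (Cell, CellEvent, CellParameters, CellState,
                              advance_cycle, consumption_rate, divide,
                              radius_at_age)

P = CellParameters()


def make_cell(state=CellState.G1, phase_age=0.0, pressure=0.0,
              glucose=5.0, po2=0.13, **kw):
    cell = Cell(id=0, position=np.zeros(3), radius=radius_at_age(phase_age, P),
                state=state, phase_age=phase_age, pressure=pressure,
                local_pO2=po2, local_glucose=glucose, **kw)
    return cell


class TestConsumption:
    @pytest.mark.parametrize("state,nutrient,expected", [
        (CellState.G1, "O2", 83.0),
        (CellState.M, "O2", 83.0),
        (CellState.S, "glucose", 180.0),
        (CellState.QUIESCENT, "glucose", 130.0),
        (CellState.QUIESCENT, "O2", 49.0),
        (CellState.ARRESTED_DAMAGED, "O2", 49.0),
        (CellState.NECROTIC, "O2", 0.0),
        (CellState.APOPTOTIC, "glucose", 0.0),
    ])
    def test_zero_order_rates(self, state, nutrient, expected):
        assert consumption_rate(make_cell(state), nutrient, P) == expected

    def test_dissolved_rejected(self):
        with pytest.raises(ValueError):
            consumption_rate(make_cell(CellState.DISSOLVED), "O2", P)

    def test_quiescence_toggles_consumption(self, rng):
        """Crossing P_crit back and forth switches active <-> quiescent rates."""
        cell = make_cell(CellState.G1, phase_age=P.t_g1_h - 0.01, pressure=250.0)
        advance_cycle(cell, 0.02, P, rng)
        assert cell.state is CellState.QUIESCENT
        assert consumption_rate(cell, "O2", P) == 49.0
        cell.pressure = 100.0
        advance_cycle(cell, 0.02, P, rng)
        assert cell.state is CellState.S
        assert consumption_rate(cell, "O2", P) == 83.0


class TestQuiescence:
    def test_supercritical_pressure_enters_quiescence(self, rng):
        cell = make_cell(phase_age=P.t_g1_h - 0.05, pressure=250.0)
        events = advance_cycle(cell, 0.1, P, rng)
        assert CellEvent.ENTER_QUIESCENCE in events
        assert cell.state is CellState.QUIESCENT

    def test_exactly_critical_pressure_passes_checkpoint(self, rng):
        # quiescence requires pressure strictly above P_crit
        cell = make_cell(phase_age=P.t_g1_h - 0.05, pressure=200.0)
        advance_cycle(cell, 0.1, P, rng)
        assert cell.state is CellState.S

    def test_just_above_critical_quiesces(self, rng):
        cell = make_cell(phase_age=P.t_g1_h - 0.05, pressure=200.0 + 1e-9)
        advance_cycle(cell, 0.1, P, rng)
        assert cell.state is CellState.QUIESCENT

    def test_release_at_subcritical_pressure(self, rng):
        cell = make_cell(CellState.QUIESCENT, phase_age=P.t_g1_h, pressure=0.0)
        events = advance_cycle(cell, 0.1, P, rng)
        assert events == [CellEvent.EXIT_QUIESCENCE]
        assert cell.state is CellState.S


class TestDeath:
    def test_starvation_triggers_necrosis(self, rng):
        cell = make_cell(glucose=0.0)
        events = advance_cycle(cell, 0.1, P, rng)
        assert events == [CellEvent.NECROSE]
        assert cell.state is CellState.NECROTIC

    def test_anoxia_alone_never_kills(self, rng):
        cell = make_cell(po2=0.0, glucose=1.0)
        for _ in range(50):
            events = advance_cycle(cell, 0.1, P, rng)
            assert not {CellEvent.NECROSE, CellEvent.MITOTIC_DEATH} & set(events)
        assert cell.state in (CellState.G1, CellState.S)

    def test_dead_cells_shrink_and_dissolve(self, rng):
        cell = make_cell(glucose=0.0)
        advance_cycle(cell, 0.1, P, rng)
        r0 = cell.radius
        radii = [r0]
        for _ in range(10000):
            events = advance_cycle(cell, 1.0, P, rng)
            radii.append(cell.radius)
            if CellEvent.DISSOLVE in events:
                break
        assert cell.state is CellState.DISSOLVED
        assert cell.radius == 0.0
        assert all(b <= a for a, b in zip(radii, radii[1:]))  # monotone shrink

    def test_death_clock_means(self):
        """Dissolution durations are exponential with the configured means."""
        rng = np.random.default_rng(0)
        durations = []
        for _ in range(3000):
            cell = make_cell(glucose=0.0)
            advance_cycle(cell, 0.1, P, rng)
            durations.append(cell.death_duration)
        mean = np.mean(durations)
        # 3 sigma of the sample mean of Exp(24): 24/sqrt(3000)*3 ~ 1.3
        assert abs(mean - P.tau_necrosis_h) < 1.5

    def test_arrested_damaged_dies_at_mitotic_attempts(self):
        rng = np.random.default_rng(3)
        died = 0
        for _ in range(2000):
            cell = make_cell(CellState.ARRESTED_DAMAGED,
                             phase_age=P.t_g1_h + P.t_s_h + P.t_g2_h,
                             damaged=True)
            events = advance_cycle(cell, P.t_m_h, P, rng)  # one attempt
            died += CellEvent.MITOTIC_DEATH in events
        # one attempt kills with probability MM = 0.3 (3 sigma binomial)
        assert abs(died / 2000 - P.mm) < 3 * np.sqrt(0.3 * 0.7 / 2000)


class TestCycleProgression:
    def test_volume_doubles_over_one_cycle(self, rng):
        cell = make_cell()
        n = 2000
        dt = P.cycle_time_h / n
        for _ in range(n):
            events = advance_cycle(cell, dt, P, rng)
            if CellEvent.DIVIDE in events:
                break
        assert CellEvent.DIVIDE in events
        assert cell.radius == pytest.approx(P.r_final_um, rel=1e-3)
        ratio = P.r_final_um ** 3 / P.r_init_um ** 3
        assert ratio == pytest.approx(2.0, rel=2e-3)

    def test_damaged_cell_arrests_at_g2m(self, rng):
        cell = make_cell(CellState.G2, phase_age=P.t_g1_h + P.t_s_h + P.t_g2_h - 0.1,
                         damaged=True)
        events = advance_cycle(cell, 0.2, P, rng)
        assert events == [CellEvent.ARREST]
        assert cell.state is CellState.ARRESTED_DAMAGED

    def test_negative_dt_rejected(self, rng):
        with pytest.raises(ValueError):
            advance_cycle(make_cell(), -0.1, P, rng)

    def test_dissolved_rejected(self, rng):
        with pytest.raises(ValueError):
            advance_cycle(make_cell(CellState.DISSOLVED), 0.1, P, rng)


class TestDivision:
    def _mother(self):
        return make_cell(CellState.M, phase_age=P.cycle_time_h)

    def test_daughter_radii(self, rng):
        d1, d2 = divide(self._mother(), rng, params=P)
        assert d1.radius == d2.radius == P.r_init_um
        assert d1.state is d2.state is CellState.G1

    def test_daughter_volume_ratio(self, rng):
        mother = self._mother()
        d1, d2 = divide(mother, rng, params=P)
        ratio = (d1.volume() + d2.volume()) / mother.volume()
        assert ratio == pytest.approx(2 * 7.94 ** 3 / 10 ** 3, rel=1e-9)

    def test_daughters_overlap_at_most_one_radius(self, rng):
        d1, d2 = divide(self._mother(), rng, params=P)
        sep = np.linalg.norm(d1.position - d2.position)
        assert sep == pytest.approx(P.r_init_um, rel=1e-9)
        overlap = 2 * P.r_init_um - sep
        assert overlap <= P.r_init_um + 1e-9

    def test_same_seed_same_axis(self):
        a = divide(self._mother(), np.random.default_rng(5), params=P)
        b = divide(self._mother(), np.random.default_rng(5), params=P)
        assert np.allclose(a[0].position, b[0].position)
        assert np.allclose(a[1].position, b[1].position)

    def test_non_m_division_rejected(self, rng):
        with pytest.raises(ValueError):
            divide(make_cell(CellState.G1), rng, params=P)


# one-biology-step legal transitions per starting state (small dt: at most
# one checkpoint can be crossed)
LEGAL = {
    CellState.G1: {CellState.G1, CellState.S, CellState.QUIESCENT,
                   CellState.NECROTIC},
    CellState.S: {CellState.S, CellState.G2, CellState.NECROTIC},
    CellState.G2: {CellState.G2, CellState.M, CellState.ARRESTED_DAMAGED,
                   CellState.NECROTIC},
    CellState.M: {CellState.M, CellState.NECROTIC},
    CellState.QUIESCENT: {CellState.QUIESCENT, CellState.S, CellState.NECROTIC},
    CellState.ARRESTED_DAMAGED: {CellState.ARRESTED_DAMAGED,
                                 CellState.APOPTOTIC, CellState.NECROTIC},
    CellState.APOPTOTIC: {CellState.APOPTOTIC, CellState.DISSOLVED},
    CellState.NECROTIC: {CellState.NECROTIC, CellState.DISSOLVED},
}

AGE_FOR_STATE = {
    CellState.G1: 0.0, CellState.S: P.t_g1_h, CellState.G2: P.t_g1_h + P.t_s_h,
    CellState.M: P.t_g1_h + P.t_s_h + P.t_g2_h,
}


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    state=st.sampled_from(sorted(LEGAL, key=lambda s: s.name)),
    age_frac=st.floats(0.0, 0.999),
    pressure=st.floats(0.0, 400.0),
    glucose=st.floats(0.0, 5.0),
    damaged=st.booleans(),
    seed=st.integers(0, 2 ** 20),
)
def test_state_machine_closure(state, age_frac, pressure, glucose, damaged, seed):
    """Small-step fuzzing never produces an illegal state transition."""
    rng = np.random.default_rng(seed)
    if state in AGE_FOR_STATE:
        base = AGE_FOR_STATE[state]
        span = {CellState.G1: P.t_g1_h, CellState.S: P.t_s_h,
                CellState.G2: P.t_g2_h, CellState.M: P.t_m_h}[state]
        age = base + age_frac * span
    else:
        age = P.t_g1_h
    cell = make_cell(state, phase_age=age, pressure=pressure, glucose=glucose,
                     damaged=damaged or state is CellState.ARRESTED_DAMAGED)
    if state in (CellState.APOPTOTIC, CellState.NECROTIC):
        cell.death_duration = cell.death_clock = 1.0 + 10.0 * age_frac
        cell.radius_at_death = cell.radius
    dt = 0.1  # h, less than the shortest phase
    for _ in range(5):
        before = cell.state
        advance_cycle(cell, dt, P, rng)
        allowed = LEGAL[before] | ({CellState.M} if before is CellState.G2
                                   else set())
        assert cell.state in allowed, f"{before} -> {cell.state}"
        if cell.state is CellState.DISSOLVED:
            break
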