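"""Cell domain types and the cell-cycle state machine.

Cells progress G1 -> S -> G2 -> M and divide at the end of M.  Growth is
linear in *volume* across the cycle, from the initial radius (start of G1)
to the final radius (end of G2/M), so a full unperturbed cycle doubles the
cell volume.  At the G1/S checkpoint a cell under supra-critical mechanical
pressure enters reversible quiescence and is released once the pressure
drops back below ``P_crit``.  Glucose starvation triggers necrosis in any
live state; cells are fully tolerant to anoxia (oxygen never kills).
Radiation-damaged cells arrest at the G2/M checkpoint and undergo mitotic
death with a fixed per-attempt probability.  Dead cells shrink linearly to
zero radius over an exponentially distributed dissolution time and are then
removed from the system (DISSOLVED).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum, auto

import numpy as np

from .config import SimulationConfig


class CellState(Enum):
    G1 = auto()
    S = auto()
    G2 = auto()
    M = auto()
    QUIESCENT = auto()
    ARRESTED_DAMAGED = auto()
    APOPTOTIC = auto()
    NECROTIC = auto()
    DISSOLVED = auto()


#: states that consume at the active rate
CYCLING_STATES = frozenset({CellState.G1, CellState.S, CellState.G2, CellState.M})
#: live = counted in census fractions (cycling + quiescent + arrested)
LIVE_STATES = CYCLING_STATES | {CellState.QUIESCENT, CellState.ARRESTED_DAMAGED}
DEAD_STATES = frozenset({CellState.APOPTOTIC, CellState.NECROTIC})


class CellEvent(Enum):
    DIVIDE = auto()
    ENTER_QUIESCENCE = auto()
    EXIT_QUIESCENCE = auto()
    NECROSE = auto()
    DISSOLVE = auto()
    ARREST = auto()
    MITOTIC_DEATH = auto()


@dataclass
class CellParameters:
    t_g1_h: float = 8.0
    t_s_h: float = 8.0
    t_g2_h: float = 3.0
    t_m_h: float = 1.0
    r_init_um: float = 7.94
    r_final_um: float = 10.0
    o2_active_amol_s: float = 83.0
    o2_quiescent_amol_s: float = 49.0
    glucose_active_amol_s: float = 180.0
    glucose_quiescent_amol_s: float = 130.0
    p_crit_pa: float = 200.0
    starvation_glucose_mM: float = 0.0
    hypoxia_threshold_mM: float = 0.014
    tau_necrosis_h: float = 24.0
    tau_apoptosis_h: float = 12.0
    mm: float = 0.3

    @classmethod
    def from_config(cls, cfg: SimulationConfig) -> "CellParameters":
        return cls(
            t_g1_h=cfg.t_g1_h, t_s_h=cfg.t_s_h, t_g2_h=cfg.t_g2_h,
            t_m_h=cfg.t_m_h, r_init_um=cfg.r_init_um, r_final_um=cfg.r_final_um,
            o2_active_amol_s=cfg.oxygen_active_amol_s,
            o2_quiescent_amol_s=cfg.oxygen_quiescent_amol_s,
            glucose_active_amol_s=cfg.glucose_active_amol_s,
            glucose_quiescent_amol_s=cfg.glucose_quiescent_amol_s,
            p_crit_pa=cfg.p_crit_pa,
            starvation_glucose_mM=cfg.starvation_glucose_mM,
            hypoxia_threshold_mM=cfg.hypoxia_threshold_mM,
            tau_necrosis_h=cfg.tau_necrosis_h, tau_apoptosis_h=cfg.tau_apoptosis_h,
            mm=cfg.mm,
        )

    @property
    def cycle_time_h(self) -> float:
        return self.t_g1_h + self.t_s_h + self.t_g2_h + self.t_m_h

    def phase_boundaries(self) -> tuple[float, float, float, float]:
        """Cumulative phase-age boundaries (end of G1, S, G2, M) in hours."""
        b1 = self.t_g1_h
        b2 = b1 + self.t_s_h
        b3 = b2 + self.t_g2_h
        return b1, b2, b3, b3 + self.t_m_h


_id_counter = itertools.count()


def fresh_id() -> int:
    return next(_id_counter)


@dataclass
class Cell:
    id: int
    position: np.ndarray          # (3,) um
    radius: float                 # um
    state: CellState = CellState.G1
    phase_age: float = 0.0        # h within the cycle (cumulative over phases)
    damaged: bool = False         # delayed radiation damage flag
    death_clock: float = 0.0      # h remaining until dissolution (dead states)
    pressure: float = 0.0         # Pa, cached from mechanics
    local_pO2: float = 0.13       # mM, cached from transport
    local_glucose: float = 5.0    # mM, cached from transport
    # internal bookkeeping
    death_duration: float = 0.0   # h, total drawn dissolution time
    radius_at_death: float = 0.0  # um
    arrest_timer: float = 0.0     # h since last mitotic attempt while arrested

    def volume(self) -> float:
        return (4.0 / 3.0) * np.pi * self.radius ** 3

    @property
    def alive(self) -> bool:
        return self.state in LIVE_STATES


def radius_at_age(phase_age: float, params: CellParameters) -> float:
    """Radius under linear-in-volume growth across the whole cycle."""
    v0 = params.r_init_um ** 3
    v1 = params.r_final_um ** 3
    frac = min(max(phase_age / params.cycle_time_h, 0.0), 1.0)
    return (v0 + (v1 - v0) * frac) ** (1.0 / 3.0)


def _start_death(cell: Cell, state: CellState, tau_h: float,
                 rng: np.random.Generator) -> None:
    cell.state = state
    cell.death_duration = max(rng.exponential(tau_h), 1e-6)
    cell.death_clock = cell.death_duration
    cell.radius_at_death = cell.radius
    cell.arrest_timer = 0.0


def advance_cycle(cell: Cell, dt: float, params: CellParameters,
                  rng: np.random.Generator) -> list[CellEvent]:
    """Advance one cell by ``dt`` hours; return the emitted events.

    The caller is responsible for acting on ``DIVIDE`` (via :func:`divide`)
    and for keeping the cached environment fields (pressure, pO2, glucose)
    up to date before the call.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if cell.state is CellState.DISSOLVED:
        raise ValueError("cannot advance a dissolved cell")
    if not isinstance(cell.state, CellState):
        raise ValueError(f"unknown cell state {cell.state!r}")

    events: list[CellEvent] = []

    # -- dead cells: count down and shrink ----------------------------------
    if cell.state in DEAD_STATES:
        cell.death_clock = max(cell.death_clock - dt, 0.0)
        if cell.death_clock <= 0.0:
            cell.state = CellState.DISSOLVED
            cell.radius = 0.0
            events.append(CellEvent.DISSOLVE)
        else:
            cell.radius = cell.radius_at_death * cell.death_clock / cell.death_duration
        return events

    # -- starvation necrosis (any live state; anoxia alone never kills) -----
    if cell.local_glucose <= params.starvation_glucose_mM:
        _start_death(cell, CellState.NECROTIC, params.tau_necrosis_h, rng)
        events.append(CellEvent.NECROSE)
        return events

    if cell.state is CellState.QUIESCENT:
        if cell.pressure <= params.p_crit_pa:
            cell.state = CellState.S
            cell.phase_age = params.t_g1_h
            events.append(CellEvent.EXIT_QUIESCENCE)
        return events

    if cell.state is CellState.ARRESTED_DAMAGED:
        cell.arrest_timer += dt
        while cell.arrest_timer >= params.t_m_h:
            cell.arrest_timer -= params.t_m_h
            if rng.random() < params.mm:
                _start_death(cell, CellState.APOPTOTIC, params.tau_apoptosis_h, rng)
                events.append(CellEvent.MITOTIC_DEATH)
                return events
        return events

    # -- active cycling ------------------------------------------------------
    b_g1, b_s, b_g2, b_m = params.phase_boundaries()
    remaining = dt
    while remaining > 0:
        if cell.phase_age < b_g1:
            boundary, crossing = b_g1, "g1/s"
        elif cell.phase_age < b_s:
            boundary, crossing = b_s, "s/g2"
        elif cell.phase_age < b_g2:
            boundary, crossing = b_g2, "g2/m"
        else:
            boundary, crossing = b_m, "division"
        step = min(remaining, boundary - cell.phase_age)
        cell.phase_age += step
        remaining -= step
        cell.radius = radius_at_age(cell.phase_age, params)
        if cell.phase_age < boundary:
            break
        # checkpoint reached
        if crossing == "g1/s":
            if cell.pressure > params.p_crit_pa:
                cell.state = CellState.QUIESCENT
                cell.phase_age = b_g1
                events.append(CellEvent.ENTER_QUIESCENCE)
                return events
            cell.state = CellState.S
        elif crossing == "s/g2":
            cell.state = CellState.G2
        elif crossing == "g2/m":
            if cell.damaged:
                cell.state = CellState.ARRESTED_DAMAGED
                cell.arrest_timer = 0.0
                events.append(CellEvent.ARREST)
                return events
            cell.state = CellState.M
        else:  # end of M
            cell.phase_age = b_m
            cell.radius = params.r_final_um
            events.append(CellEvent.DIVIDE)
            return events
    return events


def divide(cell: Cell, rng: np.random.Generator,
           params: CellParameters | None = None,
           id_start: int | None = None) -> tuple[Cell, Cell]:
    """Split a mother cell at the end of M into two G1 daughters.

    Daughters of initial radius are placed symmetrically about the mother
    centre along a uniformly random unit axis, centre separation equal to
    one initial radius (they overlap; mechanics relaxation resolves it).
    """
    if cell.state is not CellState.M:
        raise ValueError("only cells at the end of M may divide")
    # uniform random direction (via normalised normal deviates)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    r_init = params.r_init_um if params is not None else cell.radius * 0.5 ** (1 / 3)
    offset = axis * (r_init / 2.0)
    ids = (fresh_id(), fresh_id()) if id_start is None else (id_start, id_start + 1)
    daughters = tuple(
        Cell(id=i, position=cell.position + s * offset, radius=r_init,
             state=CellState.G1, phase_age=0.0,
             local_pO2=cell.local_pO2, local_glucose=cell.local_glucose)
        for i, s in zip(ids, (+1.0, -1.0))
    )
    return daughters  # type: ignore[return-value]


def consumption_rate(cell: Cell, nutrient: str, params: CellParameters) -> float:
    """Zero-order uptake demand in amol/s (independent of concentration)."""
    if cell.state is CellState.DISSOLVED:
        raise ValueError("dissolved cells have no consumption")
    nutrient = nutrient.lower()
    if nutrient in ("o2", "oxygen"):
        active, quiescent = params.o2_active_amol_s, params.o2_quiescent_amol_s
    elif nutrient in ("glucose", "glc"):
        active, quiescent = params.glucose_active_amol_s, params.glucose_quiescent_amol_s
    else:
        raise ValueError(f"unknown nutrient {nutrient!r}")
    if cell.state in CYCLING_STATES:
        return active
    if cell.state in (CellState.QUIESCENT, CellState.ARRESTED_DAMAGED):
        # non-cycling cells consume at the reduced (quiescent) rate
        return quiescent
    return 0.0  # apoptotic / necrotic
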