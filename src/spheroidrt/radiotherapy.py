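"""Radiation response: phase-dependent LQ survival, OER, dose delivery.

Survival of a cell receiving dose ``D`` follows the linear-quadratic model
``S_p = exp(-(alpha_p D_eff + beta_p D_eff^2))`` with phase-group specific
coefficients (G1, S, M/G2).  The effective dose combines two modifiers:

* oxygen enhancement, ``D_eff = D * OER(pO2) / O_max`` with the
  Alper/Howard-Flanders form ``OER(p) = (O_max p + H) / (p + H)`` — fully
  oxic cells receive the nominal dose, anoxic cells ``D / O_max``; setting
  ``O_max = 1`` makes radiation damage oxygen-independent (hypoxic
  sensitizer limit);
* quiescence resistance, a further division by ``QRF`` for quiescent
  cells.

Cells that fail the survival roll die acutely with probability ``AC``
(apoptotic, fast dissolution) or carry delayed damage: they arrest at the
G2/M checkpoint and die at an attempted mitosis with per-attempt
probability ``MM`` (handled by the cell-cycle machine).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum, auto
import numpy as np

from .cells import Cell, CellState, _start_death
from .config import SimulationConfig


class RadiationError(ValueError):
    pass


@dataclass
class RadiationParameters:
    alpha: dict = field(default_factory=lambda: {"G1": 0.351, "S": 0.1235,
                                                 "M/G2": 0.793})
    beta: dict = field(default_factory=lambda: {"G1": 0.04, "S": 0.0285,
                                                "M/G2": 0.0})
    qrf: float = 1.5
    o_max: float = 2.9
    h_mM: float = 0.0052          # OER half-effect concentration
    ac: float = 0.66              # acute death chance
    mm: float = 0.3               # mitotic mismatch rate
    tau_apoptosis_h: float = 12.0

    @classmethod
    def from_config(cls, cfg: SimulationConfig) -> "RadiationParameters":
        return cls(
            alpha={"G1": cfg.alpha_g1, "S": cfg.alpha_s, "M/G2": cfg.alpha_g2m},
            beta={"G1": cfg.beta_g1, "S": cfg.beta_s, "M/G2": cfg.beta_g2m},
            qrf=cfg.qrf, o_max=cfg.o_max, h_mM=cfg.oer_h_mM,
            ac=cfg.ac, mm=cfg.mm, tau_apoptosis_h=cfg.tau_apoptosis_h,
        )


#: LQ phase group per cell state.  Quiescent cells sit at the G1/S
#: checkpoint (G1 coefficients + QRF); arrested cells are held at G2/M.
PHASE_GROUP = {
    CellState.G1: "G1",
    CellState.S: "S",
    CellState.G2: "M/G2",
    CellState.M: "M/G2",
    CellState.QUIESCENT: "G1",
    CellState.ARRESTED_DAMAGED: "M/G2",
}


def oer(pO2_mM, params: RadiationParameters):
    """Oxygen enhancement ratio (O_max p + H) / (p + H); OER(0)=1."""
    p = np.asarray(pO2_mM, dtype=float)
    if np.any(p < 0):
        raise RadiationError("pO2 must be non-negative")
    with np.errstate(invalid="ignore"):
        value = (params.o_max * p + params.h_mM) / (p + params.h_mM)
    value = np.where(np.isinf(p), params.o_max, value)
    return float(value) if np.isscalar(pO2_mM) else value


def survival_probability(phase_group: str, quiescent: bool, dose_gy: float,
                         pO2_mM: float, params: RadiationParameters) -> float:
    """LQ survival with oxygen-enhancement and quiescence dose scaling."""
    if dose_gy < 0:
        raise RadiationError("dose must be non-negative")
    if phase_group not in params.alpha:
        raise RadiationError(f"unknown phase group {phase_group!r}")
    d_eff = dose_gy * oer(pO2_mM, params) / params.o_max
    if quiescent:
        d_eff /= params.qrf
    a, b = params.alpha[phase_group], params.beta[phase_group]
    return float(np.exp(-(a * d_eff + b * d_eff ** 2)))


class Outcome(Enum):
    SURVIVE = auto()
    ACUTE_DEATH = auto()
    DELAYED_DEATH = auto()


def irradiate(cells: list[Cell], dose_gy: float, params: RadiationParameters,
              rng: np.random.Generator,
              o_max_override: float | None = None) -> dict[int, Outcome]:
    """Deliver a dose; mutate cells and return per-cell outcomes by id.

    Cells are processed in id order so the outcome stream is a pure
    function of the RNG seed.  Requires cached cell pO2 to be current
    (solve transport immediately before delivery).  Dead cells are
    unaffected and not reported.
    """
    if dose_gy < 0:
        raise RadiationError("dose must be non-negative")
    p = params
    if o_max_override is not None:
        p = RadiationParameters(alpha=params.alpha, beta=params.beta,
                                qrf=params.qrf, o_max=o_max_override,
                                h_mM=params.h_mM, ac=params.ac, mm=params.mm,
                                tau_apoptosis_h=params.tau_apoptosis_h)
    outcomes: dict[int, Outcome] = {}
    for cell in sorted((c for c in cells if c.state in PHASE_GROUP),
                       key=lambda c: c.id):
        group = PHASE_GROUP[cell.state]
        quiescent = cell.state is CellState.QUIESCENT
        s = survival_probability(group, quiescent, dose_gy, cell.local_pO2, p)
        if rng.random() < s:
            outcomes[cell.id] = Outcome.SURVIVE
            continue
        if rng.random() < p.ac:
            _start_death(cell, CellState.APOPTOTIC, p.tau_apoptosis_h, rng)
            outcomes[cell.id] = Outcome.ACUTE_DEATH
        else:
            cell.damaged = True
            if cell.state is CellState.M:
                # already past the G2/M checkpoint: arrest immediately,
                # damaged cells never complete a division
                cell.state = CellState.ARRESTED_DAMAGED
                cell.arrest_timer = 0.0
            outcomes[cell.id] = Outcome.DELAYED_DEATH
    return outcomes


@dataclass(frozen=True)
class DoseEvent:
    time_h: float
    dose_gy: float
    o_max: float | None = None   # None -> global default


@dataclass
class TreatmentSchedule:
    events: tuple[DoseEvent, ...] = ()

    def __post_init__(self):
        times = [e.time_h for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise RadiationError("schedule times must be strictly increasing")
        if any(e.dose_gy < 0 for e in self.events):
            raise RadiationError("doses must be non-negative")

    @classmethod
    def fractionated(cls, first_time_h: float, dose_gy: float,
                     interval_h: float, n_fractions: int,
                     o_max: float | None = None) -> "TreatmentSchedule":
        return cls(tuple(DoseEvent(first_time_h + k * interval_h, dose_gy, o_max)
                         for k in range(n_fractions)))

    @classmethod
    def read_csv(cls, path) -> "TreatmentSchedule":
        events = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                o_max = row.get("omax", "")
                events.append(DoseEvent(
                    time_h=float(row["time_h"]), dose_gy=float(row["dose_Gy"]),
                    o_max=float(o_max) if o_max not in ("", None) else None))
        return cls(tuple(events))

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_h", "dose_Gy", "omax"])
            for e in self.events:
                w.writerow([e.time_h, e.dose_gy,
                            "" if e.o_max is None else e.o_max])


def run_schedule(sim, schedule: TreatmentSchedule):
    """Advance a grown simulation through a treatment schedule.

    Thin forwarding wrapper; the coupled loop lives in
    :meth:`spheroidrt.runner.Simulation.run_schedule`.
    """
    return sim.run_schedule(schedule)
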