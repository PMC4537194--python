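"""Experiment orchestration: the coupled growth/treatment loop.

One biology step (default 10 simulated minutes) performs, in order:

1. deposit cell density and zero-order sinks, adapt the blood boundary,
   and re-solve both nutrient fields to pseudo-steady state;
2. sample the fields at the cell centres (cached pO2 / glucose);
3. deliver any radiation dose scheduled for this instant;
4. advance every cell's cycle state machine and apply division/death;
5. rebuild the contact graph, relax positions (overdamped mechanics) and
   cache per-cell pressures;
6. record the observable row.

Randomness is split into independent named streams (division axes, death
clocks, radiation outcomes, seeding, mesh jitter) derived from the master
seed, so trajectories are bit-reproducible and adding draws to one concern
does not perturb the others.  Checkpoints capture cells, fields, RNG
states and the config hash; resuming continues bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as srt_io
from .cells import (Cell, CellEvent, CellParameters, CellState, advance_cycle,
                    divide, radius_at_age)
from .config import ConfigError, SimulationConfig
from .fixtures import measure_dmax
from .mechanics import MechanicsParameters, build_neighbours, pressures, relax_positions
from .observables import ObservableSeries
from .radiotherapy import (RadiationParameters, TreatmentSchedule, irradiate)
from .transport import (Grid, TransportParameters, deposit_sinks,
                        effective_diffusivity, raw_density, sample,
                        solve_steady, update_boundary)

STREAMS = ("seeding", "division", "death", "radiation", "mesh")


class Simulation:
    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        self.grid = Grid(config.n_nodes, config.system_size_um)
        self.cell_params = CellParameters.from_config(config)
        self.mech_params = MechanicsParameters.from_config(config)
        self.transport_params = TransportParameters.from_config(config)
        self.rad_params = RadiationParameters.from_config(config)
        seq = np.random.SeedSequence(config.seed)
        self.rng = {name: np.random.Generator(np.random.PCG64(child))
                    for name, child in zip(STREAMS, seq.spawn(len(STREAMS)))}
        self.cells: list[Cell] = []
        self.time_h = 0.0
        self.next_id = 0
        self.d_max = measure_dmax(self.grid, cell_radius_um=config.r_final_um)
        shape = self.grid.shape
        self.fields = {
            "oxygen": np.full(shape, config.oxygen_boundary_mM),
            "glucose": np.full(shape, config.glucose_boundary_mM),
        }
        self.limited = {"oxygen": None, "glucose": None}
        self.realised_totals = {"oxygen": 0.0, "glucose": 0.0}
        self.observables = ObservableSeries(
            thresholds_mM=(config.hypoxia_threshold_mM,
                           config.anoxia_threshold_mM))
        self._pending: list = []
        self.delivery_log: list[dict] = []
        self.log: list[str] = []
        self._density_raw = np.zeros(shape)
        self._solve_info: dict[str, tuple[int, int]] = {}

    # ------------------------------------------------------------- seeding --
    def seed_cells(self) -> None:
        """Place the seeder cells near the centre, phases uniform over G1+S."""
        cfg = self.config
        rng = self.rng["seeding"]
        centre = np.full(3, cfg.system_size_um / 2.0)
        for _ in range(cfg.n_seeder_cells):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = cfg.seeder_ball_radius_um * rng.random() ** (1.0 / 3.0)
            age = rng.uniform(0.0, cfg.t_g1_h + cfg.t_s_h)
            state = CellState.G1 if age < cfg.t_g1_h else CellState.S
            cell = Cell(id=self.next_id, position=centre + r * u,
                        radius=radius_at_age(age, self.cell_params),
                        state=state, phase_age=age,
                        local_pO2=cfg.oxygen_boundary_mM,
                        local_glucose=cfg.glucose_boundary_mM)
            self.next_id += 1
            self.cells.append(cell)
        self._mechanics(relax_s=60.0)

    # ------------------------------------------------------------ one step --
    def _solve_fields(self) -> None:
        cfg = self.config
        self._density_raw = raw_density(self.cells, self.grid, cfg.r_final_um)
        fixed = update_boundary(self._density_raw)
        rho_norm = np.clip(self._density_raw / self.d_max, 0.0, 1.0)
        for name in ("oxygen", "glucose"):
            species = self.transport_params.species(name)
            D = effective_diffusivity(rho_norm, species,
                                      self.transport_params.orientation)
            Q = deposit_sinks(self.cells, self.grid, name, self.cell_params)
            res = solve_steady(D, Q, fixed, species.boundary_mM, self.grid,
                               tol=cfg.solver_tol, maxiter=cfg.solver_maxiter,
                               x0=self.fields[name], limited0=self.limited[name])
            self.fields[name] = res.C
            self.limited[name] = res.limited
            self._solve_info[name] = (res.passes, int(res.limited.sum()))
            self.realised_totals[name] = float(np.sum(res.realised_Q)
                                               * self.grid.node_volume)

    def _sample_fields(self) -> None:
        present = [c for c in self.cells if c.state is not CellState.DISSOLVED]
        if not present:
            return
        pos = np.array([c.position for c in present])
        po2 = sample(self.fields["oxygen"], pos, self.grid)
        glc = sample(self.fields["glucose"], pos, self.grid)
        for c, o, g in zip(present, po2, glc):
            c.local_pO2 = float(o)
            c.local_glucose = float(g)

    def _advance_cells(self) -> None:
        dt = self.config.biology_dt_h
        new_cells: list[Cell] = []
        removed: set[int] = set()
        for cell in list(self.cells):
            if cell.state is CellState.DISSOLVED:
                removed.add(cell.id)
                continue
            events = advance_cycle(cell, dt, self.cell_params, self.rng["death"])
            for ev in events:
                if ev is CellEvent.DIVIDE:
                    d1, d2 = divide(cell, self.rng["division"],
                                    params=self.cell_params,
                                    id_start=self.next_id)
                    self.next_id += 2
                    new_cells.extend([d1, d2])
                    removed.add(cell.id)
                elif ev is CellEvent.DISSOLVE:
                    removed.add(cell.id)
        self.cells = [c for c in self.cells if c.id not in removed] + new_cells

    def _mechanics(self, relax_s: float) -> None:
        if not any(c.state is not CellState.DISSOLVED and c.radius > 0
                   for c in self.cells):
            return
        graph = build_neighbours(self.cells, self.mech_params, self.rng["mesh"])
        if graph.n_edges:
            relax_positions(self.cells, graph, self.mech_params, relax_s)
            graph = build_neighbours(self.cells, self.mech_params,
                                     self.rng["mesh"])
        p = pressures(self.cells, graph, self.mech_params)
        for local, k in enumerate(graph.members):
            self.cells[k].pressure = float(p[local])
        lo, hi = 0.0, self.config.system_size_um
        for c in self.cells:
            if c.state is not CellState.DISSOLVED and (
                    np.any(c.position < lo) or np.any(c.position > hi)):
                raise RuntimeError(
                    f"cell {c.id} escaped the domain at {c.position} um; "
                    "the simulation cube is too small for this spheroid")

    def _deliver_due_doses(self) -> None:
        from .observables import fraction_below
        due = [e for e in self._pending if e.time_h <= self.time_h + 1e-9]
        for event in due:
            self.delivery_log.append({
                "time_h": self.time_h, "dose_gy": event.dose_gy,
                "o_max": event.o_max if event.o_max is not None
                else self.rad_params.o_max,
                "hypoxic_fraction_at_delivery": fraction_below(
                    self.cells, self.config.hypoxia_threshold_mM),
            })
            irradiate(self.cells, event.dose_gy, self.rad_params,
                      self.rng["radiation"], o_max_override=event.o_max)
            self._pending.remove(event)

    def step(self) -> dict:
        """One biology step; returns the recorded observable row."""
        self._solve_fields()
        self._sample_fields()
        self._deliver_due_doses()
        self._advance_cells()
        self._mechanics(relax_s=self.config.update_interval_min * 60.0)
        self.time_h += self.config.biology_dt_h
        n_live = sum(1 for c in self.cells if c.alive)
        solve = " ".join(
            f"{name}[passes={p} limited={m}]"
            for name, (p, m) in sorted(self._solve_info.items()))
        self.log.append(
            f"step={len(self.observables.rows) + 1} t={self.time_h:.3f}h "
            f"cells={len(self.cells)} live={n_live} {solve}")
        return self.observables.record(
            self.time_h, self.cells, self.fields["oxygen"],
            self._density_raw, self.grid,
            {k: v for k, v in self.realised_totals.items()})

    def run(self, duration_h: float,
            schedule: TreatmentSchedule | None = None) -> ObservableSeries:
        if schedule is not None:
            for e in schedule.events:
                if e.time_h < self.time_h - 1e-9:
                    raise ConfigError(
                        f"schedule time {e.time_h} h lies before current "
                        f"time {self.time_h} h")
                self._pending.append(e)
            self._pending.sort(key=lambda e: e.time_h)
        n_steps = int(round(duration_h / self.config.biology_dt_h))
        for _ in range(n_steps):
            self.step()
        return self.observables

    def run_schedule(self, schedule: TreatmentSchedule) -> ObservableSeries:
        """Continue the coupled simulation through a treatment schedule."""
        if not schedule.events:
            return self.observables
        horizon = schedule.events[-1].time_h + 24.0
        return self.run(horizon - self.time_h, schedule)

    # ---------------------------------------------------------- checkpoint --
    def save_checkpoint(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.config.save(d / "config.txt")
        srt_io.write_cells_csv(self.cells, d / "cells.csv", full=True)
        np.savez(d / "fields.npz",
                 oxygen=self.fields["oxygen"], glucose=self.fields["glucose"],
                 density=self._density_raw,
                 limited_oxygen=(self.limited["oxygen"]
                                 if self.limited["oxygen"] is not None
                                 else np.zeros(self.grid.shape, bool)),
                 limited_glucose=(self.limited["glucose"]
                                  if self.limited["glucose"] is not None
                                  else np.zeros(self.grid.shape, bool)))
        meta = {
            "time_h": self.time_h,
            "next_id": self.next_id,
            "d_max": self.d_max,
            "config_hash": self.config.digest(),
            "rng": {k: g.bit_generator.state for k, g in self.rng.items()},
            "pending": [[e.time_h, e.dose_gy, e.o_max] for e in self._pending],
            "delivery_log": self.delivery_log,
            "realised_totals": self.realised_totals,
        }
        (d / "meta.json").write_text(json.dumps(meta))
        self.observables.to_frame().to_csv(d / "observables.csv", index=False)

    @classmethod
    def load_checkpoint(cls, directory) -> "Simulation":
        from .radiotherapy import DoseEvent
        d = Path(directory)
        config = SimulationConfig.load(d / "config.txt")
        sim = cls(config)
        meta = json.loads((d / "meta.json").read_text())
        if meta["config_hash"] != config.digest():
            raise ConfigError("checkpoint config hash mismatch")
        sim.time_h = meta["time_h"]
        sim.next_id = meta["next_id"]
        sim.d_max = meta["d_max"]
        sim.realised_totals = meta["realised_totals"]
        for k, state in meta["rng"].items():
            sim.rng[k].bit_generator.state = state
        sim._pending = [DoseEvent(t, dose, o) for t, dose, o in meta["pending"]]
        sim.delivery_log = meta.get("delivery_log", [])
        sim.cells = srt_io.read_cells_csv(d / "cells.csv")
        data = np.load(d / "fields.npz")
        sim.fields = {"oxygen": data["oxygen"], "glucose": data["glucose"]}
        sim._density_raw = data["density"]
        sim.limited = {"oxygen": data["limited_oxygen"],
                       "glucose": data["limited_glucose"]}
        obs_path = d / "observables.csv"
        df = pd.read_csv(obs_path)
        sim.observables.rows = df.to_dict("records")
        return sim


# ------------------------------------------------------------- experiments --

def grow(config: SimulationConfig,
         duration_h: float | None = None) -> Simulation:
    """Grow a spheroid from the seeder cells for ``total_days`` (or
    ``duration_h`` if given)."""
    sim = Simulation(config)
    sim.seed_cells()
    sim.run(config.total_days * 24.0 if duration_h is None else duration_h)
    return sim


EXPERIMENTS = ("growth", "single_dose", "fractionated")


def run_experiment(name: str, config: SimulationConfig,
                   schedule: TreatmentSchedule | None = None,
                   outdir=None, follow_up_h: float = 24.0) -> dict:
    """Run a named experiment and write the output bundle.

    Returns the exit summary (onset times, post-dose timings, per-fraction
    hypoxic fractions at delivery).
    """
    if name not in EXPERIMENTS:
        raise ConfigError(f"unknown experiment {name!r}; choose from {EXPERIMENTS}")
    if name == "growth" and schedule is not None and schedule.events:
        raise ConfigError("growth experiment takes no schedule")
    if name in ("single_dose", "fractionated"):
        if schedule is None or not schedule.events:
            raise ConfigError(f"{name} experiment requires a schedule")
        if name == "single_dose" and len(schedule.events) != 1:
            raise ConfigError("single_dose experiment takes exactly one dose")
        if schedule.events[0].time_h > config.total_days * 24.0:
            raise ConfigError("first dose scheduled after the growth horizon")

    sim = Simulation(config)
    sim.seed_cells()
    if schedule is not None and schedule.events:
        sim.run(schedule.events[0].time_h)  # growth phase up to the first dose
        horizon = schedule.events[-1].time_h + follow_up_h
        sim.run(horizon - sim.time_h, schedule)
    else:
        sim.run(config.total_days * 24.0)

    summary = summarize(sim)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        config.save(out / "config.txt")
        sim.observables.save_csv(out / "observables.csv")
        srt_io.write_cells_csv(sim.cells, out / "census.csv")
        srt_io.write_vtk_points(sim.cells, out / "cells.vtk")
        srt_io.write_vtk_structured(sim.fields["oxygen"], sim.grid,
                                    out / "oxygen.vtk", "oxygen_mM")
        (out / "run.log").write_text("\n".join(sim.log) + "\n")
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def summarize(sim: Simulation) -> dict:
    cfg = sim.config
    obs = sim.observables
    hyp = f"frac_below_{cfg.hypoxia_threshold_mM:g}"
    anx = f"frac_below_{cfg.anoxia_threshold_mM:g}"
    def _clean(v):
        return None if isinstance(v, float) and np.isnan(v) else v

    summary = {
        "final_time_h": sim.time_h,
        "n_cells_final": len(sim.cells),
        "final_diameter_um": _clean(obs.rows[-1]["diameter_um"])
        if obs.rows else None,
        "first_hypoxic_h": _clean(obs.first_time(hyp, lambda v: v > 0)),
        "first_anoxic_h": _clean(obs.first_time(anx, lambda v: v > 0)),
        "first_necrotic_h": _clean(obs.first_time("n_necrotic",
                                                  lambda v: v > 0)),
    }
    if sim.delivery_log:
        summary["deliveries"] = sim.delivery_log
        cleared = [k for k, d in enumerate(sim.delivery_log)
                   if d["hypoxic_fraction_at_delivery"] == 0.0]
        summary["first_cleared_fraction_index"] = cleared[0] if cleared else None
        # re-depletion: time after the last dose at which the hypoxic
        # fraction first recovers to its at-delivery value
        last = sim.delivery_log[-1]
        t_last, f_last = last["time_h"], last["hypoxic_fraction_at_delivery"]
        recovered = float("nan")
        dipped = False
        for row in obs.rows:
            if row["time_h"] <= t_last:
                continue
            frac = row.get(hyp)
            if frac is None or (isinstance(frac, float) and np.isnan(frac)):
                continue
            if frac < f_last:
                dipped = True
            elif dipped:
                recovered = row["time_h"] - t_last
                break
        summary["redepletion_after_last_dose_h"] = _clean(recovered)
    return summary
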