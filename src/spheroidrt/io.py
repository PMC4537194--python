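"""Text export/import: cell census CSV and legacy-VTK snapshots."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .cells import Cell, CellState
from .transport import Grid

_BASE_COLUMNS = ["id", "x", "y", "z", "radius", "state", "phase_age",
                 "pressure", "pO2", "glucose"]
_FULL_COLUMNS = _BASE_COLUMNS + ["damaged", "death_clock", "death_duration",
                                 "radius_at_death", "arrest_timer"]


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_cells_csv(cells: list[Cell], path, full: bool = False) -> None:
    """Cell census as CSV; ``full=True`` adds the bookkeeping columns
    needed for loss-free checkpointing."""
    columns = _FULL_COLUMNS if full else _BASE_COLUMNS
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(columns)
        for c in cells:
            row = [c.id, _fmt(c.position[0]), _fmt(c.position[1]),
                   _fmt(c.position[2]), _fmt(c.radius), c.state.name,
                   _fmt(c.phase_age), _fmt(c.pressure), _fmt(c.local_pO2),
                   _fmt(c.local_glucose)]
            if full:
                row += [int(c.damaged), _fmt(c.death_clock),
                        _fmt(c.death_duration), _fmt(c.radius_at_death),
                        _fmt(c.arrest_timer)]
            w.writerow(row)


def read_cells_csv(path) -> list[Cell]:
    cells = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            cell = Cell(
                id=int(row["id"]),
                position=np.array([float(row["x"]), float(row["y"]),
                                   float(row["z"])]),
                radius=float(row["radius"]),
                state=CellState[row["state"]],
                phase_age=float(row["phase_age"]),
                pressure=float(row["pressure"]),
                local_pO2=float(row["pO2"]),
                local_glucose=float(row["glucose"]),
            )
            if "damaged" in row:
                cell.damaged = bool(int(row["damaged"]))
                cell.death_clock = float(row["death_clock"])
                cell.death_duration = float(row["death_duration"])
                cell.radius_at_death = float(row["radius_at_death"])
                cell.arrest_timer = float(row["arrest_timer"])
            cells.append(cell)
    return cells


def write_vtk_points(cells: list[Cell], path) -> None:
    """Cell centres with radius/state scalars as a legacy-VTK point cloud."""
    present = [c for c in cells if c.state is not CellState.DISSOLVED]
    lines = ["# vtk DataFile Version 3.0", "spheroidrt cells", "ASCII",
             "DATASET POLYDATA", f"POINTS {len(present)} float"]
    lines += [f"{c.position[0]:.6g} {c.position[1]:.6g} {c.position[2]:.6g}"
              for c in present]
    lines.append(f"POINT_DATA {len(present)}")
    lines.append("SCALARS radius float 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{c.radius:.6g}" for c in present]
    lines.append("SCALARS state int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(c.state.value) for c in present]
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_structured(field: np.ndarray, grid: Grid, path,
                         name: str = "value") -> None:
    """Scalar grid field as legacy-VTK structured points."""
    n = grid.n
    lines = ["# vtk DataFile Version 3.0", f"spheroidrt field {name}", "ASCII",
             "DATASET STRUCTURED_POINTS", f"DIMENSIONS {n} {n} {n}",
             "ORIGIN 0 0 0", f"SPACING {grid.h:.6g} {grid.h:.6g} {grid.h:.6g}",
             f"POINT_DATA {field.size}", f"SCALARS {name} float 1",
             "LOOKUP_TABLE default"]
    # VTK structured points iterate x fastest
    flat = np.transpose(field, (2, 1, 0)).ravel()
    lines += [f"{v:.6g}" for v in flat]
    Path(path).write_text("\n".join(lines) + "\n")


def write_field_csv(field: np.ndarray, path) -> None:
    """Flat (i, j, k, value) CSV of a scalar grid field."""
    n = field.shape[0]
    idx = np.indices(field.shape).reshape(3, -1)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["i", "j", "k", "value"])
        for i, j, k, v in zip(*idx, field.ravel()):
            w.writerow([i, j, k, f"{v:.10g}"])
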