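"""Measurement layer: oxygenation fractions, profiles, integral oxygen.

All observables operate on plain cell lists and concentration grids, so
they can be applied to live simulations, checkpoints or constructed
fixtures alike.  ``integral_oxygen`` is the tumour-masked Riemann sum of
the oxygen field, the model counterpart of an integral PET-type tracer
signal; ``fraction_below`` implements the thresholded oxygenation census
(live cells = cycling + quiescent + arrested).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cells import Cell, CellState, LIVE_STATES
from .transport import Grid, sample


def live_cells(cells: list[Cell]) -> list[Cell]:
    return [c for c in cells if c.state in LIVE_STATES]


def fraction_below(cells: list[Cell], threshold_mM: float) -> float:
    """Fraction of live cells whose local pO2 is below the threshold.

    Returns NaN when there are no live cells.
    """
    live = live_cells(cells)
    if not live:
        return float("nan")
    n_below = sum(1 for c in live if c.local_pO2 < threshold_mM)
    return n_below / len(live)


def radial_profile(C: np.ndarray, grid: Grid, centre: np.ndarray,
                   n_bins: int = 25, r_max_um: float = 500.0):
    """Mean concentration in equal-width radial bins around ``centre``.

    Bins are averaged over the grid nodes falling inside each shell
    (deterministic quadrature); empty bins are NaN.  Returns
    (bin_centres_um, bin_means).
    """
    centre = np.asarray(centre, dtype=float)
    r = grid.radius_field(centre)
    edges = np.linspace(0.0, r_max_um, n_bins + 1)
    which = np.digitize(r.ravel(), edges) - 1
    means = np.full(n_bins, np.nan)
    flat = C.ravel()
    for b in range(n_bins):
        m = which == b
        if m.any():
            means[b] = flat[m].mean()
    return 0.5 * (edges[:-1] + edges[1:]), means


def integral_oxygen(C: np.ndarray, density_raw: np.ndarray, grid: Grid) -> float:
    """Integral oxygen P(t) = sum over tumour nodes of C * node volume.

    Units: mM * um^3 = amol.  The tumour mask is density > 0.
    """
    mask = density_raw > 0
    return float(np.sum(C[mask]) * grid.node_volume)


def spheroid_diameter(cells: list[Cell]) -> float:
    """Robust diameter estimate from non-dissolved cell positions (um).

    2 x (95th percentile of centre-to-centroid distances + mean radius);
    the percentile makes the estimate insensitive to straggler cells.
    """
    present = [c for c in cells if c.state is not CellState.DISSOLVED]
    if not present:
        return float("nan")
    pos = np.array([c.position for c in present])
    radii = np.array([c.radius for c in present])
    if len(present) == 1:
        return 2.0 * radii[0]
    centroid = pos.mean(axis=0)
    dist = np.linalg.norm(pos - centroid, axis=1)
    return 2.0 * (np.percentile(dist, 95) + radii.mean())


def census(cells: list[Cell]) -> dict[str, int]:
    counts = {state.name: 0 for state in CellState}
    for c in cells:
        counts[c.state.name] += 1
    return counts


@dataclass
class ObservableSeries:
    """Time-indexed record of the simulation observables."""
    thresholds_mM: tuple[float, ...] = (0.014, 0.001)
    rows: list[dict] = field(default_factory=list)

    def record(self, time_h: float, cells: list[Cell], C_oxygen: np.ndarray,
               density_raw: np.ndarray, grid: Grid,
               realised_totals: dict[str, float] | None = None) -> dict:
        centre = np.full(3, grid.size_um / 2.0)
        row: dict = {"time_h": time_h}
        row.update({f"n_{k.lower()}": v for k, v in census(cells).items()})
        row["n_live"] = sum(1 for c in cells if c.state in LIVE_STATES)
        for t in self.thresholds_mM:
            row[f"frac_below_{t:g}"] = fraction_below(cells, t)
        row["diameter_um"] = spheroid_diameter(cells)
        row["central_pO2_mM"] = float(sample(C_oxygen, centre, grid)[0])
        row["integral_oxygen_amol"] = integral_oxygen(C_oxygen, density_raw, grid)
        if realised_totals:
            for name, val in realised_totals.items():
                row[f"consumed_{name}_amol_s"] = val
        self.rows.append(row)
        return row

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def first_time(self, column: str, predicate) -> float:
        """First time_h at which ``predicate(value)`` is true (NaN if never)."""
        for row in self.rows:
            v = row.get(column)
            if v is not None and not (isinstance(v, float) and np.isnan(v)) \
                    and predicate(v):
                return row["time_h"]
        return float("nan")
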