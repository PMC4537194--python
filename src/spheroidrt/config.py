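"""Simulation configuration.

All model parameters live in a single flat :class:`SimulationConfig`.  The
defaults are the reference parameter set of the model (EMT6/V79-type generic
cancer cell): boundary concentrations of capillary blood, measured diffusion
coefficients for water and tumour tissue, zero-order consumption rates,
cell-cycle radii, the quiescence pressure threshold, and the radiation
response constants (phase-wise LQ coefficients, OER parameters, acute-death
and mitotic-mismatch probabilities).

Configs round-trip losslessly through a flat, commented ``key = value`` text
dialect (:func:`SimulationConfig.save` / :func:`SimulationConfig.load`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path


class ConfigError(ValueError):
    """Raised for physically inconsistent or malformed configuration."""


@dataclass
class SimulationConfig:
    # --- domain / grid -----------------------------------------------------
    n_nodes: int = 71                 # diffusion nodes per dimension
    system_size_um: float = 1000.0    # cubic lattice edge length

    # --- transport ---------------------------------------------------------
    glucose_boundary_mM: float = 5.0
    oxygen_boundary_mM: float = 0.13
    update_interval_min: float = 10.0  # biology/diffusion update cadence
    d_h2o_glucose: float = 690.0       # um^2/s
    d_tis_glucose: float = 105.0
    d_h2o_oxygen: float = 3300.0
    d_tis_oxygen: float = 1750.0
    diffusivity_orientation: str = "narrative"  # or "printed"
    solver_tol: float = 1e-8
    solver_maxiter: int = 20000

    # --- cell cycle / geometry ---------------------------------------------
    r_init_um: float = 7.94           # radius at start of G1
    r_final_um: float = 10.0          # radius at end of G2
    t_g1_h: float = 8.0
    t_s_h: float = 8.0
    t_g2_h: float = 3.0
    t_m_h: float = 1.0

    # --- death / environment thresholds ------------------------------------
    tau_necrosis_h: float = 24.0      # mean necrotic dissolution time
    tau_apoptosis_h: float = 12.0     # mean apoptotic dissolution time
    starvation_glucose_mM: float = 0.0
    p_crit_pa: float = 200.0          # quiescence critical pressure
    hypoxia_threshold_mM: float = 0.014
    anoxia_threshold_mM: float = 0.001

    # --- zero-order consumption (amol / cell / s) ---------------------------
    glucose_active_amol_s: float = 180.0
    glucose_quiescent_amol_s: float = 130.0
    oxygen_active_amol_s: float = 83.0
    oxygen_quiescent_amol_s: float = 49.0

    # --- radiation ----------------------------------------------------------
    alpha_g1: float = 0.351           # Gy^-1
    beta_g1: float = 0.04             # Gy^-2
    alpha_s: float = 0.1235
    beta_s: float = 0.0285
    alpha_g2m: float = 0.793
    beta_g2m: float = 0.0
    qrf: float = 1.5                  # quiescence resistance factor
    o_max: float = 2.9                # maximum oxygen enhancement
    oer_h_mM: float = 0.0052          # OER half-effect concentration
    ac: float = 0.66                  # acute death chance
    mm: float = 0.3                   # mitotic mismatch rate

    # --- mechanics ----------------------------------------------------------
    youngs_modulus_pa: float = 1000.0
    poisson_ratio: float = 0.4
    adhesion_j_m2: float = 1e-3
    friction_ns_m: float = 1.0
    contact_cutoff_factor: float = 1.05
    mech_max_disp_um: float = 0.1     # displacement cap per mechanics substep
    mech_force_tol_n: float = 1e-11   # early-exit net-force tolerance

    # --- run control ---------------------------------------------------------
    n_seeder_cells: int = 10
    seeder_ball_radius_um: float = 30.0
    total_days: float = 14.0
    seed: int = 0
    output_cadence_steps: int = 6     # observable row every step; snapshots every N
    output_dir: str = "out"

    # --- unit conversions ----------------------------------------------------
    mM_per_mmHg: float = 0.0013       # 100 mmHg == 0.13 mM arterial pO2

    # ------------------------------------------------------------------ api --
    @property
    def cycle_time_h(self) -> float:
        return self.t_g1_h + self.t_s_h + self.t_g2_h + self.t_m_h

    @property
    def biology_dt_h(self) -> float:
        return self.update_interval_min / 60.0

    def validate(self) -> None:
        """Reject physically inconsistent settings with a named error."""
        if self.d_h2o_glucose <= self.d_tis_glucose:
            raise ConfigError("glucose D_H2O must exceed D_Tis")
        if self.d_h2o_oxygen <= self.d_tis_oxygen:
            raise ConfigError("oxygen D_H2O must exceed D_Tis")
        if min(self.d_tis_glucose, self.d_tis_oxygen) <= 0:
            raise ConfigError("tissue diffusion coefficients must be positive")
        if min(self.glucose_boundary_mM, self.oxygen_boundary_mM) <= 0:
            raise ConfigError("boundary concentrations must be positive")
        if not (0 < self.r_init_um < self.r_final_um):
            raise ConfigError("need 0 < r_init < r_final")
        for name in ("t_g1_h", "t_s_h", "t_g2_h", "t_m_h", "tau_necrosis_h",
                     "tau_apoptosis_h", "glucose_active_amol_s",
                     "glucose_quiescent_amol_s", "oxygen_active_amol_s",
                     "oxygen_quiescent_amol_s", "update_interval_min"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.glucose_quiescent_amol_s >= self.glucose_active_amol_s:
            raise ConfigError("quiescent glucose consumption must be < active")
        if self.oxygen_quiescent_amol_s >= self.oxygen_active_amol_s:
            raise ConfigError("quiescent oxygen consumption must be < active")
        for name in ("alpha_g1", "beta_g1", "alpha_s", "beta_s", "alpha_g2m",
                     "beta_g2m"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.qrf < 1 or self.o_max < 1:
            raise ConfigError("QRF and O_max must be >= 1")
        if not (0 <= self.ac <= 1 and 0 <= self.mm <= 1):
            raise ConfigError("AC and MM are probabilities")
        if self.youngs_modulus_pa <= 0 or not (0 <= self.poisson_ratio < 0.5):
            raise ConfigError("need E > 0 and 0 <= nu < 0.5")
        if self.adhesion_j_m2 < 0 or self.friction_ns_m <= 0:
            raise ConfigError("need gamma >= 0 and eta > 0")
        if self.diffusivity_orientation not in ("narrative", "printed"):
            raise ConfigError("diffusivity_orientation: 'narrative' or 'printed'")
        if self.n_nodes < 3:
            raise ConfigError("need at least 3 diffusion nodes per dimension")

    # ----------------------------------------------------------- file format --
    def save(self, path: str | Path) -> None:
        lines = ["# spheroidrt configuration (flat key = value)"]
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ConfigError(f"line {lineno}: unknown key {key!r}")
            typ = known[key].type
            if typ in ("int", int):
                kwargs[key] = int(value)
            elif typ in ("float", float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value.strip("'\"")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the full parameter set (used by checkpoints)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def scaled_down_config(**overrides) -> SimulationConfig:
    """Reduced problem size for fast property tests and examples.

    500 um cube on a 36^3 grid with a 5 h cycle; transport, consumption and
    radiation parameters keep their reference values, so nutrient penetration
    depths (and hence the hypoxia/anoxia/necrosis layering) are unchanged —
    only the spheroid needs fewer divisions to reach them.
    """
    cfg = SimulationConfig(
        n_nodes=36, system_size_um=500.0,
        t_g1_h=2.0, t_s_h=2.0, t_g2_h=0.75, t_m_h=0.25,
        total_days=2.5,
    )
    return cfg.replace(**overrides) if overrides else cfg
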