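"""Spheroid growth and the rise of hypoxia (scaled-down profile).

Grows a spheroid from 10 seeder cells on the fast test profile (500 um
cube, 36^3 nodes, 5 h cycle) until necrosis begins, then prints the onset
times of the hypoxic population, central anoxia and necrosis.  Expect the
canonical ordering: hypoxia first, anoxia next (cells tolerate it),
necrosis last when the deeper-reaching glucose is finally exhausted.
Takes a couple of minutes on one CPU.
"""

from spheroidrt import Simulation, scaled_down_config
from spheroidrt.runner import summarize

cfg = scaled_down_config(seed=1)
sim = Simulation(cfg)
sim.seed_cells()
while sim.time_h < 60.0:
    row = sim.step()
    if len(sim.observables.rows) % 60 == 0:
        print(f"  t = {row['time_h']:5.1f} h   live cells {row['n_live']:6d}  "
              f"diameter {row['diameter_um']:5.0f} um   "
              f"hypoxic fraction {row['frac_below_0.014']:.3f}")
    if row["n_necrotic"] >= 20:
        break

s = summarize(sim)
print(f"\nfirst hypoxic cell : {s['first_hypoxic_h']:.1f} h")
print(f"first anoxic cell  : {s['first_anoxic_h']:.1f} h")
print(f"first necrosis     : {s['first_necrotic_h']:.1f} h")
print(f"final diameter     : {s['final_diameter_um']:.0f} um, "
      f"{s['n_cells_final']} cells")
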