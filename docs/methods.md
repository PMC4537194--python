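# Model and methods

`spheroidrt` simulates an avascular tumour spheroid — the standard in
vitro proxy for the inter-capillary micro-regions of vascularised tumours
— as an off-lattice, centre-based cell population coupled to a
reaction-diffusion description of oxygen and glucose, with a radiotherapy
module acting through phase-dependent linear-quadratic (LQ) survival.
This note records the model equations, the parameter choices and their
rationale, the numerical methods, and the known limitations.

## Cells and cycle regulation

Each cell is a sphere with a position, radius and a cycle state
(G1 → S → G2 → M, plus quiescent, arrested, apoptotic, necrotic and
dissolved compartments).  Volume grows linearly in time over the cycle
from the initial radius 7.94 μm (start of G1) to 10 μm (end of G2/M), so
one unperturbed cycle doubles the volume; division replaces the mother by
two daughters of initial radius placed symmetrically along a uniformly
random axis at one-initial-radius centre separation, leaving overlap for
the mechanics to resolve.

Phase durations default to G1 = 8 h, S = 8 h, G2 = 3 h, M = 1 h (a ~20 h
generic cancer-cell cycle); they are configuration values, not code
constants.  The scaled-down test profile shortens them proportionally
(5 h cycle) so desk-scale runs need fewer divisions to reach the
diffusion-limited regime.

Environmental regulation:

* **Quiescence.** At the G1/S checkpoint a cell whose mechanical pressure
  exceeds `P_crit` = 200 Pa enters a reversible quiescent state; it
  re-enters the cycle (into S) as soon as the pressure falls to
  sub-critical values.  The comparison is strict (`> P_crit` enters,
  `≤ P_crit` releases).
* **Starvation necrosis.** Local glucose at or below the starvation level
  (default 0 mM) triggers necrosis in any live state.  Because the
  transport solver pins fully depleted nodes to exactly zero, the
  equality test fires precisely where the tissue has consumed all supply.
* **Anoxia tolerance.** Oxygen never kills: anoxic cells survive
  indefinitely as long as glucose lasts.  This produces the viable anoxic
  layer between the hypoxic rim and the necrotic core.
* **Death and dissolution.** Necrotic and apoptotic cells persist for an
  exponentially distributed time (means τ_n = 24 h, τ_A = 12 h), during
  which the radius shrinks linearly to zero so the local density — and
  with it the diffusivity — recovers gradually; at the end of the clock
  the cell dissolves and is removed.

Consumption is zero-order (independent of local concentration): 83/49
amol cell⁻¹ s⁻¹ oxygen and 180/130 amol cell⁻¹ s⁻¹ glucose for
active/quiescent cells.  Arrested (radiation-damaged, non-cycling) cells
consume at the quiescent rates; dead cells consume nothing.

## Mechanics

Neighbourhood is the 3D Delaunay triangulation of cell centres, pruned to
centre distances within `contact_cutoff_factor` (1.05) times the radius
sum; small or degenerate configurations fall back to all-pairs contacts.
The pairwise force is the Johnson–Kendall–Roberts (JKR) adhesive elastic
contact.  With effective modulus E* = E/(2(1−ν²)) and reduced radius
R* = r_i r_j/(r_i + r_j), the equilibrium JKR branch is parameterised by
the neck radius a:

    δ(a) = a²/R* − √(2πγa/E*),
    F(a) = (4/3)(E*/R*)a³ − √(8πγE*a³),

solved per contact by a scaled Newton iteration (the problem collapses to
the universal curve â² − √â = δ̂).  The law reduces to Hertz repulsion for
γ = 0, has the classical pull-off force −(3/2)πγR*, and is zero beyond
the fixed-grips detachment displacement.  Under displacement control true
JKR has a finite jump −(5/6)πγR* → 0 at detachment; we keep the faithful
branch rather than smoothing it, since the jump is ~10⁻⁹ N at cell scale
and has no observable effect on relaxation.

Per-cell pressure is the sum of *repulsive* contact forces divided by the
cell surface area 4πr² (adhesive tension is not pressure); this is the
quantity compared against `P_crit`.  Positions follow overdamped dynamics
ẋ = F/η, integrated explicitly with substeps capped at 0.1 μm
displacement and an early exit once the largest net force is below
tolerance; mechanics is relaxed for the duration of each biology step
(quasi-static between biology updates).

Parameter choices (defaults; all configurable): E = 1 kPa, ν = 0.4,
γ = 10⁻³ J m⁻², η = 1.0 N s m⁻¹.  The adhesion energy is the one genuinely
calibrated value: with an order of magnitude less adhesion the aggregate
relaxes to a barely-touching packing whose oxygen consumption density is
so low that the diffusion range exceeds the whole domain and no hypoxic
core can form — contradicting the compact-spheroid regime the model is
meant to describe.  At γ = 10⁻³ J m⁻² the adhesive equilibrium overlap
(~4–5 μm for full-grown cells) packs tissue at the density of the
compressed-mass calibration fixture, and growth then reproduces the
hypoxia → anoxia → necrosis layering inside a 500 μm domain.  η is set so
an overlapping daughter pair relaxes in ~5–10 simulated minutes,
i.e. within a biology step.  These values put close-packing pressures on
the 10² Pa scale, making the 200 Pa quiescence threshold meaningful; the
test suite asserts this calibration.

## Nutrient transport

Oxygen and glucose fields live on a cubic nodal grid (71 nodes per
dimension over 1 mm in the reference profile) and obey

    ∂C/∂t = ∇·(D(x,t) ∇C) − Q(x,t),

with zero-order sinks Q deposited from the cells by trilinear weights
(deposition conserves total demand exactly) and a density-dependent
diffusion coefficient interpolating linearly between the water and tissue
values,

    D = D_H2O − (D_H2O − D_Tis) · ρ/d_max,

so cell-free space diffuses like water and densely packed tissue like
tumour tissue.  (The opposite endpoint orientation is retained behind the
config switch `diffusivity_orientation = printed` for replication
studies, but the default follows the physics: dissolution of dead cells
*increases* the local diffusivity.)  The normalising density `d_max` is
measured at startup from a generated maximally compressed FCC ball — the
"compressed cell mass" — rather than hard-coded, and cached.

The blood boundary is adaptive: zero-density nodes 6-connected to the
domain faces hold the arterial concentrations (5 mM glucose, 0.13 mM
oxygen) as Dirichlet values; zero-density pockets enclosed by tissue
(e.g. a dissolved necrotic core) are ordinary interior nodes.  Face
diffusivities use harmonic means (flux continuity across coefficient
jumps); the operator is the standard 7-point heterogeneous-coefficient
stencil.

By default the fields are re-solved to **pseudo-steady state** every
biology step (10 min cadence), justified by the seconds-scale relaxation
of the diffusion fields relative to the biology; the linear systems are
solved by diagonal-preconditioned BiCGStab to relative residual 10⁻⁸,
warm-started from the previous step.  A Crank–Nicolson transient stepper
with adaptive sub-stepping (≤5% relative change per substep) is kept for
validation; in reflective, sink-free configurations it conserves mass to
solver tolerance.

**Sink limiting.** Zero-order sinks are unphysical where C → 0, and the
model must decide what happens there (demand persists — cells are
anoxia-tolerant).  We solve the obstacle problem with an active set:
fully depleted nodes are pinned to C = 0, their *realised* consumption is
the diffusive inflow (never more than requested), and nodes are released
when supply exceeds demand again.  This guarantees C ≥ 0, a discrete
maximum principle (C never exceeds the boundary concentration), and exact
bookkeeping of realised versus requested consumption.  Starvation is then
detected downstream via sampled C = 0.

Concentrations at cell positions are read by trilinear interpolation
(exact for linear fields; reproduces nodal values at nodes).

## Radiation response

A dose D is translated into per-cell survival by the LQ model
S_p = exp(−(α_p D_eff + β_p D_eff²)) with phase-group coefficients
(V79 x-ray values): α = 0.351/0.1235/0.793 Gy⁻¹ and
β = 0.04/0.0285/0 Gy⁻² for G1 / S / M-G2.  Quiescent cells use the G1
pair; arrested cells, held at the G2/M checkpoint, use the M/G2 pair.

The effective dose combines two modifiers:

* **Oxygen enhancement**: OER(pO₂) = (O_max·pO₂ + H)/(pO₂ + H) with
  O_max = 2.9 and half-effect H = 0.0052 mM (Alper–Howard-Flanders form,
  cycle-independent).  The dose-modification convention is
  D_eff = D · OER(pO₂)/O_max: fully oxic cells receive the nominal dose,
  anoxic cells D/O_max.  Setting O_max = 1 removes all oxygen dependence
  (hypoxic-sensitizer limit).
* **Quiescence resistance**: a further division by QRF = 1.5 for
  quiescent cells, compounding multiplicatively with the oxygen factor.

Cells failing the survival roll die **acutely** with probability
AC = 0.66 (apoptotic pathway, τ_A clock) or carry **delayed** damage:
they cycle on, arrest at the first G2/M checkpoint, never complete a
division, and at each subsequent mitotic attempt (one M-duration apart)
die with probability MM = 0.3.  Mitotic death routes into the fast
(apoptotic-clock) dissolution pathway; the specific post-catastrophe
death mode is a modelling choice.  pO₂ for survival is sampled at the
cell centre from a field solved immediately before delivery.

Treatment schedules are ordered (time, dose, optional O_max override)
events; delivery happens inside the coupled loop at the first biology
step whose start time reaches the event time.

## Observables

* Thresholded oxygenation census: fraction of live cells (cycling +
  quiescent + arrested) with pO₂ below a threshold; defaults report the
  radiobiological hypoxia threshold 0.014 mM (≈10 mmHg at the
  0.0013 mM/mmHg conversion) and an operational anoxia threshold of
  0.001 mM (the literature does not pin a number to "anoxic"; ours is a
  documented convention).
* Radial concentration profiles (equal-width shells, node-quadrature bin
  means) and the central concentration.
* Integral oxygen P(t) = Σ_tumour C · ΔV (tumour mask: nodes with
  positive cell density) — the model counterpart of an integral PET-type
  tracer signal, in amol.
* Spheroid diameter: 2 × (95th percentile of centre-to-centroid
  distances + mean cell radius).  The percentile makes the estimate
  robust to straggler cells; this convention defines what "diameter"
  means everywhere in the package.

## Simulation loop and reproducibility

Per biology step (default 10 min): deposit density and sinks → adapt the
boundary → pseudo-steady solve per species → sample fields to cells →
deliver due doses → advance every cell's state machine (divisions,
quiescence, deaths) → rebuild contacts, relax mechanics, cache pressures
→ record observables.  Randomness is split into independent named streams
(seeding, division axes, death clocks, radiation outcomes, mesh jitter)
spawned from the master seed, so trajectories are bit-reproducible and
adding draws to one concern does not disturb the others.  Checkpoints
store cells, fields, active sets, RNG states and the config hash; a
resumed run continues bit-identically, which the test suite verifies.

Seeding places 10 cells uniformly in a 30 μm ball at the domain centre
with phase ages uniform over G1 ∪ S.

## Problem sizes and what the tests show

The test suite runs entirely at desk scale: unit and property tests on
constructed fixtures, the transport solver against the closed-form
uniformly-consuming-sphere solution (error < 2% at 71³, monotonically
decreasing under refinement from 21³), Monte-Carlo irradiation of 10⁵
cells against binomial oracles, and one scaled-down coupled run (500 μm
cube, 36³ nodes, 5 h cycle, ~13 000 cells, a few CPU-minutes) on which
the emergent signatures are asserted: hypoxia before anoxia before
necrosis, the transient post-dose rise of the hypoxic survivor fraction,
full reoxygenation after 4 Gy, and the rise-then-fall of P(t).

Full-scale replication experiments (1 mm cube, 71³ nodes, 20 h cycle,
14 days of growth to ~700 μm, single-dose and fractionated schedules with
O_max ∈ {2.9, 1}) are multi-hour jobs provided in
`scripts/nightly_replications.py`; they are not part of the default test
run, and the phase-duration defaults quoted above should be re-checked
against the day-14 diameter when those jobs are run.

What passing the desk-scale tests does *not* show: quantitative onset
*times* at full scale (the scaled profile compresses them by design), any
in vivo effect involving perfusion or acute hypoxia (no vasculature is
modelled), and cell-line-specific accuracy beyond the generic EMT6/V79
parameter set.

## Known limitations

* Contact geometry is spherical-cap, not a full Voronoi tessellation;
  pressures are therefore approximate at high polydispersity.
* The JKR force has the (physical, but under displacement control
  abrupt) detachment jump noted above.
* Zero-order consumption plus sink limiting concentrates all
  concentration-dependence of metabolism into the C = 0 boundary; there
  is no Michaelis–Menten roll-off.
* No sublethal-damage repair between fractions, no LET dependence, no
  cell migration, no lactate/pH coupling.
* The diameter and anoxia conventions above are package definitions;
  comparisons with other sources must use the same conventions.
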