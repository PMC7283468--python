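# Methods

`mechamigr` simulates a single polarized, deformable 3D cell migrating on a
flat elastic-ligand substrate with a discrete-element method: the cell
cortex is a closed triangulated shell whose nodes move in overdamped
(inertia-free) dynamics, and all biology — protrusion, adhesion,
contraction, mechanosensing — enters as forces on those nodes.

## Model summary

**Cortex.** The cortex is an icosphere (default radius 8 µm). Edges are
Kelvin–Voigt elements: a linear spring `F = k_cortex (d − d*)` about the
built edge length plus a dashpot that enters the friction operator. Shape
is maintained by four standard discrete-membrane energies whose analytic
gradients supply the forces:

- local area: `Σ_t (k_area_loc/2)(A − A_ref)²/A_ref`
- global area: `(k_area_glob/2)(A_tot − A_ref,tot)²/A_ref,tot`
- volume: `(k_vol/2)(V − V_ref)²/V_ref`
- bending: `k_bend Σ_hinges (1 − cos(θ − θ_ref))`, θ_ref from the built
  sphere (spontaneous curvature of the rest shape, so a free cell relaxes
  toward the rounded state).

All gradients are verified against central finite differences in the test
suite (≤ 1e-5 relative).

**Substrate.** A rigid plane at z = 0 tiled by right isosceles triangles of
area 2.102 µm², used to accumulate traction. Substrate stiffness is *not*
a property of the plane: it enters through the ligand spring of each focal
adhesion.

**Transient contact.** Cortex triangles interact with the plane through an
adhesive Maugis–Dugdale-type contact: a repulsive Hertzian core using the
sphere fit to each triangle's 1-ring (substrate side flat, i.e. infinite
radius; cell-side radius capped at `R_contact_max` for flat patches), plus
a constant-stress (Dugdale) adhesive annulus of stress `sigma0_contact`
acting where the undeformed gap profile is below `h_contact`. The annulus
area is capped at the triangle's own area, and the adhesive ramp is
evaluated on the undeformed profile — a DMT-regime simplification of the
fully self-consistent Maugis solution that keeps the exact Hertz limit at
zero adhesion energy (tested against the closed form to 1e-6). A linear
node–plane penalty (`k_wall`) supplements the triangle-level core so that
individual nodes stay within ~1 nm of the plane; without it, contact-line
nodes sink tens of nm between triangle centroids and would spuriously
pre-tension the nanometre-scale adhesion springs.

**Actin field and regions.** A globular-actin surface concentration G
(molecules/m²) evolves on the triangles by
`∂G/∂t = k_gen·1[source] − k_deg·G + D_actin ∇²G` with a finite-volume
Laplacian over triangle adjacency (explicit Euler, sub-cycled when the step
exceeds the diffusive stability bound; at the default parameters the bound
is far above dt). Sources are the boundary ring of the cell–substrate
interface, so G peaks at the spread cell's edge and decays inward and over
the top with length `sqrt(D_actin/k_deg) ≈ 2.2 µm`. Thresholds on G,
expressed as fractions of the source steady state `G* = k_gen/k_deg`,
demarcate the lamellipodium (`theta_Lp`) and lamella (`theta_Lm`); the
front/rear split is by triangle centroid x relative to the interface centre
of mass (ties to the front), and the lamellipodium is restricted to the
leading front. During initialization the field is set directly to its exact
steady state by a sparse linear solve — the fixed point the explicit
integrator relaxes to.

**Protrusion.** Each lamellipodium triangle receives
`F = k_prot · G · ∇G/|∇G|` projected on the substrate-tangent plane
(zero where the gradient is degenerate), and every cortex node receives
`−(1/n_node) Σ F_prot` so that protrusion and counter force cancel exactly
over the cell — net motion can only arise through substrate-coupled terms.

**Focal adhesions.** Any lamellum node within 0.075 µm of the plane forms
an FA at rate `r_on_FA` (per-step probability `1 − exp(−r_on dt)`), one FA
per node, anchored at the instantaneous closest plane point; the anchor
never moves. The bond is two springs in series (stiff FA spring `k_FA`,
soft ligand spring `k_ECM`), carrying tension
`(1/k_FA + 1/k_ECM)⁻¹ (L − L₀)` when stretched and nothing in compression.
Since `k_FA ≫ k_ECM` the response is set by the ligand. Disassembly is a
catch-like Poisson process `r = β r_off0 exp(−ζ|F|)` (β = 1 front, 2 rear;
the exponential only with FA maturation ON; ×10 for FAs that left the
lamella), and any FA whose force strictly exceeds `F_rup = 7.7 nN` ruptures,
leaving its node refractory for 30 min. The expected zero-force lifetime
`⟨λ⟩ = −1/ln(1 − r)` (seconds → reported minutes) reproduces the study's
lifetime table.

**Stress fibers.** Unbound FAs pair stochastically into fibers (each
unbound FA attempts at `sf_pair_rate`; partners must be ≥ 8 µm apart, which
on a spread cell ~16 µm across means front↔rear pairs). A fiber pulls its
two cortex nodes together with `n_str · F_am · φ(ΔL)`: `φ` is a logistic
weakening factor halved at a shortening of `dL50 = 3.5 µm`, and `n_str`
steps 1 → 5 each time the fiber stalls — its 10 s moving-average length
changing by less than `L_thr` between consecutive comparisons (first
comparison 20 s after formation). With strengthening OFF stalls are
detected but the force stays at `F_am`. A fiber stays bound to its *nodes*
while at least one of the two FAs it formed between survives; because a
later FA at the same node is a new bond that can seed a new fiber, forces
from successive fibers stack on a node — this stacking, plus membrane
transmission of force from released neighbors, is what pushes individual
adhesions past the rupture threshold on stiff substrates and triggers the
collective cascade.

**Full (collective) retraction.** When ≥ `n_thr = 15` ruptures fall within
a trailing 60 s window, all FAs are removed, orphaned fibers deleted, and
every lamellum node set refractory; the rupture window resets so one
cascade counts once.

**Equation of motion.** Each step solves `M v = F` and advances positions
by `v·dt` with `dt = 0.05 s`. `M` sums the cortex dashpots (`Lambda_d` in
graph-Laplacian structure over mesh edges), substrate contact friction
(`Gamma_subs` on nodes in contact or holding an FA), and liquid drag
(`Gamma_liquid`). Friction is isotropic per node/pair, so the 3N×3N system
decouples into one N×N symmetric positive-definite solve (dense Cholesky at
the mesh sizes used) applied to three right-hand sides. Forces are explicit,
friction implicit; the scheme is verified against the closed-form
Kelvin–Voigt relaxation to 1% and refuses steps that move a node more than
0.5 µm (instability guard).

**Initialization.** The cell is placed just above the plane and advanced
with contact + cortex forces only (no FAs, fibers, protrusion, or
mechanosensing; no randomness) until the interface area changes by less
than 1% per minute (checked each simulated minute after a 5-minute floor),
capped at `init_duration`. The actin steady state and region labels are then
computed, the clock reset, and the procedure is identical for every
condition — two runs with the same seed are bitwise identical.

## Parameters

Core model parameters (cell radius, cortex spring and damping, actin rates,
adhesion kinetics and rupture force, fiber forces and thresholds, the
polarity factors, dt) carry the published values and are listed with units
in `mechamigr.params.ParamSet`. Interpretation choices for three entries
whose printed units are inconsistent: the actin diffusivity is read as
`8e-14 m²/s`, and the fiber-weakening pair as `mu = 5e6 1/m`,
`dL50 = 3.5e-6 m` — the SI readings consistent with force persisting to
strains of roughly −0.25…−0.4 on ≥ 8 µm fibers. All three remain
configurable.

Extension parameters not fixed by the core description were set once by the
calibration procedures below and are all exposed in the config:

| parameter | default | calibration target |
|---|---|---|
| `k_area_loc` | 2e-2 N/m | in-plane stiffness: membrane transmits ~nN forces at sub-µm relative node displacements (load redistribution during rupture cascades) |
| `k_area_glob` | 5e-4 N/m | global area bounded during spreading |
| `k_vol` | 4e3 Pa | volume within ±5% after spreading, ±10% during migration |
| `k_bend` | 3e-18 J | rounded rest shape; thin-front/thick-rear under load |
| `E_contact` | 1e8 Pa | contact gap ≪ the 15 nm rupture stretch of the stiffest ligand, so fresh FAs carry ~no force |
| `sigma0_contact` | 2.5e4 Pa | spread interface ~110 µm² (≈ 30 FA-capable lamellum nodes at subdivision 2) |
| `h_contact` | 0.4 µm | adhesive range reaches the next node ring during spreading |
| `k_wall` | 10 N/m | nodes within ~1 nm of the plane at nN loads, stiffness bounded for explicit stability |
| `Gamma_subs` | 0.5 N·s/m | explicit-force stability at the stiffest ligand spring; rear-retraction speed O(10 µm/h) |
| `Gamma_liquid` | 1e-3 N·s/m | small regularizing drag on free nodes |
| `theta_Lp`, `theta_Lm` | 0.17, 0.09 | lamellipodium = outer ~1 triangle ring, lamella the next ~2 µm band of the spread interface |
| `sf_pair_rate` | 0.05 1/s | most eligible FAs fiber-bound within ~1 min |
| `k_prot` | calibrated | mean per-Lp-triangle protrusion force 0.12 nN on the initialized cell (`mechamigr calibrate`) |
| `init_duration` | 1800 s | upper bound; convergence usually earlier |

## Problem sizes

The package defaults to an icosphere subdivision of 3 (642 nodes) for the
cortex; most of the whole-cell test suite, the calibration, and the
acceptance script run at subdivision 2 (162 nodes, 320 triangles), the
resolution at which the calibrations above were performed, with simulated
durations of minutes to a few hours rather than the full 24 h study. The
collective-retraction slice of the phase-structure test runs at
subdivision 3: the cascade criterion counts 15 ruptures in one minute, and
the rear lamellum of a subdivision-2 cell holds barely that many adhesions
in total, so the cascade needs the finer mesh's ~90-adhesion pool to
resolve (at subdivision 3 the event fires within ~12 simulated minutes on
the stiffest substrate with long-lived adhesions and both mechanisms
active). The 480-run parameter study (`mechamigr manifest`) is supported
but not exercised by the default test run.

## What the simulations show — and what they do not

The synthetic substrate is a featureless rigid plane with uniform ligand
properties; there is no ECM fiber structure, ligand density field,
substrate viscoelasticity, or chemical gradient. The cell has no nucleus,
no cortical turnover or remeshing (connectivity is immutable, an
acknowledged limitation that caps migration speed), and polarization is
imposed, not emergent. Passing tests therefore demonstrate the internal
consistency of the mechanosensing model — catch-like adhesion
stabilization, stalling-driven fiber strengthening, and the resulting
progressive vs. collective phase structure — not quantitative prediction
for any particular cell type.

## Numerical choices

- dt = 0.05 s throughout; the actin substep has its own stability bound and
  sub-cycles if ever needed.
- Curvature radii for contact are refreshed every 200 steps (10 s);
  curvature evolves on far slower time scales.
- Rupture uses a strict inequality (`|F| > F_rup`); exactly 7.7 nN does not
  rupture.
- The stall comparison clock is aligned to each fiber's birth.
- Stochastic sub-updates run in a fixed order after the mechanical update:
  FA disassembly/rupture, full-retraction detection, fiber
  stall/strengthen/prune, fiber formation, FA formation — one RNG stream
  per run keyed by the manifest seed.
- Degenerate guards: zero-length edges and collinear triangles raise;
  zero-gradient protrusion and coincident fiber endpoints give zero force;
  an empty interface gives an empty source set with a warning.

## Mode classification

A finished run is *collective* if at least one full-retraction event fired;
otherwise *progressive* if the interface centre of mass advanced ≥ 3 µm by
the end and every sliding 4 h window (capped at the run duration for short
runs) shows positive displacement; otherwise *none* — in particular a
net-negative displacement (the counter-force dragging unattached top nodes
backwards) is no migration. The sliding-window operationalization of
"continuously moved forward" is a documented package choice.
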