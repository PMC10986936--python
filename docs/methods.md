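# Methods

## Flow model

Haemolymph in the wing veins is treated as an incompressible Newtonian
fluid in steady, fully developed laminar flow through rigid circular
conduits.  Each vein of length `l_n` and lumen diameter `d_n` is a
hydraulic resistor `R_n = 128 μ l_n / (π d_n⁴)`; the linear law
`Δp_n = R_n q_n` couples the signed per-vein flow `q_n` to its pressure
drop.  Junction (minor) losses are neglected: at Reynolds numbers of order
10⁻⁵ frictional loss dominates by many orders of magnitude.  Vein walls are
rigid and flow is steady — pulsatility, compliance and non-Newtonian
rheology are out of scope.

Fluid constants: viscosity `μ = 1.3 × 10⁻³ Pa·s` (fruit-fly haemolymph at
22 °C) and density `ρ = 1.02 × 10³ kg/m³` (borrowed from another
holometabolan species; density enters only the Reynolds estimate, never the
flow solution).  The boundary condition is a fixed volumetric inflow
`Q_in = Q_out = 5.2 × 10² μm³/s` injected at the inlet node and withdrawn
at the outlet.  By linearity, normalised flows `q_n / Q_in` and all
relative quantities (decrease rates, resistance fractions) are independent
of `Q_in`.

Units: micrometres (and μm³/s, μm²) at every public interface; conversion
to SI happens exactly once, inside the resistance law.  Pressures are Pa,
resistances Pa·s/m³, power W.

## Solvers

Three independent routes solve the same linear problem; their agreement is
asserted in the test suite rather than assumed.

- **Loop (mesh) matrix.**  Chords of a breadth-first spanning tree rooted
  at the inlet define an independent loop basis.  A particular flow routes
  all of `Q_in` along the tree path inlet → outlet; chord circulations are
  the unknowns, one energy equation per chord loop, plus one equation
  around the loop closed through the external source in which the total
  pressure loss appears as the extra unknown.  The dense system is solved
  with LAPACK in double precision.  Any independent basis yields the same
  flows; the choice of tree is a convenience, not a modelling decision.
- **Nodal (graph Laplacian).**  Conductance-weighted Laplacian on node
  pressures, outlet pinned to zero.  Algebraically independent of the loop
  route; serves as its oracle (agreement ≤ 10⁻⁹ relative per vein is a
  test invariant).
- **Hardy–Cross.**  Classical loop-correction iteration, started from the
  tree-path routing with idle chords.  For the linear laminar law each
  correction `Δ = −Σ s R q / Σ R` zeroes its loop exactly, so sequential
  sweeps converge geometrically; a single-loop network converges in one
  correction.  Default stopping rule: largest correction in a sweep below
  10⁻¹⁰ × `Q_in` (reaching agreement with the direct solvers far inside
  the sub-percent range), capped at 10⁵ sweeps with a convergence error
  carrying the residual.

Sign convention: flows and drops are positive along each vein's reference
orientation (rails inlet → outlet, rungs edge → base, the cross vein
anterior → posterior).  A "direction change" between two scenarios is a
sign flip between two flows whose magnitudes both exceed 10⁻¹² × `Q_in`.

## The wing fixture

The geometry table lists 23 veins (7 edge, 7 base, 4 whole connecting
veins, the fifth and sixth connecting veins as split edge-/base-side
segments, and the posterior cross vein) with measured lengths and lumen
diameters; lumen diameters are 20% of the measured outer diameters, as
taken from published cross-sections.  The ladder topology — two rails from
a common inlet to a common outlet, rung *i* joining the *i*-th rail
junctions, the PCV bridging the split points (Node A, Node P) of rungs 5
and 6 — is the reading of the published network diagram under which a
direct solve of the table reproduces every printed circuit result (total
losses, decrease rate, PCV inflow share, per-vein decreases, resistance
fractions).  That reproduction was verified before the fixture was frozen
and is re-verified by the acceptance tests.  Nodes A and P are first-class
nodes, so removing the PCV leaves the split rungs as pairs of series
segments (equivalent by series additivity).

## Membrane cells

A membrane cell's surface area counts both faces (`A_S = 2 A_m`); its
contact area with each bounding vein is half that vein's wall
(`π l_n d_n / 2`), since the cell touches one side of the vein.  Steady
water balance — seepage in through the contact area, evaporation out
through the surface — gives `v_in / v_out = A_S / A_C`.

Cell-to-vein membership is not published as a table and was fixed as:
M1{E1,C1,B1}, M2{E2,C1,C2,B2}, M3{E3,C2,C3,B3}, M4{E4,C3,C4,B4},
M5{E5,C4,C5_E,C5_B,B5}, M6_E{E6,C5_E,C6_E,PCV}, M6_B{B6,C5_B,C6_B,PCV},
M7{E7,C6_E,C6_B,B7}.  This assignment reproduces every published ratio
(anterior mean 16, posterior mean 46, maximum 64 at M6_E, the 50% / +38%
division shifts, and the 2.6× posterior-pair excess).  The printed
contact-area column of the cell table is mutually inconsistent with the
defining formula applied to the vein table (by a cell-dependent factor);
the formula on the vein table is authoritative, because only it reproduces
the published ratios, and the printed column is shipped for reference only.
The 2.6× comparison averages per-cell ratios (not pooled areas); ratio
averaging is what reproduces the published factor.

## The simplified divided cell and the attachment scan

To move the PCV's attachment points continuously, its host cell is
simplified: base and connecting veins become straight segments joining
their endpoints, and the edge vein becomes a circular arc through its two
endpoints whose arc length equals the measured vein length (this single
condition fixes the radius given the chord; the arc bulges away from the
cell).  Attachment positions are fractions of each connecting vein measured
from its base end; the cross vein is the straight segment between the two
attachment points.  Placements whose segment crosses the boundary are
excluded (masked, not zeroed); for a convex cell every placement is valid,
which the scan exploits by skipping the crossing test.  The default scan
step is 0.001 over (0.001…0.999)²; the orchestrated report and the
substitution experiment use 0.01, which moves the located maximum by at
most one coarse cell (a tested refinement-stability property).

The edge-side divided cell's ratio uses `A_S = 2 ×` (divided polygon area,
arc segment included) and contact veins {full edge arc, edge-side parts of
both rungs (piecewise lumen diameters where a rung has two measured
segments), the cross vein}.  For substitute cross veins the diameter inside
the scan follows the matching rule below, so the scan's objective is
consistent with the vein that is subsequently inserted.

**Coordinate fixture (synthetic).**  The original corner coordinates were
measured from a wing photograph and are not published, so the package ships
calibrated synthetic coordinates (`data/simplified_cells_synthetic.json`).
For the PCV's host cell the corners were chosen, by a one-time randomised
search over the two rung directions with ≤5% slack on the side lengths,
such that (i) model boundary-vein lengths stay within 5% of the measured
table (worst 4.2%), (ii) the model membrane area is within 5% of the
tabulated value (2.2%), and (iii) the scan's maximising fractions fall
within 0.03 of the actual attachment fractions (0.322, 0.754) — the
geometric property the analysis tests.  One known limitation: at the actual
fractions the model cross-vein length is ~220 μm versus the measured
180 μm.  With straight rungs this is unavoidable — the corner-to-corner
distances make a 180 μm separation at those fractions geometrically
infeasible for any convex corner set — and it reflects the curvature of the
real veins that the straight-segment model discards.  The exact published
colormap surface is therefore not claimed, only the calibrated properties
above.

Candidate host cells M2–M5 (each bounded by two connecting veins, the
prerequisite for a PCV-like bridge) use the same two-angle construction
with rungs as parallel as the constraints allow and areas matched to the
cell table where feasible (M2 −4.7%, M3 +2.9%, M4 −3.3%).  M5's tabulated
area is unreachable by any straight-segment cell (its rungs are twenty
times its base; the best convex model is 32% small) and the shape closest
to the target is used; this affects only where the substitute attaches,
not its resistance.

## Substitute cross veins

A substitute is a straight vein between two attachment points in a host
cell, spliced into the PCV-less network by splitting each rung at the
attachment fraction (series resistance preserved exactly).  Its diameter is
set by matching `l/d⁴` to the PCV's value, which by the resistance law
makes its hydraulic resistance equal the PCV's whatever its length
(doubling the length scales the diameter by 2^¼).  Each substitute is
placed at its own cell's ratio-maximising fractions, mirroring the
criterion the real PCV satisfies.  The experiment reports the decrease in
total pressure loss relative to the PCV-less baseline; the true PCV is
included as a reference row, computed by the identical comparison path.

## Synthetic generators

All generators are pure functions of `(seed, config)`.  Geometry ranges
default to the span of the measured vein table (lengths 69–1900 μm,
diameters 1.7–12 μm).  They emulate structure, not biology: ladders
reproduce the rail/rung topology (optionally rail-symmetric, which the
solvers must respect by mirror symmetry); series-parallel networks carry
their closed-form equivalent resistance as an oracle; random convex cells
exercise the geometry code.  They do not emulate vein curvature, spatial
correlation of measurement error, or venation development — so passing
tests certify the numerics on networks *like* the wing, not new biology.

`perturbed_forewing` jitters each vein independently and multiplicatively
within the stated average measurement uncertainties (0.92% length, 15%
diameter).  Because resistance scales with `d⁻⁴`, diameter jitter dominates:
across seeded draws the PCV's pressure-loss benefit always persists
(positive decrease rate), with roughly nine in ten draws inside a 10–35%
band around the nominal 20% — a robustness statement about this
implementation under the stated uncertainty model, not a published claim.

## Numerical choices and degenerate inputs

- Dense LAPACK solves in double precision; the networks are small (tens of
  nodes), so sparsity machinery would be overhead.
- Arc geometry solves `sin θ / θ = chord / arc length` by bracketed root
  finding; `chord = arc length` degenerates to a straight segment (zero
  segment area), and `chord > arc length` is a geometry error.
- Non-positive lengths, diameters, viscosities, inflows, or fractions
  outside (0, 1) raise immediately with the offending vein named.
- Disconnected networks, or removals that disconnect inlet from outlet,
  raise structural errors at construction.
- Problem sizes in the packaged analyses: the 23-vein network solves in
  milliseconds; the full test suite runs the 0.001-step scan once and a
  thousand series-parallel oracle instances, a few seconds in total.

## Known limitations

- Steady rigid-wall Poiseuille flow only; no pulsatility, compliance,
  wall elasticity or non-circular lumens.
- Absolute pressures and powers inherit the `d⁴` sensitivity of
  two-significant-figure diameter measurements; relative quantities
  (decrease rates, fractions) are far more robust, as the perturbation
  analysis shows.
- The simplified-cell coordinates are calibrated synthetic stand-ins; all
  conclusions drawn from them are about the calibrated model's properties,
  not about exact reproduction of the published attachment-scan surface.
- The evaporation–seepage model is the stated velocity-ratio identity;
  no evaporation physics beyond mass balance is modelled.
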