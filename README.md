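# wingflux

Hydraulic-circuit analysis of haemolymph (insect blood) flow in the wing
vein network of the fruit fly *Drosophila melanogaster*.

Insect wing veins are fluid-carrying conduits: haemolymph enters at the
anterior wing base, traverses the venation, and exits posteriorly.  At the
measured scales (diameters ~10⁻⁶ m, velocities ~10⁻⁴ m/s) the Reynolds
number is of order 10⁻⁵, so each vein behaves as a laminar Poiseuille
resistor

    R_n = 128 μ l_n / (π d_n⁴),        Δp_n = R_n q_n,

with `l_n` the vein length, `d_n` its lumen diameter and `μ` the haemolymph
viscosity.  The whole venation is then a resistor circuit obeying
Kirchhoff-style conservation laws — mass at every junction, pressure around
every loop — and can be solved for per-vein flow rates `q_n` and the total
inlet-to-outlet pressure loss `Δp_total` at a fixed boundary inflow
`Q_in = 5.2 × 10² μm³/s`.

Topologically the fruit-fly forewing is a ladder: an *edge* rail and a
*base* rail running from inlet to outlet, joined by six *connecting* veins.
One vein breaks the symmetry — the **posterior cross vein (PCV)**, which
bridges the fifth and sixth connecting veins.  This package quantifies what
that vein does hydraulically (by removing and rearranging it in silico) and
geometrically (through the surface-to-contact area ratio `A_S / A_C` of the
membrane cells, which by water mass balance equals the seepage-to-
evaporation velocity ratio the membrane needs to stay hydrated).

The package provides:

- `network` / `drosophila` — domain types, the Poiseuille resistance law,
  and the packaged 23-vein forewing fixture built from the measured
  geometry table;
- `solvers` — three independent steady-flow solvers (loop/mesh matrix,
  nodal graph Laplacian, Hardy–Cross iteration) plus resistance utilities;
- `ablation` — PCV removal, flow-change reports, resistance-matched
  substitute cross veins, and the edge–base pair resistance profile;
- `membrane` — membrane-cell area ratios and the simplified divided-cell
  model with the cross-vein attachment-position scan;
- `synthetic` — generators (ladders, series-parallel networks with
  closed-form equivalents, jittered fixtures, random cells) used as ground
  truth in the test suite;
- `report` / `cli` — a one-call full analysis and the `wingflux` command.

## Worked example

```python
import wingflux as wf
from wingflux import drosophila

net  = drosophila.build_drosophila_forewing()
bc   = wf.BoundaryConditions(5.2e2)                 # μm³/s
sol  = wf.solve_loops(net, wf.HAEMOLYMPH, bc)
base = wf.solve_loops(wf.remove_vein(net, "PCV"), wf.HAEMOLYMPH, bc)
rep  = wf.compare_flows(base, sol)

print(f"loss with PCV    : {sol.total_pressure_loss:.1f} Pa")
print(f"loss without PCV : {base.total_pressure_loss:.1f} Pa")
print(f"decrease rate    : {100*rep.pressure_loss_decrease_rate:.1f} %")
print(f"PCV inflow share : {wf.pcv_inflow(sol):.3f} x Q_in")
print(f"pumping power    : {wf.pumping_power(sol):.2e} W")
```

prints

```
loss with PCV    : 322.4 Pa
loss without PCV : 403.7 Pa
decrease rate    : 20.1 %
PCV inflow share : 0.315 x Q_in
pumping power    : 1.68e-13 W
```

Read: the PCV runs parallel to the sixth edge–base vein pair — by far the
most resistive pair in the wing — and cuts the network's total pressure
loss by a fifth, while carrying about a third of the boundary inflow.  The
pumping power `Δp_total · Q_in` is the cost of maintaining circulation;
`wf.substitution_experiment` shows that a resistance-matched cross vein
placed in any other membrane cell recovers at most a few percent of that
saving, and `wf.scan_pcv_positions` shows the PCV's actual attachment
points nearly maximise the divided cell's `A_S / A_C` ratio.

The same analyses are available from the shell:

```sh
wingflux solve
wingflux ablate --vein PCV
wingflux substitute --cells M2,M3,M4,M5
wingflux scan --cell M6 --step 0.001
wingflux report --out results/
```

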