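"""In-silico vein experiments: ablation, comparison, and substitution.

The central experiment removes the posterior cross vein (PCV) and compares
the two steady flow fields; the substitution experiment asks whether a
cross vein placed in any other membrane cell — resistance-matched to the
PCV through equal ``l/d⁴`` — could lower the total pressure loss as much.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import drosophila
from .membrane import SimplifiedCell, scan_pcv_positions
from .network import FluidProperties, VeinNetwork, VeinSegment
from .solvers import (BoundaryConditions, FlowSolution,
                      combined_parallel_resistance, solve_nodal)

__all__ = [
    "ComparisonReport",
    "CrossVeinSpec",
    "PlacementError",
    "remove_vein",
    "compare_flows",
    "pcv_inflow",
    "matched_diameter",
    "make_substitute_cross_vein",
    "insert_cross_vein",
    "substitution_experiment",
    "pair_resistance_profile",
]


class PlacementError(ValueError):
    """A candidate cross-vein placement intersects the cell boundary."""


def remove_vein(network: VeinNetwork, vein_id: str) -> VeinNetwork:
    """Copy of the network without one vein.

    Split-rung pass-through nodes (A, P) are retained as degree-2 nodes, so
    removing the PCV leaves the two halves of each split rung as series
    segments.  Raises ``StructuralError`` if removal disconnects the network.
    """
    if vein_id not in network.veins:
        raise KeyError(f"no vein {vein_id!r} in network")
    veins = [v for vid, v in network.veins.items() if vid != vein_id]
    return VeinNetwork(veins, network.inlet, network.outlet, network.node_coords)


@dataclass
class ComparisonReport:
    """Per-vein flow changes between a baseline and a scenario solution.

    `table` columns: ``q_o`` (baseline flow), ``q`` (scenario flow), both in
    μm³/s and signed along each vein's reference orientation;
    ``dq_over_qo = (q − q_o)/q_o``; ``magnitude_ratio = |q|/|q_o|``;
    ``direction_changed`` flags sign flips between two non-negligible flows.
    """

    table: pd.DataFrame
    pressure_loss_decrease_rate: float  # (Δp_o − Δp) / Δp_o
    baseline_loss_pa: float
    scenario_loss_pa: float

    def direction_changed(self) -> list[str]:
        t = self.table
        return list(t.index[t["direction_changed"]])


def compare_flows(baseline: FlowSolution, scenario: FlowSolution,
                  negligible: float = 1e-12) -> ComparisonReport:
    """Compare two solutions of (nearly) the same network.

    Veins present in only one solution get one-sided rows with NaN on the
    other side.  `negligible` sets the dead band (as a fraction of the
    boundary inflow) below which a flow has no meaningful direction.
    """
    if not math.isclose(baseline.inflow_rate_um3_s, scenario.inflow_rate_um3_s):
        raise ValueError("solutions were driven with different inflow rates")
    tiny = negligible * baseline.inflow_rate_um3_s
    ids = sorted(set(baseline.flow_rates) | set(scenario.flow_rates))
    rows = {}
    for vid in ids:
        q_o = baseline.flow_rates.get(vid, np.nan)
        q = scenario.flow_rates.get(vid, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            dq = (q - q_o) / q_o
            ratio = abs(q) / abs(q_o)
        flip = (not np.isnan(q_o) and not np.isnan(q)
                and abs(q_o) > tiny and abs(q) > tiny
                and (q > 0) != (q_o > 0))
        rows[vid] = {"q_o": q_o, "q": q, "dq_over_qo": dq,
                     "magnitude_ratio": ratio, "direction_changed": flip}
    table = pd.DataFrame.from_dict(rows, orient="index")
    dp_o = baseline.total_pressure_loss
    dp = scenario.total_pressure_loss
    return ComparisonReport(
        table=table,
        pressure_loss_decrease_rate=(dp_o - dp) / dp_o,
        baseline_loss_pa=dp_o,
        scenario_loss_pa=dp,
    )


def pcv_inflow(solution: FlowSolution, node: str = "A",
               feeders: tuple[str, str] = ("V_C_5_E", "V_C_5_B"),
               cross_vein: str = "PCV") -> float:
    """Fraction of the boundary inflow delivered to the PCV.

    Sums the flows entering the anterior attachment node from both segments
    of the split connecting vein; by mass conservation at that node the sum
    equals ``|q_PCV|``.  The result is expressed as a multiple of Q_in.
    """
    net = solution.network
    if cross_vein not in net.veins:
        raise ValueError(f"network has no {cross_vein!r}; the inflow fraction "
                         "is undefined without it")
    total = 0.0
    for vid in feeders:
        v = net.veins[vid]
        q = solution.flow_rates[vid]
        if v.head == node:
            total += q          # + along tail->head enters `node`
        elif v.tail == node:
            total -= q
        else:
            raise ValueError(f"vein {vid!r} does not touch node {node!r}")
    return abs(total) / solution.inflow_rate_um3_s


# ---------------------------------------------------------------------------
# substitute cross veins
# ---------------------------------------------------------------------------

def matched_diameter(length_um: float,
                     reference_length_um: float = drosophila.PCV_LENGTH_UM,
                     reference_diameter_um: float = drosophila.PCV_DIAMETER_UM):
    """Diameter making ``l/d⁴`` equal to the reference vein's value.

    Because the Poiseuille resistance is proportional to ``l/d⁴``, a vein
    with the matched diameter has exactly the reference resistance whatever
    its length; doubling the length scales the diameter by ``2^(1/4)``.
    """
    ld4 = reference_length_um / reference_diameter_um ** 4
    return (np.asarray(length_um, float) / ld4) ** 0.25


@dataclass(frozen=True)
class CrossVeinSpec:
    """A straight cross vein linking two connecting veins of one cell.

    Fractions are measured from the base end of each rung (the base-side
    segment's share of the rung length), mirroring the attachment variables
    of the simplified cell model.
    """

    host_cell: str
    anterior_rung: str
    anterior_fraction: float
    posterior_rung: str
    posterior_fraction: float
    length_um: float
    diameter_um: float

    def __post_init__(self) -> None:
        for f in (self.anterior_fraction, self.posterior_fraction):
            if not 0.0 < f < 1.0:
                raise ValueError(f"attachment fractions must lie in (0, 1), got {f}")
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ValueError("cross vein needs positive length and diameter")


def make_substitute_cross_vein(cell: SimplifiedCell, anterior_fraction: float,
                               posterior_fraction: float,
                               reference_length_um: float = drosophila.PCV_LENGTH_UM,
                               reference_diameter_um: float = drosophila.PCV_DIAMETER_UM,
                               ) -> CrossVeinSpec:
    """Cross-vein spec for one attachment placement in a simplified cell.

    The vein is the straight segment between the two attachment points; its
    diameter follows the ``l/d⁴`` matching rule, so its hydraulic resistance
    equals the reference (PCV) resistance exactly.  Placements whose straight
    segment leaves the cell are rejected.
    """
    if not 0.0 < anterior_fraction < 1.0 or not 0.0 < posterior_fraction < 1.0:
        raise ValueError("attachment fractions must lie in (0, 1)")
    from .membrane import _segment_crossings
    (ax, ay), (px, py) = cell.attachment_points(anterior_fraction, posterior_fraction)
    boundary = cell.boundary_polyline(256)
    crossings = _segment_crossings(np.atleast_1d(ax), np.atleast_1d(ay),
                                   np.atleast_1d(px), np.atleast_1d(py), boundary)
    if int(crossings[0]) > 0:
        raise PlacementError(
            f"cell {cell.id!r}: straight cross vein at "
            f"({anterior_fraction}, {posterior_fraction}) intersects the boundary")
    length = float(cell.cross_vein_length_um(anterior_fraction, posterior_fraction))
    return CrossVeinSpec(
        host_cell=cell.id,
        anterior_rung=cell.anterior_vein,
        anterior_fraction=float(anterior_fraction),
        posterior_rung=cell.posterior_vein,
        posterior_fraction=float(posterior_fraction),
        length_um=length,
        diameter_um=float(matched_diameter(length, reference_length_um,
                                           reference_diameter_um)),
    )


def _rung_chain(network: VeinNetwork, rung: str):
    """The rung's vein segments from base to edge.

    Fixture rungs are oriented edge → base; a split rung ``V_C_k`` exists as
    ``V_C_k_E`` (edge side) and ``V_C_k_B`` (base side).
    """
    if rung in network.veins:
        return [network.veins[rung]]
    split = [f"{rung}_B", f"{rung}_E"]
    if all(s in network.veins for s in split):
        return [network.veins[s] for s in split]
    raise KeyError(f"rung {rung!r} not found in network")


def _split_rung(veins: dict, rung_chain, fraction: float, new_node: str):
    """Split a rung chain at a base-side length fraction; returns new veins."""
    total = sum(v.length_um for v in rung_chain)
    target = fraction * total
    # chain is ordered base -> edge, each vein oriented edge -> base
    pos = 0.0
    for v in rung_chain:
        if target <= pos + v.length_um or v is rung_chain[-1]:
            within = target - pos            # distance from v's base end (head)
            frac_from_tail = 1.0 - within / v.length_um
            del veins[v.id]
            veins[v.id + "_e"] = VeinSegment(
                v.id + "_e", v.vein_class, v.tail, new_node,
                frac_from_tail * v.length_um, v.diameter_um)
            veins[v.id + "_b"] = VeinSegment(
                v.id + "_b", v.vein_class, new_node, v.head,
                (1 - frac_from_tail) * v.length_um, v.diameter_um)
            return
        pos += v.length_um


def insert_cross_vein(network: VeinNetwork, spec: CrossVeinSpec) -> VeinNetwork:
    """Splice a substitute cross vein into the network.

    Each attachment rung is split at the requested fraction (measured from
    its base end); the split preserves the rung's series resistance exactly.
    """
    veins = dict(network.veins)
    node_a = f"X_{spec.host_cell}_A"
    node_p = f"X_{spec.host_cell}_P"
    _split_rung(veins, _rung_chain(network, spec.anterior_rung),
                spec.anterior_fraction, node_a)
    _split_rung(veins, _rung_chain(network, spec.posterior_rung),
                spec.posterior_fraction, node_p)
    veins[f"CV_{spec.host_cell}"] = VeinSegment(
        f"CV_{spec.host_cell}", "cross", node_a, node_p,
        spec.length_um, spec.diameter_um)
    return VeinNetwork(veins.values(), network.inlet, network.outlet,
                       network.node_coords)


def substitution_experiment(network: VeinNetwork, cells, fluid: FluidProperties,
                            bc: BoundaryConditions, scan_step: float = 0.01,
                            ) -> pd.DataFrame:
    """Pressure-loss decrease rate for each candidate cross vein.

    For every candidate cell the substitute is placed at the cell's own
    surface-to-contact-ratio-maximising attachment fractions (found by
    scanning, with the matched-diameter rule applied inside the scan), then
    spliced into the PCV-less network and solved.  The true PCV is included
    as its own row for reference.  Rates are percentages of the PCV-less
    total pressure loss.
    """
    if "PCV" in network.veins:
        baseline_net = remove_vein(network, "PCV")
        full_net = network
    else:
        baseline_net = network
        full_net = None
    baseline = solve_nodal(baseline_net, fluid, bc)

    rows = []
    if full_net is not None:
        with_pcv = solve_nodal(full_net, fluid, bc)
        rows.append({
            "cell": "M6 (PCV)", "f_anterior": np.nan, "f_posterior": np.nan,
            "length_um": full_net.veins["PCV"].length_um,
            "diameter_um": full_net.veins["PCV"].diameter_um,
            "decrease_rate_percent":
                100.0 * compare_flows(baseline, with_pcv).pressure_loss_decrease_rate,
        })
    for cell in cells:
        scan = scan_pcv_positions(cell, step=scan_step, cross_diameter=matched_diameter)
        fa, fp = scan.argmax_fractions
        spec = make_substitute_cross_vein(cell, fa, fp)
        scenario = solve_nodal(insert_cross_vein(baseline_net, spec), fluid, bc)
        rows.append({
            "cell": cell.id, "f_anterior": fa, "f_posterior": fp,
            "length_um": spec.length_um, "diameter_um": spec.diameter_um,
            "decrease_rate_percent":
                100.0 * compare_flows(baseline, scenario).pressure_loss_decrease_rate,
        })
    return pd.DataFrame(rows)


def pair_resistance_profile(network: VeinNetwork, fluid: FluidProperties,
                            ) -> pd.DataFrame:
    """Combined resistance of each edge–base vein pair, Fig-8 style.

    Pair *i* combines ``V_E_i`` and ``V_B_i`` in parallel; where the network
    carries a cross vein parallel to the pair (the PCV for pair 6) a second
    column adds it to the combination.  Both columns are normalised by pair
    6 without the PCV.
    """
    resist = network.resistances(fluid)
    rows = []
    for i in range(1, 8):
        pair = combined_parallel_resistance(
            [resist[f"V_E_{i}"], resist[f"V_B_{i}"]])
        with_cross = np.nan
        if i == 6 and "PCV" in resist:
            with_cross = combined_parallel_resistance(
                [resist["V_E_6"], resist["V_B_6"], resist["PCV"]])
        rows.append({"pair": i, "R_pair": pair, "R_pair_with_cross": with_cross})
    df = pd.DataFrame(rows).set_index("pair")
    ref = df.loc[6, "R_pair"]
    df["normalized"] = df["R_pair"] / ref
    df["normalized_with_cross"] = df["R_pair_with_cross"] / ref
    return df
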