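"""Steady Poiseuille flow on a vein network, by three routes.

All solvers enforce Kirchhoff-style conservation laws: mass at every node,
energy (pressure) around every closed loop.  The boundary condition is a
fixed volumetric inflow injected at the inlet and withdrawn at the outlet.

``solve_loops``
    The loop-matrix formulation: independent flows are the chords of a
    spanning tree, one energy equation per chord loop plus one for the loop
    closed through the pressure source, with the total pressure loss as the
    extra unknown.  This mirrors the ``Ax = y`` mesh analysis of electrical
    circuits.
``solve_nodal``
    Weighted graph-Laplacian solve on node pressures; algebraically
    independent of the loop route and used as its cross-check.
``solve_hardy_cross``
    The classical iterative loop-correction scheme of pipe-network analysis.
    For the linear (laminar) resistance law each loop correction is exact,
    so sequential sweeps converge geometrically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import FluidProperties, StructuralError, VeinNetwork

__all__ = [
    "BoundaryConditions",
    "FlowSolution",
    "ConvergenceError",
    "solve_loops",
    "solve_nodal",
    "solve_hardy_cross",
    "combined_parallel_resistance",
    "equivalent_resistance",
    "pumping_power",
]

UM3 = 1e-18  # m³ per μm³


class ConvergenceError(RuntimeError):
    """Hardy–Cross failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class BoundaryConditions:
    """Fixed boundary inflow (= outflow) rate in μm³/s."""

    inflow_rate_um3_s: float = 5.2e2

    def __post_init__(self) -> None:
        if self.inflow_rate_um3_s <= 0:
            raise ValueError("inflow rate must be positive")

    @property
    def inflow_rate_si(self) -> float:
        return self.inflow_rate_um3_s * UM3


@dataclass
class FlowSolution:
    """Signed per-vein flows and pressure drops plus node pressures.

    Flows are positive along each vein's reference (tail → head) orientation
    and reported in μm³/s; pressure drops satisfy ``Δp_n = R_n q_n`` with the
    same sign convention.  The outlet pressure is pinned to zero, so the
    total loss equals the inlet node pressure.
    """

    network: VeinNetwork
    flow_rates: dict[str, float]          # μm³/s
    pressure_drops: dict[str, float]      # Pa
    node_pressures: dict[str, float]      # Pa
    total_pressure_loss: float            # Pa
    inflow_rate_um3_s: float
    solver: str
    iterations: int | None = None

    def q_over_qin(self, vein_id: str) -> float:
        return self.flow_rates[vein_id] / self.inflow_rate_um3_s

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"vein_id": vid, "q_um3_per_s": q,
             "q_over_Qin": q / self.inflow_rate_um3_s,
             "dp_Pa": self.pressure_drops[vid]}
            for vid, q in self.flow_rates.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        out = {
            "total_pressure_loss_Pa": self.total_pressure_loss,
            "equivalent_resistance_Pa_s_per_m3":
                self.total_pressure_loss / (self.inflow_rate_um3_s * UM3),
            "power_W": self.total_pressure_loss * self.inflow_rate_um3_s * UM3,
            "solver": self.solver,
        }
        if self.iterations is not None:
            out["iterations"] = self.iterations
        return out

    def to_json(self) -> str:
        return json.dumps(self.summary())


# ---------------------------------------------------------------------------
# shared plumbing: spanning tree, chord loops, tree-path routing
# ---------------------------------------------------------------------------

def _bfs_tree(network: VeinNetwork):
    """BFS spanning tree rooted at the inlet.

    Returns (parent, tree_ids) where parent maps node -> (parent node,
    vein id, sign); sign is +1 when the vein's reference orientation points
    from parent to node.
    """
    adj: dict[str, list[tuple[str, str, int]]] = {}
    for v in network.veins.values():
        adj.setdefault(v.tail, []).append((v.head, v.id, +1))
        adj.setdefault(v.head, []).append((v.tail, v.id, -1))
    parent: dict[str, tuple[str, str, int] | None] = {network.inlet: None}
    order = [network.inlet]
    tree_ids: set[str] = set()
    i = 0
    while i < len(order):
        node = order[i]
        i += 1
        for nbr, vid, sign in adj.get(node, ()):
            if nbr not in parent:
                parent[nbr] = (node, vid, sign)
                tree_ids.add(vid)
                order.append(nbr)
    return parent, tree_ids


def _path_to_root(parent, node):
    """Veins from `node` up to the root as {vein_id: sign toward root}."""
    out: dict[str, int] = {}
    while parent[node] is not None:
        up, vid, sign = parent[node]
        # sign=+1 means vein points parent->node, i.e. against the walk to root
        out[vid] = -sign
        node = up
    return out


def _tree_path(parent, a, b):
    """Signed veins along the tree path a -> b (sign +1 = along reference)."""
    to_root_a = _path_to_root(parent, a)
    to_root_b = _path_to_root(parent, b)
    path = {}
    for vid, s in to_root_a.items():
        if vid not in to_root_b:
            path[vid] = s
    for vid, s in to_root_b.items():
        if vid not in to_root_a:
            path[vid] = -s
    return path


def _chord_loops(network: VeinNetwork, parent, tree_ids):
    """One independent loop per chord: chord + tree path head -> tail."""
    loops = []
    for v in network.veins.values():
        if v.id in tree_ids:
            continue
        loop = {v.id: +1}
        for vid, s in _tree_path(parent, v.head, v.tail).items():
            loop[vid] = s
        loops.append(loop)
    return loops


def _pressures_from_flows(network, resist, q_si):
    """Node pressures by integrating Δp = R q along a tree from the outlet."""
    parent, _ = _bfs_tree(network)
    pressures = {}
    for node in network.nodes | {network.inlet, network.outlet}:
        p = 0.0
        for vid, sign in _path_to_root(parent, node).items():
            # walking node -> inlet; accumulate drops, then reference to outlet
            p += sign * resist[vid] * q_si[vid]
        pressures[node] = p  # relative to inlet for now: p = p_inlet - p_node? see below
    # The walk above accumulates sum of signed drops along node->inlet, which
    # equals p_node - p_inlet.  Rebase so the outlet is exactly zero.
    off = pressures[network.outlet]
    return {n: p - off for n, p in pressures.items()}


def _package(network, resist, q_si, bc, solver, iterations=None) -> FlowSolution:
    pressures = _pressures_from_flows(network, resist, q_si)
    drops = {vid: resist[vid] * q_si[vid] for vid in q_si}
    total = pressures[network.inlet] - pressures[network.outlet]
    return FlowSolution(
        network=network,
        flow_rates={vid: q / UM3 for vid, q in q_si.items()},
        pressure_drops=drops,
        node_pressures=pressures,
        total_pressure_loss=total,
        inflow_rate_um3_s=bc.inflow_rate_um3_s,
        solver=solver,
        iterations=iterations,
    )


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

def solve_loops(network: VeinNetwork, fluid: FluidProperties,
                bc: BoundaryConditions) -> FlowSolution:
    """Loop-matrix (mesh) solve with the total loss as an extra unknown.

    Independent flow variables are the chords of a BFS spanning tree rooted
    at the inlet; dependent vein flows are eliminated through mass
    conservation by superposing chord-loop circulations on a particular flow
    that routes the whole inflow along the tree path from inlet to outlet.
    One energy equation is written per chord loop, plus one around the loop
    closed through the external source, whose right-hand side is the unknown
    total pressure loss.
    """
    resist = network.resistances(fluid)
    parent, tree_ids = _bfs_tree(network)
    loops = _chord_loops(network, parent, tree_ids)
    source_path = _tree_path(parent, network.inlet, network.outlet)

    q_in = bc.inflow_rate_si
    q_part = {vid: 0.0 for vid in network.veins}
    for vid, s in source_path.items():
        q_part[vid] = s * q_in

    m = len(loops)
    a = np.zeros((m + 1, m + 1))
    y = np.zeros(m + 1)
    for i, loop_i in enumerate(loops):
        for vid, s_i in loop_i.items():
            r = resist[vid]
            y[i] -= r * s_i * q_part[vid]
            for j, loop_j in enumerate(loops):
                s_j = loop_j.get(vid)
                if s_j:
                    a[i, j] += r * s_i * s_j
    # source loop: sum of drops along the inlet->outlet path minus Δp_total = 0
    for vid, s_p in source_path.items():
        r = resist[vid]
        y[m] -= r * s_p * q_part[vid]
        for j, loop_j in enumerate(loops):
            s_j = loop_j.get(vid)
            if s_j:
                a[m, j] += r * s_p * s_j
    a[m, m] = -1.0

    try:
        x = np.linalg.solve(a, y)
    except np.linalg.LinAlgError as exc:
        raise StructuralError(f"singular loop system: {exc}") from exc

    q_si = dict(q_part)
    for j, loop_j in enumerate(loops):
        for vid, s in loop_j.items():
            q_si[vid] += s * x[j]
    return _package(network, resist, q_si, bc, "loops")


def solve_nodal(network: VeinNetwork, fluid: FluidProperties,
                bc: BoundaryConditions) -> FlowSolution:
    """Nodal (graph-Laplacian) solve: mass conservation at every node.

    Node pressures are the unknowns; the outlet is pinned to zero and the
    boundary inflow enters the right-hand side.  Per-vein flows follow from
    the Poiseuille law on each pressure difference.
    """
    resist = network.resistances(fluid)
    nodes = sorted(network.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    lap = np.zeros((n, n))
    rhs = np.zeros(n)
    for vid, v in network.veins.items():
        g = 1.0 / resist[vid]
        i, j = idx[v.tail], idx[v.head]
        lap[i, i] += g
        lap[j, j] += g
        lap[i, j] -= g
        lap[j, i] -= g
    rhs[idx[network.inlet]] = bc.inflow_rate_si
    rhs[idx[network.outlet]] = -bc.inflow_rate_si
    k = idx[network.outlet]
    lap[k, :] = 0.0
    lap[k, k] = 1.0
    rhs[k] = 0.0
    try:
        p = np.linalg.solve(lap, rhs)
    except np.linalg.LinAlgError as exc:
        raise StructuralError(f"singular nodal system: {exc}") from exc

    q_si = {vid: (p[idx[v.tail]] - p[idx[v.head]]) / resist[vid]
            for vid, v in network.veins.items()}
    drops = {vid: resist[vid] * q for vid, q in q_si.items()}
    pressures = {node: p[idx[node]] for node in nodes}
    total = pressures[network.inlet] - pressures[network.outlet]
    return FlowSolution(
        network=network,
        flow_rates={vid: q / UM3 for vid, q in q_si.items()},
        pressure_drops=drops,
        node_pressures=pressures,
        total_pressure_loss=total,
        inflow_rate_um3_s=bc.inflow_rate_um3_s,
        solver="nodal",
    )


def solve_hardy_cross(network: VeinNetwork, fluid: FluidProperties,
                      bc: BoundaryConditions, tolerance: float = 1e-10,
                      max_iter: int = 100_000) -> FlowSolution:
    """Hardy–Cross loop-correction iteration.

    Starts from a mass-conserving assignment (all inflow routed along the
    spanning-tree path, chords idle) and repeatedly applies to each chord
    loop the correction ``Δ = −Σ s R q / Σ R`` that zeroes the loop's
    pressure imbalance.  Stops when the largest correction in a sweep,
    relative to the boundary inflow, falls below `tolerance`.
    """
    resist = network.resistances(fluid)
    parent, tree_ids = _bfs_tree(network)
    loops = _chord_loops(network, parent, tree_ids)
    q_in = bc.inflow_rate_si

    q_si = {vid: 0.0 for vid in network.veins}
    for vid, s in _tree_path(parent, network.inlet, network.outlet).items():
        q_si[vid] = s * q_in

    loop_dens = [sum(resist[vid] for vid in loop) for loop in loops]
    sweeps = 0
    worst = math.inf
    while sweeps < max_iter:
        sweeps += 1
        worst = 0.0
        for loop, den in zip(loops, loop_dens):
            num = sum(s * resist[vid] * q_si[vid] for vid, s in loop.items())
            delta = -num / den
            for vid, s in loop.items():
                q_si[vid] += s * delta
            worst = max(worst, abs(delta))
        if not loops or worst <= tolerance * q_in:
            break
    else:
        raise ConvergenceError(
            f"Hardy–Cross did not converge in {max_iter} sweeps "
            f"(residual {worst / q_in:.3e} of Q_in)", worst / q_in)
    return _package(network, resist, q_si, bc, "hardy-cross", iterations=sweeps)


# ---------------------------------------------------------------------------
# resistance utilities
# ---------------------------------------------------------------------------

def combined_parallel_resistance(resistances) -> float:
    """Harmonic combination ``(Σ 1/R_i)⁻¹`` of resistors sharing endpoints."""
    rs = list(resistances)
    if not rs:
        raise ValueError("need at least one resistance")
    if any(r <= 0 for r in rs):
        raise ValueError("resistances must be positive")
    return 1.0 / sum(1.0 / r for r in rs)


def equivalent_resistance(network: VeinNetwork, fluid: FluidProperties) -> float:
    """Two-terminal equivalent resistance Δp_total / Q_in, in Pa·s/m³.

    Independent of the probing inflow by linearity of the Poiseuille law.
    """
    bc = BoundaryConditions(inflow_rate_um3_s=1.0)
    sol = solve_nodal(network, fluid, bc)
    return sol.total_pressure_loss / bc.inflow_rate_si


def pumping_power(solution: FlowSolution,
                  bc: BoundaryConditions | None = None) -> float:
    """Pumping power Δp_total × Q_in in watts."""
    q = bc.inflow_rate_um3_s if bc is not None else solution.inflow_rate_um3_s
    return solution.total_pressure_loss * q * UM3
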