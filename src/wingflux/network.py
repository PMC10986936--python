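"""Core domain types for hydraulic vein networks.

A wing vein is modelled as a straight cylindrical conduit carrying laminar
(Poiseuille) flow.  The network is a graph of such conduits between labelled
nodes, with one designated inlet and one outlet.  Geometry is expressed in
micrometres at every public interface; conversion to SI happens exactly once,
inside :func:`hydraulic_resistance`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import networkx as nx

__all__ = [
    "FluidProperties",
    "VeinSegment",
    "VeinNetwork",
    "FixtureError",
    "StructuralError",
    "hydraulic_resistance",
    "inner_diameter_from_outer",
    "reynolds_number",
    "HAEMOLYMPH",
]

UM = 1e-6  # metres per micrometre

VEIN_CLASSES = ("edge", "base", "connecting", "cross")


class FixtureError(ValueError):
    """A geometry table or serialized network violates the schema."""


class StructuralError(ValueError):
    """A network is disconnected or otherwise unsolvable."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid constants.

    Parameters
    ----------
    viscosity : float
        Dynamic viscosity in Pa·s.
    density : float
        Mass density in kg/m³.  Only the Reynolds-number estimate uses it;
        steady flow rates and pressure losses are density-independent.
    """

    viscosity: float
    density: float

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity}")
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")


#: Haemolymph of the adult fruit fly: viscosity measured at 22 °C, density
#: taken from another holometabolan insect at the same temperature.
HAEMOLYMPH = FluidProperties(viscosity=1.3e-3, density=1.02e3)


def hydraulic_resistance(length_um: float, diameter_um: float, fluid: FluidProperties,
                         *, vein_id: str | None = None) -> float:
    """Poiseuille resistance ``128 μ l / (π d⁴)`` of one conduit, in Pa·s/m³.

    Parameters
    ----------
    length_um, diameter_um : float
        Conduit length and inner diameter in μm.
    fluid : FluidProperties
        Carrier fluid; only the viscosity enters.
    vein_id : str, optional
        Included in the error message when the geometry is invalid.
    """
    if length_um <= 0 or diameter_um <= 0:
        tag = f" for vein {vein_id!r}" if vein_id else ""
        raise ValueError(
            f"length and diameter must be positive{tag}: "
            f"l={length_um} um, d={diameter_um} um")
    l_m = length_um * UM
    d_m = diameter_um * UM
    return 128.0 * fluid.viscosity * l_m / (math.pi * d_m ** 4)


def inner_diameter_from_outer(outer_diameter_um: float, fraction: float = 0.2) -> float:
    """Lumen diameter from the measured outer diameter.

    Cross-sections of fruit-fly wing veins show a haemolymph-filled core of
    roughly 20% of the outer diameter; the packaged geometry table already
    stores inner diameters, so this helper is for new measurements only.
    """
    if outer_diameter_um <= 0:
        raise ValueError("outer diameter must be positive")
    return fraction * outer_diameter_um


def reynolds_number(fluid: FluidProperties, velocity: float, diameter: float) -> float:
    """Reynolds number ``ρ v d / μ`` (SI inputs: m/s and m)."""
    if velocity < 0 or diameter < 0:
        raise ValueError("velocity and diameter must be non-negative")
    return fluid.density * velocity * diameter / fluid.viscosity


@dataclass(frozen=True)
class VeinSegment:
    """One conduit of the network.

    The (tail, head) pair fixes the reference orientation: flows and pressure
    drops reported for this vein are positive when directed tail → head.
    """

    id: str
    vein_class: str
    tail: str
    head: str
    length_um: float
    diameter_um: float

    def __post_init__(self) -> None:
        if self.vein_class not in VEIN_CLASSES:
            raise ValueError(
                f"vein {self.id!r}: class must be one of {VEIN_CLASSES}, "
                f"got {self.vein_class!r}")
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ValueError(
                f"vein {self.id!r}: length and diameter must be positive")
        if self.tail == self.head:
            raise ValueError(f"vein {self.id!r}: tail and head coincide")

    def resistance(self, fluid: FluidProperties) -> float:
        """Hydraulic resistance of this vein in Pa·s/m³."""
        return hydraulic_resistance(self.length_um, self.diameter_um, fluid,
                                    vein_id=self.id)


class VeinNetwork:
    """A connected network of vein segments with designated inlet and outlet.

    Parallel veins between the same pair of nodes are allowed (the network is
    a multigraph).  Nodes may optionally carry 2-D coordinates in μm; the flow
    solvers never use them.
    """

    def __init__(self, veins, inlet: str, outlet: str,
                 node_coords: dict[str, tuple[float, float]] | None = None):
        veins = list(veins)
        ids = [v.id for v in veins]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise FixtureError(f"duplicated vein ids: {sorted(dup)}")
        if inlet == outlet:
            raise StructuralError("inlet and outlet must differ")
        self.veins: dict[str, VeinSegment] = {v.id: v for v in veins}
        self.inlet = inlet
        self.outlet = outlet
        self.node_coords = dict(node_coords or {})
        g = self.to_graph()
        if inlet not in g or outlet not in g:
            raise StructuralError("inlet/outlet must be endpoints of some vein")
        if not nx.is_connected(g):
            comp = min(nx.connected_components(g), key=len)
            raise StructuralError(
                f"network is disconnected; smallest component: {sorted(comp)}")

    # -- container conveniences ------------------------------------------
    @property
    def nodes(self) -> set[str]:
        out = set()
        for v in self.veins.values():
            out.add(v.tail)
            out.add(v.head)
        return out

    def __len__(self) -> int:
        return len(self.veins)

    def __contains__(self, vein_id: str) -> bool:
        return vein_id in self.veins

    def to_graph(self) -> nx.MultiGraph:
        """Undirected multigraph view; edge keys are vein ids."""
        g = nx.MultiGraph()
        for v in self.veins.values():
            g.add_edge(v.tail, v.head, key=v.id, vein=v)
        return g

    def resistances(self, fluid: FluidProperties) -> dict[str, float]:
        """Per-vein Poiseuille resistances in Pa·s/m³."""
        return {vid: v.resistance(fluid) for vid, v in self.veins.items()}

    def replace_vein(self, vein_id: str, **changes) -> "VeinNetwork":
        """Copy of the network with one vein's fields replaced."""
        if vein_id not in self.veins:
            raise KeyError(f"no vein {vein_id!r} in network")
        veins = [replace(v, **changes) if vid == vein_id else v
                 for vid, v in self.veins.items()]
        return VeinNetwork(veins, self.inlet, self.outlet, self.node_coords)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "nodes": [
                {"id": n, **({"x_um": self.node_coords[n][0],
                              "y_um": self.node_coords[n][1]}
                             if n in self.node_coords else {})}
                for n in sorted(self.nodes)
            ],
            "veins": [
                {"id": v.id, "class": v.vein_class, "tail": v.tail,
                 "head": v.head, "length_um": v.length_um,
                 "inner_diameter_um": v.diameter_um}
                for v in self.veins.values()
            ],
            "inlet": self.inlet,
            "outlet": self.outlet,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "VeinNetwork":
        try:
            doc = json.loads(text)
            veins = [VeinSegment(r["id"], r["class"], r["tail"], r["head"],
                                 r["length_um"], r["inner_diameter_um"])
                     for r in doc["veins"]]
            coords = {n["id"]: (n["x_um"], n["y_um"])
                      for n in doc["nodes"] if "x_um" in n}
            declared = {n["id"] for n in doc["nodes"]}
        except (KeyError, TypeError, json.JSONDecodeError) as exc:
            raise FixtureError(f"malformed network document: {exc}") from exc
        net = cls(veins, doc["inlet"], doc["outlet"], coords)
        missing = net.nodes - declared
        if missing:
            raise FixtureError(f"vein endpoints not declared as nodes: {sorted(missing)}")
        return net

    def to_graphml(self, path) -> None:
        g = nx.MultiGraph()
        for n in sorted(self.nodes):
            attrs = {}
            if n in self.node_coords:
                attrs = {"x_um": self.node_coords[n][0], "y_um": self.node_coords[n][1]}
            g.add_node(n, **attrs)
        for v in self.veins.values():
            g.add_edge(v.tail, v.head, key=v.id, vein_class=v.vein_class,
                       length_um=v.length_um, inner_diameter_um=v.diameter_um)
        g.graph["inlet"] = self.inlet
        g.graph["outlet"] = self.outlet
        nx.write_graphml(g, path)
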