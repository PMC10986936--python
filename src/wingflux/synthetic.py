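"""Synthetic networks and cells with known ground truth.

Every generator is a pure function of its configuration (identical seeds
reproduce identical outputs), so solver and geometry code can be exercised
against closed-form oracles without touching the packaged wing fixture.
Default geometry ranges span the measured vein table: lengths 69–1900 μm,
inner diameters 1.7–12 μm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from . import drosophila
from .membrane import SimplifiedCell, build_simplified_cell
from .network import VeinNetwork, VeinSegment

__all__ = [
    "GeneratorConfig",
    "random_ladder",
    "random_series_parallel",
    "perturbed_forewing",
    "synthetic_cell",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared knobs for the synthetic generators.

    `n_rungs` sizes ladders (rung count) and series-parallel networks
    (composition leaves).  Length/diameter ranges are sampled uniformly.
    Jitter bounds for ``perturbed_forewing`` default to the stated average
    measurement errors of the imaging pipeline (0.92% on lengths, 15% on
    diameters).
    """

    seed: int = 0
    n_rungs: int = 6
    length_range_um: tuple[float, float] = (6.9e1, 1.9e3)
    diameter_range_um: tuple[float, float] = (1.7, 12.0)
    topology: str = "ladder"
    symmetric: bool = False
    length_jitter: float = 0.0092
    diameter_jitter: float = 0.15

    def __post_init__(self) -> None:
        if self.n_rungs < 1:
            raise ValueError("n_rungs must be at least 1")
        for lo, hi in (self.length_range_um, self.diameter_range_um):
            if lo <= 0 or hi < lo:
                raise ValueError("ranges must be positive and ordered")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _draw_geometry(rng, config) -> tuple[float, float]:
    length = rng.uniform(*config.length_range_um)
    diameter = rng.uniform(*config.diameter_range_um)
    return length, diameter


def random_ladder(config: GeneratorConfig) -> VeinNetwork:
    """Two rails from IN to OUT joined by `n_rungs` rungs.

    With ``symmetric=True`` the base rail duplicates the edge rail's
    geometry, so the network is invariant under swapping the rails and the
    solved flows must respect that mirror symmetry.
    """
    rng = config.rng()
    n = config.n_rungs
    veins = []
    edge_geo = [_draw_geometry(rng, config) for _ in range(n + 1)]
    base_geo = (edge_geo if config.symmetric
                else [_draw_geometry(rng, config) for _ in range(n + 1)])
    rung_geo = [_draw_geometry(rng, config) for _ in range(n)]
    t = ["IN"] + [f"t{i}" for i in range(1, n + 1)] + ["OUT"]
    b = ["IN"] + [f"b{i}" for i in range(1, n + 1)] + ["OUT"]
    for i in range(n + 1):
        l, d = edge_geo[i]
        veins.append(VeinSegment(f"E{i + 1}", "edge", t[i], t[i + 1], l, d))
        l, d = base_geo[i]
        veins.append(VeinSegment(f"B{i + 1}", "base", b[i], b[i + 1], l, d))
    for i in range(1, n + 1):
        l, d = rung_geo[i - 1]
        veins.append(VeinSegment(f"C{i}", "connecting", f"t{i}", f"b{i}", l, d))
    return VeinNetwork(veins, inlet="IN", outlet="OUT")


def random_series_parallel(config: GeneratorConfig, fluid=None):
    """A series-parallel network plus its closed-form equivalent resistance.

    The network is grown by recursive series/parallel composition of single
    veins; the same composition tree reduced with ``R_series = R₁ + R₂`` and
    ``R_parallel = (1/R₁ + 1/R₂)⁻¹`` yields the exact equivalent resistance,
    which serves as an independent oracle for the circuit solvers.

    Returns ``(network, equivalent_resistance)``; the resistance is in
    Pa·s/m³ and computed for `fluid` (haemolymph constants by default).
    """
    from .network import HAEMOLYMPH, hydraulic_resistance
    fluid = fluid or HAEMOLYMPH
    rng = config.rng()
    counter = [0]
    veins: list[VeinSegment] = []

    def fresh_node() -> str:
        counter[0] += 1
        return f"n{counter[0]}"

    def compose(n_leaves: int, a: str, z: str) -> float:
        if n_leaves == 1:
            length, diameter = _draw_geometry(rng, config)
            vid = f"v{len(veins) + 1}"
            veins.append(VeinSegment(vid, "connecting", a, z, length, diameter))
            return hydraulic_resistance(length, diameter, fluid, vein_id=vid)
        left = int(rng.integers(1, n_leaves))
        right = n_leaves - left
        if rng.random() < 0.5:  # series
            mid = fresh_node()
            return compose(left, a, mid) + compose(right, mid, z)
        r1 = compose(left, a, z)
        r2 = compose(right, a, z)
        return 1.0 / (1.0 / r1 + 1.0 / r2)

    r_eq = compose(max(config.n_rungs, 1), "IN", "OUT")
    return VeinNetwork(veins, inlet="IN", outlet="OUT"), r_eq


def perturbed_forewing(config: GeneratorConfig) -> VeinNetwork:
    """The wing fixture with multiplicative measurement jitter.

    Each vein's length and diameter are scaled by independent uniform
    factors within the configured jitter bounds — a simple model of the
    imaging uncertainty, for sensitivity reporting only.  Zero jitter
    reproduces the fixture exactly.
    """
    rng = config.rng()
    base = drosophila.build_drosophila_forewing()
    veins = []
    for v in base.veins.values():
        fl = rng.uniform(1 - config.length_jitter, 1 + config.length_jitter)
        fd = rng.uniform(1 - config.diameter_jitter, 1 + config.diameter_jitter)
        veins.append(dc_replace(v, length_um=v.length_um * fl,
                                diameter_um=v.diameter_um * fd))
    return VeinNetwork(veins, base.inlet, base.outlet, base.node_coords)


def synthetic_cell(config: GeneratorConfig, max_tries: int = 200) -> SimplifiedCell:
    """A random convex quadrilateral-plus-arc cell with rung metadata.

    Corners are sampled with the base on the x-axis and both rungs rising at
    moderate random angles; candidates failing convexity or the chord/arc
    constraint are rejected and redrawn.  Convexity guarantees that every
    straight cross-vein placement stays inside the cell.
    """
    rng = config.rng()
    for _ in range(max_tries):
        base = rng.uniform(*config.length_range_um)
        l_ant = rng.uniform(*config.length_range_um)
        l_post = rng.uniform(*config.length_range_um)
        a = math.radians(rng.uniform(55, 125))
        b = math.radians(rng.uniform(55, 125))
        q4 = (0.0, 0.0)
        q3 = (base, 0.0)
        q1 = (l_ant * math.cos(a), l_ant * math.sin(a))
        q2 = (base + l_post * math.cos(b), l_post * math.sin(b))
        chord = math.hypot(q2[0] - q1[0], q2[1] - q1[1])
        arc = chord * rng.uniform(1.0, 1.25)
        d_ant, d_post, d_edge, d_base, d_cross = (
            rng.uniform(*config.diameter_range_um) for _ in range(5))
        try:
            return build_simplified_cell(
                [q4, q1, q2, q3], arc,
                {"anterior_segments": [(1.0, d_ant)],
                 "posterior_segments": [(1.0, d_post)],
                 "edge_diameter_um": d_edge, "base_diameter_um": d_base},
                cell_id=f"synthetic-{config.seed}",
                cross_vein_diameter_um=d_cross)
        except ValueError:
            continue
    raise RuntimeError("could not draw a valid synthetic cell")
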