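"""Packaged *Drosophila melanogaster* forewing fixture.

The vein geometry table lists the 23 conduits of the forewing network with
measured lengths and inner (lumen) diameters; the membrane table lists the
eight membrane cells with their printed surface areas and the veins bounding
each.  Topologically the network is a ladder: an edge rail and a base rail
both running from the anterior inlet to the posterior outlet, joined by six
connecting veins ("rungs").  The posterior cross vein (PCV) breaks the
ladder symmetry by linking the fifth rung (split at Node A) to the sixth
(split at Node P).

The simplified-cell coordinate fixture is synthetic: corner positions were
calibrated so that model vein lengths and cell areas track the measured
tables (see the file's docstring and the methods note), because the original
wing-photograph coordinates are not part of the published tables.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .membrane import MembraneCell, SimplifiedCell, build_simplified_cell
from .network import FixtureError, VeinNetwork, VeinSegment

__all__ = [
    "load_vein_table",
    "load_membrane_table",
    "build_drosophila_forewing",
    "membrane_cells",
    "load_simplified_cell",
    "candidate_cells",
    "EXPECTED_VEIN_IDS",
    "PCV_LENGTH_UM",
    "PCV_DIAMETER_UM",
]

#: Measured posterior cross vein geometry; the substitute-vein diameter rule
#: matches l/d⁴ to this vein.
PCV_LENGTH_UM = 1.8e2
PCV_DIAMETER_UM = 3.1

EXPECTED_VEIN_IDS = tuple(
    [f"V_E_{i}" for i in range(1, 8)]
    + [f"V_B_{i}" for i in range(1, 8)]
    + [f"V_C_{i}" for i in range(1, 5)]
    + ["V_C_5_E", "V_C_5_B", "V_C_6_E", "V_C_6_B", "PCV"]
)

#: Canonical ladder topology (tail, head) per vein; rails run inlet → outlet,
#: rungs edge → base, the PCV from Node A to Node P.
FOREWING_TOPOLOGY = {
    **{f"V_E_{i}": (f"t{i - 1}" if i > 1 else "IN",
                    f"t{i}" if i < 7 else "OUT") for i in range(1, 8)},
    **{f"V_B_{i}": (f"b{i - 1}" if i > 1 else "IN",
                    f"b{i}" if i < 7 else "OUT") for i in range(1, 8)},
    **{f"V_C_{i}": (f"t{i}", f"b{i}") for i in range(1, 5)},
    "V_C_5_E": ("t5", "A"), "V_C_5_B": ("A", "b5"),
    "V_C_6_E": ("t6", "P"), "V_C_6_B": ("P", "b6"),
    "PCV": ("A", "P"),
}


def _data_text(name: str) -> str:
    return resources.files("wingflux.data").joinpath(name).read_text()


def load_vein_table() -> pd.DataFrame:
    """The packaged vein geometry table (id, class, topology, l, d)."""
    import io
    return pd.read_csv(io.StringIO(_data_text("forewing_veins.csv")))


def load_membrane_table() -> pd.DataFrame:
    """Membrane cells: printed surface areas and bounding-vein lists.

    The printed contact-area column is retained for reference only; every
    operation recomputes A_C from the vein table with ``(π/2) Σ l d``, which
    is the definition consistent with the published area ratios.
    """
    import io
    df = pd.read_csv(io.StringIO(_data_text("membrane_cells.csv")))
    df["bounding_vein_ids"] = df["bounding_vein_ids"].str.split(";")
    return df


def build_drosophila_forewing(geometry_table: pd.DataFrame | None = None) -> VeinNetwork:
    """The 23-vein forewing network (16 nodes, inlet ``IN``, outlet ``OUT``).

    Parameters
    ----------
    geometry_table : DataFrame, optional
        Vein geometry records with columns ``id, class, length_um,
        inner_diameter_um`` (and optionally ``tail, head``).  Rows must cover
        exactly the 23 fixture veins; topology defaults to the canonical
        ladder above.  Omit to use the packaged table.
    """
    table = load_vein_table() if geometry_table is None else geometry_table
    ids = list(table["id"])
    missing = set(EXPECTED_VEIN_IDS) - set(ids)
    extra = set(ids) - set(EXPECTED_VEIN_IDS)
    if missing or len(ids) != len(set(ids)):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise FixtureError(
            f"bad vein table: missing {sorted(missing)}, duplicated {dups}")
    if extra:
        raise FixtureError(f"bad vein table: unknown vein ids {sorted(extra)}")

    has_topology = {"tail", "head"}.issubset(table.columns)
    veins = []
    for row in table.to_dict("records"):
        tail, head = ((row["tail"], row["head"]) if has_topology
                      else FOREWING_TOPOLOGY[row["id"]])
        veins.append(VeinSegment(
            id=row["id"],
            vein_class=row["class"],
            tail=tail, head=head,
            length_um=float(row["length_um"]),
            diameter_um=float(row["inner_diameter_um"]),
        ))
    return VeinNetwork(veins, inlet="IN", outlet="OUT")


def membrane_cells(membrane_table: pd.DataFrame | None = None) -> list[MembraneCell]:
    """The eight fixture membrane cells (M1–M5, M6_E, M6_B, M7)."""
    table = load_membrane_table() if membrane_table is None else membrane_table
    return [
        MembraneCell(id=row.cell_id,
                     surface_area_um2=float(row.surface_area_um2),
                     bounding_veins=tuple(row.bounding_vein_ids))
        for row in table.itertuples(index=False)
    ]


def undivided_m6(membrane_table: pd.DataFrame | None = None) -> MembraneCell:
    """The sixth membrane cell merged back across the PCV.

    Surface area is the sum of the two divided parts; the bounding loop is
    the outer boundary (both rungs in full, edge and base veins) without the
    PCV itself.
    """
    table = load_membrane_table() if membrane_table is None else membrane_table
    parts = table[table["cell_id"].isin(["M6_E", "M6_B"])]
    return MembraneCell(
        id="M6",
        surface_area_um2=float(parts["surface_area_um2"].sum()),
        bounding_veins=("V_E_6", "V_B_6", "V_C_5_E", "V_C_5_B",
                        "V_C_6_E", "V_C_6_B"),
    )


def _load_cell_doc() -> dict:
    return json.loads(_data_text("simplified_cells_synthetic.json"))


def load_simplified_cell(cell_id: str = "M6") -> SimplifiedCell:
    """A calibrated simplified-cell model (synthetic corner coordinates).

    ``M6`` is the PCV's host cell; ``M2``–``M5`` are the candidate host
    cells for substitute cross veins (each bounded by two connecting veins).
    """
    doc = _load_cell_doc()
    if cell_id not in doc:
        raise KeyError(f"no simplified cell {cell_id!r}; have {sorted(doc)}")
    c = doc[cell_id]
    return build_simplified_cell(
        {k: tuple(c[k]) for k in ("base_anterior", "edge_anterior",
                                  "edge_posterior", "base_posterior")},
        measured_edge_length_um=c["edge_arc_length_um"],
        rung_geometries={
            "anterior_segments": c["anterior_segments"],
            "posterior_segments": c["posterior_segments"],
            "edge_diameter_um": c["edge_diameter_um"],
            "base_diameter_um": c["base_diameter_um"],
            "anterior_vein": c["anterior_vein"],
            "posterior_vein": c["posterior_vein"],
            "edge_vein": c["edge_vein"],
            "base_vein": c["base_vein"],
        },
        cell_id=cell_id,
        nominal_fractions=c.get("nominal_fractions"),
        cross_vein_diameter_um=c.get("cross_vein_diameter_um"),
        measured_lengths_um=c.get("measured_lengths_um"),
    )


def candidate_cells() -> list[SimplifiedCell]:
    """Substitution-experiment host cells M2–M5, in order."""
    return [load_simplified_cell(cid) for cid in ("M2", "M3", "M4", "M5")]
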