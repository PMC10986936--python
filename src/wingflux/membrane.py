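"""Membrane-cell surface/contact-area model and the simplified divided cell.

A membrane cell is a patch of wing membrane enclosed by a loop of veins.
Its exposed surface area counts both faces, ``A_S = 2 A_m``; its contact
area with the surrounding veins counts half of each vein's wall,
``A_C = Σ π l_n d_n / 2``.  The ratio ``A_S / A_C`` equals, by water mass
conservation, the factor by which the seepage velocity out of the veins
must exceed the evaporation velocity off the membrane.

The simplified divided cell replaces the sixth membrane cell's boundary by
straight segments (base vein and the two connecting veins) plus one
circular arc (the edge vein), and lets the posterior cross vein's two
attachment points slide along the connecting veins.  ``scan_pcv_positions``
evaluates the edge-side cell's ``A_S / A_C`` over the whole attachment grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from shapely.geometry import Polygon

__all__ = [
    "MembraneCell",
    "SimplifiedCell",
    "RatioScan",
    "GeometryError",
    "ScanError",
    "contact_area",
    "area_ratio",
    "required_velocity_ratio",
    "build_simplified_cell",
    "scan_pcv_positions",
]


class GeometryError(ValueError):
    """A simplified cell's corner/arc data is geometrically inconsistent."""


class ScanError(RuntimeError):
    """An attachment scan produced no valid placement."""


# ---------------------------------------------------------------------------
# flat-table operations
# ---------------------------------------------------------------------------

def _vein_row(geometry_table: pd.DataFrame, vein_id: str) -> pd.Series:
    hit = geometry_table.loc[geometry_table["id"] == vein_id]
    if hit.empty:
        raise KeyError(f"vein {vein_id!r} not found in geometry table")
    return hit.iloc[0]


def contact_area(vein_ids, geometry_table: pd.DataFrame) -> float:
    """Total vein-contact area ``(π/2) Σ l_n d_n`` in μm².

    Each bounding vein contributes half of its wall area, because a membrane
    cell touches one side of the vein only.
    """
    ids = list(vein_ids)
    if not ids:
        raise ValueError("a membrane cell needs at least one bounding vein")
    total = 0.0
    for vid in ids:
        row = _vein_row(geometry_table, vid)
        total += row["length_um"] * row["inner_diameter_um"]
    return 0.5 * math.pi * total


@dataclass(frozen=True)
class MembraneCell:
    """A membrane cell: both-sided surface area plus its bounding veins."""

    id: str
    surface_area_um2: float
    bounding_veins: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.surface_area_um2 <= 0:
            raise ValueError(f"cell {self.id!r}: surface area must be positive")
        if not self.bounding_veins:
            raise ValueError(f"cell {self.id!r}: no bounding veins")


def area_ratio(cell: MembraneCell, geometry_table: pd.DataFrame) -> float:
    """Surface-to-contact ratio ``A_S / A_C`` (dimensionless)."""
    return cell.surface_area_um2 / contact_area(cell.bounding_veins, geometry_table)


def required_velocity_ratio(cell: MembraneCell, geometry_table: pd.DataFrame) -> float:
    """Seepage-to-evaporation velocity ratio ``v_in / v_out``.

    Water seeps from the veins through the contact area and leaves by
    evaporation through the membrane surface; steady mass balance
    ``v_in A_C = v_out A_S`` makes the required velocity ratio exactly
    ``A_S / A_C``.
    """
    return area_ratio(cell, geometry_table)


# ---------------------------------------------------------------------------
# circular-arc helpers
# ---------------------------------------------------------------------------

def _arc_half_angle(chord: float, arc_length: float) -> float:
    """Half-angle θ of a circular arc with given chord and length.

    Solves ``sin θ / θ = chord / arc_length``; θ → 0 is the straight limit.
    """
    if chord > arc_length * (1 + 1e-12):
        raise GeometryError(
            f"arc length {arc_length} shorter than its chord {chord}")
    ratio = min(chord / arc_length, 1.0)
    if ratio >= 1.0 - 1e-12:
        return 0.0
    return brentq(lambda t: math.sin(t) / t - ratio, 1e-12, math.pi - 1e-12)


def _arc_segment_area(chord: float, arc_length: float) -> float:
    """Area between the arc and its chord (zero in the straight limit)."""
    theta = _arc_half_angle(chord, arc_length)
    if theta == 0.0:
        return 0.0
    radius = arc_length / (2.0 * theta)
    return radius * radius * (theta - math.sin(theta) * math.cos(theta))


def _polyline_shoelace(x: np.ndarray, y: np.ndarray) -> float:
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


# ---------------------------------------------------------------------------
# the simplified divided cell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimplifiedCell:
    """Quadrilateral cell with straight veins plus one circular-arc edge vein.

    Corners, in boundary order: base_anterior → edge_anterior (anterior
    connecting vein), edge_anterior → edge_posterior (edge-vein arc, bulging
    away from the cell), edge_posterior → base_posterior (posterior
    connecting vein), base_posterior → base_anterior (base vein).

    Attachment positions are fractions of each connecting vein measured from
    its base end (the fraction is the base-side segment's share of the rung).
    ``anterior_segments``/``posterior_segments`` list ``(fraction, diameter)``
    pieces of each rung from base to edge, so rungs composed of two measured
    segments with different lumen diameters are represented exactly.
    """

    id: str
    base_anterior: tuple[float, float]
    edge_anterior: tuple[float, float]
    edge_posterior: tuple[float, float]
    base_posterior: tuple[float, float]
    edge_arc_length_um: float
    edge_diameter_um: float
    base_diameter_um: float
    anterior_segments: tuple[tuple[float, float], ...]
    posterior_segments: tuple[tuple[float, float], ...]
    anterior_vein: str = "anterior"
    posterior_vein: str = "posterior"
    edge_vein: str = "edge"
    base_vein: str = "base"
    nominal_fractions: tuple[float, float] | None = None
    cross_vein_diameter_um: float | None = None
    measured_lengths_um: dict | None = None

    # -- model geometry ---------------------------------------------------
    @property
    def corners(self) -> np.ndarray:
        return np.array([self.base_anterior, self.edge_anterior,
                         self.edge_posterior, self.base_posterior], float)

    @property
    def anterior_length_um(self) -> float:
        return float(np.hypot(*(np.subtract(self.edge_anterior, self.base_anterior))))

    @property
    def posterior_length_um(self) -> float:
        return float(np.hypot(*(np.subtract(self.edge_posterior, self.base_posterior))))

    @property
    def base_length_um(self) -> float:
        return float(np.hypot(*(np.subtract(self.base_posterior, self.base_anterior))))

    @property
    def chord_um(self) -> float:
        return float(np.hypot(*(np.subtract(self.edge_posterior, self.edge_anterior))))

    @property
    def arc_segment_area_um2(self) -> float:
        return _arc_segment_area(self.chord_um, self.edge_arc_length_um)

    @property
    def quad_area_um2(self) -> float:
        c = self.corners
        return abs(_polyline_shoelace(c[:, 0], c[:, 1]))

    @property
    def area_um2(self) -> float:
        """Model membrane area A_m: quadrilateral plus the arc bulge."""
        return self.quad_area_um2 + self.arc_segment_area_um2

    def attachment_points(self, f_anterior, f_posterior):
        """Cartesian attachment points for base-side fractions (arrays ok)."""
        fa = np.asarray(f_anterior, float)
        fp = np.asarray(f_posterior, float)
        q4, q1, q2, q3 = self.corners
        ax = q4[0] + fa * (q1[0] - q4[0])
        ay = q4[1] + fa * (q1[1] - q4[1])
        px = q3[0] + fp * (q2[0] - q3[0])
        py = q3[1] + fp * (q2[1] - q3[1])
        return (ax, ay), (px, py)

    def cross_vein_length_um(self, f_anterior, f_posterior):
        (ax, ay), (px, py) = self.attachment_points(f_anterior, f_posterior)
        return np.hypot(ax - px, ay - py)

    def _rung_contact_ld(self, segments, frac, side: str):
        """Σ l·d of one rung's edge- or base-side part, piecewise diameters."""
        frac = np.asarray(frac, float)
        length = {"anterior": self.anterior_length_um,
                  "posterior": self.posterior_length_um}[
                      "anterior" if segments is self.anterior_segments
                      else "posterior"]
        total = np.zeros_like(frac)
        lo = 0.0
        for width, dia in segments:
            hi = lo + width
            inside = np.clip(frac, lo, hi) - lo
            if side == "base":
                total = total + inside * length * dia
            else:
                total = total + (width - inside) * length * dia
            lo = hi
        return total

    def divided_areas(self, f_anterior, f_posterior):
        """(edge-side, base-side) membrane areas A_m for given fractions.

        The straight cross vein is a chord of the cell, so the two parts sum
        to the whole cell area for every placement.
        """
        fa = np.asarray(f_anterior, float)
        fp = np.asarray(f_posterior, float)
        (ax, ay), (px, py) = self.attachment_points(fa, fp)
        q4, q1, q2, q3 = self.corners
        edge_quad = 0.5 * np.abs(
            ax * (q1[1] - py) + q1[0] * (q2[1] - ay)
            + q2[0] * (py - q1[1]) + px * (ay - q2[1]))
        base_quad = 0.5 * np.abs(
            q4[0] * (ay - q3[1]) + ax * (py - q4[1])
            + px * (q3[1] - ay) + q3[0] * (q4[1] - py))
        return edge_quad + self.arc_segment_area_um2, base_quad

    def contact_areas(self, f_anterior, f_posterior, cross_diameter_um):
        """(edge-side, base-side) contact areas A_C in μm² (arrays ok)."""
        fa = np.asarray(f_anterior, float)
        fp = np.asarray(f_posterior, float)
        lcv = self.cross_vein_length_um(fa, fp)
        dcv = np.asarray(cross_diameter_um, float)
        edge = (self.edge_arc_length_um * self.edge_diameter_um
                + self._rung_contact_ld(self.anterior_segments, fa, "edge")
                + self._rung_contact_ld(self.posterior_segments, fp, "edge")
                + lcv * dcv)
        base = (self.base_length_um * self.base_diameter_um
                + self._rung_contact_ld(self.anterior_segments, fa, "base")
                + self._rung_contact_ld(self.posterior_segments, fp, "base")
                + lcv * dcv)
        return 0.5 * math.pi * edge, 0.5 * math.pi * base

    def boundary_contact_area(self) -> float:
        """A_C of the undivided cell boundary (no cross vein), μm²."""
        edge, base = self.contact_areas(0.5, 0.5, 0.0)
        return float(edge + base)

    # -- boundary as a polyline ------------------------------------------
    def arc_points(self, n: int = 128) -> np.ndarray:
        """Points along the edge-vein arc from edge_anterior to edge_posterior."""
        q1 = np.asarray(self.edge_anterior, float)
        q2 = np.asarray(self.edge_posterior, float)
        theta = _arc_half_angle(self.chord_um, self.edge_arc_length_um)
        if theta == 0.0:
            t = np.linspace(0, 1, n)[:, None]
            return q1 + t * (q2 - q1)
        radius = self.edge_arc_length_um / (2 * theta)
        mid = 0.5 * (q1 + q2)
        chord_vec = q2 - q1
        normal = np.array([-chord_vec[1], chord_vec[0]])
        normal /= np.linalg.norm(normal)
        centroid = self.corners.mean(axis=0)
        if np.dot(centroid - mid, normal) < 0:
            normal = -normal  # make it point into the cell
        centre = mid + normal * radius * math.cos(theta)
        a1 = math.atan2(*(q1 - centre)[::-1])
        a2 = math.atan2(*(q2 - centre)[::-1])
        # sweep the short way around that does NOT pass the centre side:
        # the apex sits opposite the interior normal
        sweep = (a2 - a1) % (2 * math.pi)
        apex = centre - normal * radius
        a_apex = math.atan2(*(apex - centre)[::-1])
        if not _angle_between(a1, a1 + sweep, a_apex):
            sweep = sweep - 2 * math.pi
        angles = a1 + np.linspace(0, sweep, n)
        return centre + radius * np.column_stack([np.cos(angles), np.sin(angles)])

    def boundary_polyline(self, arc_points: int = 128) -> np.ndarray:
        """Closed boundary: base_anterior → edge_anterior → arc → … → back."""
        q4, q1, q2, q3 = self.corners
        arc = self.arc_points(arc_points)
        return np.vstack([q4, arc, q3, q4])

    def polygon(self, arc_points: int = 128) -> Polygon:
        poly = Polygon(self.boundary_polyline(arc_points)[:-1])
        if not poly.is_valid:
            raise GeometryError(f"cell {self.id!r}: boundary is not simple")
        return poly


def _angle_between(a_from: float, a_to: float, a: float) -> bool:
    """Is angle `a` on the swept interval from a_from to a_to (either sense)?"""
    lo, hi = sorted((a_from, a_to))
    two_pi = 2 * math.pi
    a_norm = (a - lo) % two_pi
    return a_norm <= (hi - lo) + 1e-12


def _convex_position(corners: np.ndarray) -> bool:
    crosses = []
    for k in range(4):
        a, b, c = corners[k], corners[(k + 1) % 4], corners[(k + 2) % 4]
        u, v = b - a, c - b
        crosses.append(u[0] * v[1] - u[1] * v[0])
    return all(v > 0 for v in crosses) or all(v < 0 for v in crosses)


def build_simplified_cell(corner_coordinates, measured_edge_length_um: float,
                          rung_geometries: dict, *, cell_id: str = "cell",
                          nominal_fractions=None,
                          cross_vein_diameter_um: float | None = None,
                          measured_lengths_um: dict | None = None,
                          require_convex: bool = True) -> SimplifiedCell:
    """Assemble and validate a simplified divided cell.

    Parameters
    ----------
    corner_coordinates : mapping or sequence
        The four corners ``base_anterior, edge_anterior, edge_posterior,
        base_posterior`` in μm (a dict with those keys, or a sequence in
        that order).
    measured_edge_length_um : float
        Measured edge-vein length; becomes the arc length, which fixes the
        arc radius given the chord between the two edge corners.
    rung_geometries : dict
        ``anterior_segments`` / ``posterior_segments`` as (fraction,
        diameter μm) pieces from base to edge, plus ``edge_diameter_um`` and
        ``base_diameter_um``.
    """
    if isinstance(corner_coordinates, dict):
        seq = [corner_coordinates[k] for k in
               ("base_anterior", "edge_anterior", "edge_posterior", "base_posterior")]
    else:
        seq = list(corner_coordinates)
    corners = np.array(seq, float)
    if corners.shape != (4, 2):
        raise GeometryError("expected four 2-D corner coordinates")
    if require_convex and not _convex_position(corners):
        raise GeometryError(f"cell {cell_id!r}: corners are not in convex position")

    def _norm_segments(segs):
        segs = tuple((float(f), float(d)) for f, d in segs)
        total = sum(f for f, _ in segs)
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise GeometryError("rung segment fractions must sum to 1")
        return segs

    cell = SimplifiedCell(
        id=cell_id,
        base_anterior=tuple(corners[0]),
        edge_anterior=tuple(corners[1]),
        edge_posterior=tuple(corners[2]),
        base_posterior=tuple(corners[3]),
        edge_arc_length_um=float(measured_edge_length_um),
        edge_diameter_um=float(rung_geometries["edge_diameter_um"]),
        base_diameter_um=float(rung_geometries["base_diameter_um"]),
        anterior_segments=_norm_segments(rung_geometries["anterior_segments"]),
        posterior_segments=_norm_segments(rung_geometries["posterior_segments"]),
        anterior_vein=rung_geometries.get("anterior_vein", "anterior"),
        posterior_vein=rung_geometries.get("posterior_vein", "posterior"),
        edge_vein=rung_geometries.get("edge_vein", "edge"),
        base_vein=rung_geometries.get("base_vein", "base"),
        nominal_fractions=tuple(nominal_fractions) if nominal_fractions else None,
        cross_vein_diameter_um=cross_vein_diameter_um,
        measured_lengths_um=measured_lengths_um,
    )
    if cell.chord_um > cell.edge_arc_length_um * (1 + 1e-9):
        raise GeometryError(
            f"cell {cell_id!r}: measured edge length {measured_edge_length_um} "
            f"is shorter than the chord {cell.chord_um:.1f}")
    cell.polygon(64)  # raises if the boundary self-intersects
    return cell


# ---------------------------------------------------------------------------
# the attachment-position scan
# ---------------------------------------------------------------------------

@dataclass
class RatioScan:
    """Grid of edge-side ``A_S / A_C`` over cross-vein attachment fractions.

    Invalid placements (straight cross vein leaving the cell) are masked,
    not zeroed: `ratio` holds NaN there and `valid` is False.
    """

    cell_id: str
    f_anterior: np.ndarray
    f_posterior: np.ndarray
    ratio: np.ndarray          # shape (len(f_anterior), len(f_posterior))
    valid: np.ndarray          # same shape, bool
    argmax_fractions: tuple[float, float]
    max_ratio: float

    def to_frame(self) -> pd.DataFrame:
        fa, fp = np.meshgrid(self.f_anterior, self.f_posterior, indexing="ij")
        return pd.DataFrame({
            "fa": fa.ravel(), "fp": fp.ravel(),
            "ratio": self.ratio.ravel(), "valid": self.valid.ravel(),
        })


def _segment_crossings(ax, ay, px, py, boundary: np.ndarray) -> np.ndarray:
    """Count proper crossings of each A–P segment with the boundary polyline.

    Touching at the segment endpoints (which lie on the boundary by
    construction) does not count; only strict transversal crossings do.
    """
    b0 = boundary[:-1]
    b1 = boundary[1:]
    ax, ay, px, py = (np.asarray(v, float)[..., None] for v in (ax, ay, px, py))
    rx, ry = px - ax, py - ay
    sx = (b1[:, 0] - b0[:, 0])[None, :]
    sy = (b1[:, 1] - b0[:, 1])[None, :]
    qpx = b0[None, :, 0] - ax
    qpy = b0[None, :, 1] - ay
    denom = rx * sy - ry * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (qpx * sy - qpy * sx) / denom
        u = (qpx * ry - qpy * rx) / denom
    eps = 1e-9
    crossing = (np.abs(denom) > 0) & (t > eps) & (t < 1 - eps) & (u > -eps) & (u < 1 + eps)
    return crossing.sum(axis=-1)


def scan_pcv_positions(cell: SimplifiedCell, step: float = 0.001,
                       cross_diameter=None, arc_points: int = 256) -> RatioScan:
    """Edge-side ``A_S / A_C`` over the whole attachment grid.

    Parameters
    ----------
    cell : SimplifiedCell
    step : float
        Grid increment for both fractions; the grid spans ``step … 1 − step``.
    cross_diameter : float, callable or None
        Inner diameter of the cross vein.  A float is used as-is; a callable
        receives the cross-vein length (μm) and returns the diameter (μm);
        None uses the cell's own ``cross_vein_diameter_um``.

    The edge-side cell's surface area is twice its membrane area; its
    contact veins are the full edge arc, the edge-side parts of both
    connecting veins, and the cross vein itself.
    """
    fs = np.round(np.arange(step, 1.0 - step / 2, step), 12)
    fa, fp = np.meshgrid(fs, fs, indexing="ij")
    (ax, ay), (px, py) = cell.attachment_points(fa, fp)

    lcv = np.hypot(ax - px, ay - py)
    if cross_diameter is None:
        if cell.cross_vein_diameter_um is None:
            raise ValueError("no cross-vein diameter given and none on the cell")
        dcv = np.full_like(lcv, cell.cross_vein_diameter_um)
    elif callable(cross_diameter):
        dcv = np.asarray(cross_diameter(lcv), float)
    else:
        dcv = np.full_like(lcv, float(cross_diameter))

    edge_area, _ = cell.divided_areas(fa, fp)
    edge_contact, _ = cell.contact_areas(fa, fp, dcv)
    ratio = 2.0 * edge_area / edge_contact

    n = len(fs)
    if _convex_position(cell.corners):
        # the cell contains its quadrilateral (the arc only adds area), and
        # every A–P segment is a chord of the convex quadrilateral
        valid = np.ones((n, n), dtype=bool)
    else:
        boundary = cell.boundary_polyline(arc_points)
        valid = np.empty(n * n, dtype=bool)
        flat = [v.ravel() for v in (ax, ay, px, py)]
        chunk = max(1, int(2e7 // (4 * len(boundary))))
        for start in range(0, n * n, chunk):
            sl = slice(start, min(start + chunk, n * n))
            crossings = _segment_crossings(flat[0][sl], flat[1][sl],
                                           flat[2][sl], flat[3][sl], boundary)
            valid[sl] = crossings == 0
        valid = valid.reshape(n, n)
    if not valid.any():
        raise ScanError(f"cell {cell.id!r}: no valid cross-vein placement")

    masked = np.where(valid, ratio, np.nan)
    flat = np.nanargmax(masked)
    i, j = np.unravel_index(flat, masked.shape)
    return RatioScan(
        cell_id=cell.id,
        f_anterior=fs, f_posterior=fs,
        ratio=masked, valid=valid,
        argmax_fractions=(float(fs[i]), float(fs[j])),
        max_ratio=float(masked[i, j]),
    )
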