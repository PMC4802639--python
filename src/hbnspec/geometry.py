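"""Hydrogen-bond-network (HBN) geometry of SWS1 visual pigments.

The HBN around the retinal Schiff base is formed by the amino acids at
bovine-rhodopsin sites 86, 90, 113, 114, 118 and 295 together with two
water molecules.  Its geometry is summarised by two areas: area A spanned
by the residues at sites 90, 113 and 118 (containing the Schiff-base
nitrogen and the E113 counterion), and area B spanned by the residues at
sites 86, 90, 118 and 295 (containing the two waters).  The dimensionless
A/B ratio is the structural signature separating UV-sensitive from
violet-sensitive pigments.

Two area conventions are supported:

``distance-heron``
    Residue-residue separations are the *shortest* heavy-atom distances
    (the dotted lines of a contact map); areas follow from Heron's
    formula, the quadrilateral being split along a diagonal.

``coordinate-polygon``
    Each residue is collapsed to a representative point (side-chain
    heavy-atom centroid by default, Cα for glycine) and the polygon area
    is computed by the shoelace formula after projection onto the
    best-fit plane.

For planar, single-atom-per-residue inputs the two conventions agree
exactly; for real side chains they differ and the choice is reported in
the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

#: Bovine-rhodopsin site numbers forming the hydrogen-bond network.
HBN_SITES = (86, 90, 91, 113, 114, 118, 295)

#: Backbone heavy atoms excluded from the side-chain centroid.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

AREA_TOL = 1e-9


class MissingSiteError(KeyError):
    """A required HBN site (or the Schiff-base nitrogen) is absent."""


class DegenerateGeometryError(ValueError):
    """The requested area is not well defined (e.g. zero area B or a
    triangle-inequality violation beyond tolerance)."""


@dataclass
class HBNStructure:
    """Heavy-atom coordinates of the HBN sites of one pigment.

    Parameters
    ----------
    pigment_id:
        Free-form identifier, e.g. ``"AncVertebrate-361"``.
    residues:
        Map from bovine-rhodopsin site number to ``{atom_name: (x, y, z)}``
        in Å.  Site 86 may be absent (scabbardfish-like pigments); site 91
        then substitutes for it in area B.
    sb_nitrogen:
        Coordinate of the retinal Schiff-base nitrogen, or ``None``.
    waters:
        Up to two labelled water-oxygen coordinates.
    """

    pigment_id: str
    residues: Dict[int, Dict[str, np.ndarray]]
    sb_nitrogen: Optional[np.ndarray] = None
    waters: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residues = {
            int(site): {name: np.asarray(xyz, dtype=float) for name, xyz in atoms.items()}
            for site, atoms in self.residues.items()
        }
        for site, atoms in self.residues.items():
            if not atoms:
                raise ValueError(f"site {site} has no atoms")
            for name, xyz in atoms.items():
                if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                    raise ValueError(f"site {site} atom {name}: bad coordinate {xyz}")
        if self.sb_nitrogen is not None:
            self.sb_nitrogen = np.asarray(self.sb_nitrogen, dtype=float)
            if self.sb_nitrogen.shape != (3,) or not np.all(np.isfinite(self.sb_nitrogen)):
                raise ValueError("Schiff-base nitrogen coordinate is not a finite 3-vector")
        self.waters = {k: np.asarray(v, dtype=float) for k, v in self.waters.items()}

    @property
    def site86_present(self) -> bool:
        return 86 in self.residues

    def atoms(self, site: int) -> np.ndarray:
        """(n, 3) array of heavy-atom coordinates at a site."""
        if site not in self.residues:
            raise MissingSiteError(f"site {site} absent from {self.pigment_id!r}")
        return np.vstack(list(self.residues[site].values()))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "HBNStructure":
        """Rigidly transformed copy (used by invariance checks)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        move = lambda x: R @ x + t
        return HBNStructure(
            pigment_id=self.pigment_id,
            residues={s: {n: move(x) for n, x in a.items()} for s, a in self.residues.items()},
            sb_nitrogen=None if self.sb_nitrogen is None else move(self.sb_nitrogen),
            waters={k: move(v) for k, v in self.waters.items()},
        )


@dataclass
class HBNGeometry:
    """Derived HBN geometry: areas (Å²), sub-areas, A/B ratio and the
    counterion–Schiff-base distance (Å)."""

    pigment_id: str
    area_A: float
    area_B: float
    ab_ratio: float
    convention: str
    sub_A: Optional[Tuple[float, float, float]] = None
    sub_B: Optional[Tuple[float, float, float]] = None
    counterion_sb: Optional[float] = None
    site86_substituted: bool = False

    def validate(self) -> None:
        if self.area_A < 0 or self.area_B <= 0:
            raise DegenerateGeometryError("areas must satisfy A >= 0, B > 0")
        if not math.isclose(self.ab_ratio, self.area_A / self.area_B, rel_tol=AREA_TOL):
            raise ValueError("ab_ratio inconsistent with area_A/area_B")
        for sub, parent in ((self.sub_A, self.area_A), (self.sub_B, self.area_B)):
            if sub is not None and not math.isclose(sum(sub), parent, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError("sub-areas do not partition their parent area")


def min_residue_distance(structure: HBNStructure, site_i: int, site_j: int) -> float:
    """Shortest heavy-atom distance between two HBN residues (Å)."""
    return float(cdist(structure.atoms(site_i), structure.atoms(site_j)).min())


def heron_area(d12: float, d13: float, d23: float) -> float:
    """Triangle area from its three side lengths.

    Tiny negative radicands (numerical noise on collinear points) are
    clamped to zero; genuine triangle-inequality violations raise
    :class:`DegenerateGeometryError`.
    """
    sides = (d12, d13, d23)
    if any(d < 0 for d in sides):
        raise ValueError("side lengths must be non-negative")
    s = sum(sides) / 2.0
    radicand = s * (s - d12) * (s - d13) * (s - d23)
    if radicand < 0:
        if radicand > -1e-12:
            return 0.0
        if max(sides) > sum(sides) - max(sides) + AREA_TOL:
            raise DegenerateGeometryError(
                f"triangle inequality violated for sides {sides}"
            )
        return 0.0
    return math.sqrt(radicand)


def representative_point(structure: HBNStructure, site: int) -> np.ndarray:
    """Side-chain heavy-atom centroid; falls back to Cα (then to the
    all-atom centroid) when no side-chain atoms exist, as for glycine."""
    atoms = structure.residues.get(site)
    if atoms is None:
        raise MissingSiteError(f"site {site} absent from {structure.pigment_id!r}")
    side = [xyz for name, xyz in atoms.items() if name.upper() not in BACKBONE_ATOMS]
    if side:
        return np.mean(side, axis=0)
    if "CA" in atoms:
        return np.asarray(atoms["CA"], float)
    return np.mean(list(atoms.values()), axis=0)


def _triangle_area_coords(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(q - p, r - p)))


def _best_fit_plane(points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through ``points``: (centroid, unit normal)."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c)
    return c, vt[-1]


def _shoelace_area(points: np.ndarray) -> float:
    """Polygon area after projection onto the best-fit plane."""
    c, normal = _best_fit_plane(points)
    # orthonormal in-plane basis
    u = np.cross(normal, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-12:
        u = np.cross(normal, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    xy = np.column_stack(((points - c) @ u, (points - c) @ v))
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def area_A(
    structure: HBNStructure, convention: str = "distance-heron"
) -> Tuple[float, Optional[Tuple[float, float, float]]]:
    """Area A (sites 90, 113, 118) in Å², with sub-areas A1–A3 when the
    Schiff-base nitrogen is present.

    Sub-areas are the three triangles joining the nitrogen to each edge
    of the 90–113–118 triangle; they partition A exactly when the
    nitrogen lies inside the (planar) triangle.
    """
    sites = (90, 113, 118)
    if convention == "distance-heron":
        d = {
            (i, j): min_residue_distance(structure, i, j)
            for i, j in ((90, 113), (90, 118), (113, 118))
        }
        area = heron_area(d[(90, 113)], d[(90, 118)], d[(113, 118)])
        sub = None
        if structure.sb_nitrogen is not None:
            dn = {
                s: float(cdist(structure.sb_nitrogen[None, :], structure.atoms(s)).min())
                for s in sites
            }
            sub = (
                heron_area(dn[90], dn[113], d[(90, 113)]),
                heron_area(dn[113], dn[118], d[(113, 118)]),
                heron_area(dn[118], dn[90], d[(90, 118)]),
            )
        return area, sub
    if convention == "coordinate-polygon":
        p90, p113, p118 = (representative_point(structure, s) for s in sites)
        area = _triangle_area_coords(p90, p113, p118)
        sub = None
        if structure.sb_nitrogen is not None:
            n = structure.sb_nitrogen
            sub = (
                _triangle_area_coords(n, p90, p113),
                _triangle_area_coords(n, p113, p118),
                _triangle_area_coords(n, p118, p90),
            )
        return area, sub
    raise ValueError(f"unknown convention {convention!r}")


def _area_b_vertices(structure: HBNStructure) -> Tuple[Sequence[int], bool]:
    """Vertex sites for area B in polygon order, honouring the site-91
    substitution rule for pigments lacking site 86."""
    if structure.site86_present:
        return (86, 90, 118, 295), False
    if 91 in structure.residues:
        return (91, 90, 118, 295), True
    raise MissingSiteError(
        f"{structure.pigment_id!r} lacks site 86 and the site-91 substitute"
    )


def area_B(
    structure: HBNStructure,
    convention: str = "distance-heron",
    diagonal: Tuple[int, int] = (86, 118),
) -> Tuple[float, Optional[Tuple[float, float, float]], bool]:
    """Area B (quadrilateral over sites 86, 90, 118, 295) in Å².

    Returns ``(area, sub_areas, site86_substituted)``.  When site 86 is
    absent, site 91 stands in for it (scabbardfish rule).  Sub-areas
    B1–B3 are reported only when at least one water is supplied: the
    quadrilateral is fanned around the first water; the two triangles on
    the 118–295 / 295–86 edges are merged so three values are returned.

    ``diagonal`` selects the split used by the distance-heron convention
    (86–118 by default, 90–295 as the alternative).
    """
    verts, substituted = _area_b_vertices(structure)
    sub86 = verts[0]  # 86 or its 91 substitute
    if convention == "distance-heron":
        dg = tuple(sub86 if s == 86 else s for s in diagonal)
        if set(dg) == {sub86, 118}:
            tri1, tri2 = (sub86, 90, 118), (sub86, 118, 295)
        elif set(dg) == {90, 295}:
            tri1, tri2 = (90, sub86, 295), (90, 118, 295)
        else:
            raise ValueError(f"diagonal must join opposite vertices, got {diagonal}")
        dist = lambda i, j: min_residue_distance(structure, i, j)
        area = heron_area(dist(tri1[0], tri1[1]), dist(tri1[0], tri1[2]), dist(tri1[1], tri1[2])) + heron_area(
            dist(tri2[0], tri2[1]), dist(tri2[0], tri2[2]), dist(tri2[1], tri2[2])
        )
        points = None
    elif convention == "coordinate-polygon":
        points = np.vstack([representative_point(structure, s) for s in verts])
        area = _shoelace_area(points)
    else:
        raise ValueError(f"unknown convention {convention!r}")

    sub = None
    if structure.waters:
        w = next(iter(structure.waters.values()))
        if points is None:
            points = np.vstack([representative_point(structure, s) for s in verts])
        p86, p90, p118, p295 = points
        sub = (
            _triangle_area_coords(w, p86, p90),
            _triangle_area_coords(w, p90, p118),
            _triangle_area_coords(w, p118, p295) + _triangle_area_coords(w, p295, p86),
        )
    return area, sub, substituted


def counterion_sb_distance(structure: HBNStructure) -> float:
    """Shortest distance (Å) from the Schiff-base nitrogen to the E113
    counterion (any site-113 heavy atom)."""
    if structure.sb_nitrogen is None:
        raise MissingSiteError(
            f"{structure.pigment_id!r} has no Schiff-base nitrogen coordinate"
        )
    return float(cdist(structure.sb_nitrogen[None, :], structure.atoms(113)).min())


def ab_ratio(structure: HBNStructure, convention: str = "distance-heron") -> HBNGeometry:
    """Assemble the full :class:`HBNGeometry` (areas, ratio, sub-areas,
    counterion distance) for one structure."""
    a, sub_a = area_A(structure, convention)
    b, sub_b, substituted = area_B(structure, convention)
    if b <= 0:
        raise DegenerateGeometryError(
            f"area B of {structure.pigment_id!r} is degenerate (B = {b})"
        )
    ci = None
    if structure.sb_nitrogen is not None and 113 in structure.residues:
        ci = counterion_sb_distance(structure)
    return HBNGeometry(
        pigment_id=structure.pigment_id,
        area_A=a,
        area_B=b,
        ab_ratio=a / b,
        convention=convention,
        sub_A=sub_a,
        sub_B=sub_b,
        counterion_sb=ci,
        site86_substituted=substituted,
    )
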