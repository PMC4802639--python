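"""HBN geometry: distances, Heron/polygon areas, sub-areas, invariances."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from hbnspec.geometry import (
    DegenerateGeometryError,
    HBNStructure,
    MissingSiteError,
    ab_ratio,
    area_A,
    area_B,
    counterion_sb_distance,
    heron_area,
    min_residue_distance,
)


def single_atom_structure(points, sb=None, waters=None, pigment_id="t"):
    return HBNStructure(
        pigment_id=pigment_id,
        residues={site: {"X": np.asarray(p, float)} for site, p in points.items()},
        sb_nitrogen=sb,
        waters=waters or {},
    )


# --- heron_area -----------------------------------------------------------

@pytest.mark.parametrize(
    "sides, expected",
    [
        ((3, 4, 5), 6.0),
        ((1, 1, 1), math.sqrt(3) / 4),
        ((1, 1, 2), 0.0),
    ],
)
def test_heron_known_triangles(sides, expected):
    assert heron_area(*sides) == pytest.approx(expected, abs=1e-12)


def test_heron_symmetric_under_argument_permutations():
    for perm in itertools.permutations((2.0, 3.0, 4.0)):
        assert heron_area(*perm) == pytest.approx(heron_area(2.0, 3.0, 4.0), rel=1e-12)


def test_heron_rejects_impossible_triangle():
    with pytest.raises(DegenerateGeometryError):
        heron_area(1.0, 1.0, 5.0)
    with pytest.raises(ValueError):
        heron_area(-1.0, 1.0, 1.0)


# --- min_residue_distance -------------------------------------------------

def test_min_distance_pythagoras():
    s = single_atom_structure({90: (0, 0, 0), 113: (3, 4, 0)})
    assert min_residue_distance(s, 90, 113) == pytest.approx(5.0)
    assert min_residue_distance(s, 113, 90) == pytest.approx(5.0)


def test_min_distance_takes_minimum_over_atom_pairs():
    s = HBNStructure(
        "t",
        residues={
            90: {"A": [0, 0, 0], "B": [10, 0, 0]},
            113: {"A": [1, 0, 0]},
        },
    )
    assert min_residue_distance(s, 90, 113) == pytest.approx(1.0)


def test_min_distance_matches_exhaustive_enumeration(rng):
    for _ in range(50):
        a = rng.normal(size=(5, 3)) * 5
        b = rng.normal(size=(5, 3)) * 5
        s = HBNStructure(
            "t",
            residues={
                90: {f"a{i}": a[i] for i in range(5)},
                113: {f"b{i}": b[i] for i in range(5)},
            },
        )
        brute = min(np.linalg.norm(x - y) for x in a for y in b)
        assert min_residue_distance(s, 90, 113) == pytest.approx(brute, rel=1e-12)


def test_min_distance_unknown_site_names_the_site():
    s = single_atom_structure({90: (0, 0, 0)})
    with pytest.raises(MissingSiteError, match="113"):
        min_residue_distance(s, 90, 113)


# --- area A ---------------------------------------------------------------

TRIANGLE = {90: (0.0, 0.0, 0.0), 113: (6.0, 0.0, 0.0), 118: (0.0, 8.0, 0.0)}


@pytest.mark.parametrize("convention", ["distance-heron", "coordinate-polygon"])
def test_area_a_right_triangle(convention):
    s = single_atom_structure(TRIANGLE)
    area, sub = area_A(s, convention)
    assert area == pytest.approx(24.0)
    assert sub is None


@pytest.mark.parametrize("convention", ["distance-heron", "coordinate-polygon"])
def test_area_a_subareas_partition_with_interior_nitrogen(convention):
    centroid = np.array([2.0, 8.0 / 3.0, 0.0])
    s = single_atom_structure(TRIANGLE, sb=centroid)
    area, sub = area_A(s, convention)
    assert sub is not None and len(sub) == 3
    assert sum(sub) == pytest.approx(area, rel=1e-9)
    assert sum(sub) == pytest.approx(24.0, rel=1e-9)


def test_area_a_missing_site():
    s = single_atom_structure({90: (0, 0, 0), 113: (1, 0, 0)})
    with pytest.raises(MissingSiteError):
        area_A(s)


# --- area B ---------------------------------------------------------------

SQUARE = {86: (0.0, 0.0, 0.0), 90: (1.0, 0.0, 0.0), 118: (1.0, 1.0, 0.0), 295: (0.0, 1.0, 0.0)}


@pytest.mark.parametrize("convention", ["distance-heron", "coordinate-polygon"])
def test_area_b_unit_square(convention):
    area, _, substituted = area_B(single_atom_structure(SQUARE), convention)
    assert area == pytest.approx(1.0)
    assert not substituted


def test_area_b_site91_substitutes_for_missing_site86():
    pts = dict(SQUARE)
    pts[91] = pts.pop(86)
    area, _, substituted = area_B(single_atom_structure(pts))
    assert area == pytest.approx(1.0)
    assert substituted


def test_area_b_without_site86_or_91_fails():
    pts = {90: (1, 0, 0), 118: (1, 1, 0), 295: (0, 1, 0)}
    with pytest.raises(MissingSiteError):
        area_B(single_atom_structure(pts))


def test_area_b_alternative_diagonal_agrees_on_planar_quad():
    s = single_atom_structure(SQUARE)
    a1, _, _ = area_B(s, "distance-heron", diagonal=(86, 118))
    a2, _, _ = area_B(s, "distance-heron", diagonal=(90, 295))
    assert a1 == pytest.approx(a2, rel=1e-9)


def test_area_b_subareas_fan_around_first_water():
    w = np.array([0.5, 0.5, 0.0])
    s = single_atom_structure(SQUARE, waters={"W1": w})
    area, sub, _ = area_B(s, "coordinate-polygon")
    assert sub is not None and len(sub) == 3
    assert sum(sub) == pytest.approx(area, rel=1e-9)


# --- random planar cross-convention + invariances -------------------------

def random_planar_structure(rng, with_sb=False):
    """Random planar single-atom structure with a convex area-B quad."""
    w = rng.uniform(4.0, 12.0)
    h = rng.uniform(4.0, 12.0)
    depth = rng.uniform(2.0, 8.0)
    pts = {
        90: np.array([0.0, 0.0, 0.0]),
        118: np.array([w, 0.0, 0.0]),
        113: np.array([rng.uniform(0.2 * w, 0.8 * w), -depth, 0.0]),
        86: np.array([rng.uniform(-1.0, 1.0), h, 0.0]),
        295: np.array([w + rng.uniform(-1.0, 1.0), h, 0.0]),
    }
    sb = None
    if with_sb:
        sb = (pts[90] + pts[113] + pts[118]) / 3.0
    return single_atom_structure(pts, sb=sb)


def test_conventions_agree_on_random_planar_structures(rng):
    for _ in range(300):
        s = random_planar_structure(rng)
        g_h = ab_ratio(s, "distance-heron")
        g_p = ab_ratio(s, "coordinate-polygon")
        assert g_h.area_A == pytest.approx(g_p.area_A, rel=1e-9)
        assert g_h.area_B == pytest.approx(g_p.area_B, rel=1e-9)
        assert g_h.ab_ratio == pytest.approx(g_p.ab_ratio, rel=1e-9)


@pytest.mark.parametrize("convention", ["distance-heron", "coordinate-polygon"])
def test_rigid_motion_invariance(rng, convention):
    for _ in range(50):
        s = random_planar_structure(rng, with_sb=True)
        R = Rotation.random(random_state=np.random.RandomState(int(rng.integers(2**31)))).as_matrix()
        t = rng.uniform(-50, 50, size=3)
        g0 = ab_ratio(s, convention)
        g1 = ab_ratio(s.transformed(R, t), convention)
        assert g1.area_A == pytest.approx(g0.area_A, rel=1e-9, abs=1e-9)
        assert g1.area_B == pytest.approx(g0.area_B, rel=1e-9, abs=1e-9)
        assert g1.ab_ratio == pytest.approx(g0.ab_ratio, rel=1e-9)


def test_ninety_degree_rotation_plus_translation_exact():
    s = random_planar_structure(np.random.default_rng(7), with_sb=True)
    R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    g0, g1 = ab_ratio(s), ab_ratio(s.transformed(R, np.array([10.0, 10.0, 10.0])))
    assert g1.ab_ratio == pytest.approx(g0.ab_ratio, rel=1e-9)
    assert g1.counterion_sb == pytest.approx(g0.counterion_sb, rel=1e-9)


def test_atom_relabelling_within_residue_is_irrelevant(rng):
    s = random_planar_structure(rng)
    relabelled = HBNStructure(
        "t",
        residues={site: {f"Z{i}": xyz for i, (_, xyz) in enumerate(atoms.items())} for site, atoms in s.residues.items()},
    )
    assert ab_ratio(relabelled).ab_ratio == pytest.approx(ab_ratio(s).ab_ratio, rel=1e-12)


def test_ab_ratio_decreases_when_area_a_shrinks(rng):
    s = random_planar_structure(rng)
    base = ab_ratio(s)
    # pull site 113 toward the 90-118 edge: area A shrinks, area B fixed
    shrunk_pts = {site: atoms["X"] for site, atoms in s.residues.items()}
    shrunk_pts[113] = shrunk_pts[113] * np.array([1.0, 0.5, 1.0])
    shrunk = single_atom_structure(shrunk_pts)
    g = ab_ratio(shrunk)
    assert g.area_B == pytest.approx(base.area_B, rel=1e-9)
    assert g.ab_ratio < base.ab_ratio


# --- counterion distance & assembly ---------------------------------------

def test_counterion_distance_uses_closest_site113_atom():
    s = HBNStructure(
        "t",
        residues={113: {"OE1": [1.99, 0, 0], "OE2": [3, 0, 0]}},
        sb_nitrogen=[0, 0, 0],
    )
    assert counterion_sb_distance(s) == pytest.approx(1.99)


def test_counterion_distance_zero_when_coincident():
    s = HBNStructure("t", residues={113: {"OE1": [0, 0, 0]}}, sb_nitrogen=[0, 0, 0])
    assert counterion_sb_distance(s) == 0.0


def test_counterion_distance_requires_nitrogen():
    s = single_atom_structure({113: (0, 0, 0)})
    with pytest.raises(MissingSiteError):
        counterion_sb_distance(s)


def test_degenerate_area_b_raises():
    pts = {
        90: (0.0, 0.0, 0.0), 118: (1.0, 0.0, 0.0), 113: (0.5, -1.0, 0.0),
        86: (0.0, 0.0, 0.0), 295: (1.0, 0.0, 0.0),  # B collapses onto the 90-118 edge
    }
    with pytest.raises(DegenerateGeometryError):
        ab_ratio(single_atom_structure(pts))


def test_hbn_geometry_validate_catches_bad_ratio():
    from hbnspec.geometry import HBNGeometry

    g = HBNGeometry("t", area_A=2.0, area_B=4.0, ab_ratio=0.7, convention="distance-heron")
    with pytest.raises(ValueError):
        g.validate()
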