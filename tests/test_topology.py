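"""Skeleton I/O, entry points, depth labeling, and morphometry."""

import io

import numpy as np
import pytest

from caa3d.labels import DEEPER, LMA, D, SegmentLabel
from caa3d.topology import (
    SWCParseError,
    VascularUnit,
    VesselNode,
    d0_external_diameter,
    find_entry_point,
    label_depths,
    read_swc,
    segment_length,
    write_swc,
)

from conftest import straight_unit


# ----------------------------------------------------------------------
# labels
# ----------------------------------------------------------------------

def test_label_superficiality_order_is_total():
    chain = [LMA, D(0), SegmentLabel("BIFURCATION", 0), D(1),
             SegmentLabel("BIFURCATION", 1), D(6), DEEPER]
    assert chain == sorted(chain)
    assert str(SegmentLabel("BIFURCATION", 0)) == "D0-D1"
    assert SegmentLabel.parse("D3-D4") == SegmentLabel("BIFURCATION", 3)
    assert SegmentLabel.for_depth(9) is DEEPER


# ----------------------------------------------------------------------
# SWC
# ----------------------------------------------------------------------

def test_swc_round_trip_preserves_geometry(tmp_path):
    unit = straight_unit(24.0)
    path = tmp_path / "u.swc"
    write_swc([unit], path)
    units = read_swc(path)
    assert len(units) == 1
    got = units[0]
    assert len(got.nodes) == len(unit.nodes)
    for a, b in zip(
        sorted(unit.nodes.values(), key=lambda n: n.id),
        sorted(got.nodes.values(), key=lambda n: n.id),
    ):
        assert np.allclose(a.position, b.position, atol=1e-6)
        assert a.radius == pytest.approx(b.radius, abs=1e-6)
    # a second write is byte-identical (stable serialization)
    path2 = tmp_path / "u2.swc"
    write_swc(units, path2)
    write_swc(read_swc(path2), tmp_path / "u3.swc")
    assert (tmp_path / "u2.swc").read_bytes() == (tmp_path / "u3.swc").read_bytes()


@pytest.mark.parametrize(
    "text, message",
    [
        ("1 7 0 0 0 5 2\n2 7 0 0 10 5 -1\n", "not declared before"),
        ("1 7 0 0 0 -1 -1\n", "radius"),
        ("1 7 0 0 0 5 -1\n1 7 0 0 9 5 1\n", "duplicate"),
        ("1 7 0 0 0 5\n", "columns"),
        ("1 7 0 0 0 5 1\n", "its own parent"),
    ],
)
def test_swc_parse_errors_name_the_problem(text, message):
    with pytest.raises(SWCParseError, match=message):
        read_swc(io.StringIO(text))


def test_swc_multiple_roots_become_multiple_units():
    text = "1 7 0 0 -5 4 -1\n2 7 0 0 5 4 1\n3 7 50 0 -5 4 -1\n4 7 50 0 5 4 3\n"
    units = read_swc(io.StringIO(text))
    assert len(units) == 2


# ----------------------------------------------------------------------
# entry point
# ----------------------------------------------------------------------

def test_entry_point_is_linear_interpolation_of_crossing_edge():
    nodes = {
        0: VesselNode(0, np.array([0.0, 0.0, -10.0]), 5.0, None),
        1: VesselNode(1, np.array([20.0, 0.0, 10.0]), 5.0, 0),
    }
    unit = VascularUnit(0, nodes, 0)
    entry = find_entry_point(unit, 0.0)
    assert np.allclose(entry, [10.0, 0.0, 0.0])
    assert unit.excluded_reason is None


def test_fully_leptomeningeal_unit_is_excluded():
    nodes = {
        0: VesselNode(0, np.array([0.0, 0.0, -30.0]), 5.0, None),
        1: VesselNode(1, np.array([20.0, 0.0, -10.0]), 5.0, 0),
    }
    unit = VascularUnit(0, nodes, 0)
    assert find_entry_point(unit, 0.0) is None
    assert unit.excluded_reason == "no-entry"


def test_entry_point_moves_continuously_with_surface():
    unit = straight_unit(20.0)
    e0 = find_entry_point(unit, 0.0).copy()
    e1 = find_entry_point(unit, 0.5)
    assert np.linalg.norm(e1 - e0) < 2.0  # O(epsilon) for a near-vertical vessel


# ----------------------------------------------------------------------
# depth labeling
# ----------------------------------------------------------------------

def test_unbranched_vessel_labels_lma_and_d0_only():
    unit = straight_unit(20.0)
    assert unit.labels_present == {LMA, D(0)}


def _branching_unit(n_generations: int, diameter: float = 24.0) -> VascularUnit:
    """Deterministic binary tree: each chain descends then splits in x."""
    nodes = {}
    nid = [0]

    def add(pos, parent):
        i = nid[0]
        nid[0] += 1
        nodes[i] = VesselNode(i, np.asarray(pos, float), diameter / 2.0, parent)
        return i

    root = add([0.0, 0.0, -40.0], None)
    stem = add([0.0, 0.0, -10.0], root)

    def grow(parent, x, z, gen, dx):
        tip = parent
        for k in range(1, 9):
            tip = add([x, 0.0, z + 10.0 * k], tip)
        if gen < n_generations:
            grow(tip, x - dx, z + 80.0, gen + 1, dx / 2.0)
            grow(tip, x + dx, z + 80.0, gen + 1, dx / 2.0)

    grow(stem, 0.0, 0.0, 0, 160.0)
    unit = VascularUnit(0, nodes, root)
    find_entry_point(unit, 0.0)
    label_depths(unit, 0.0)
    return unit


def test_single_bifurcation_produces_the_expected_label_set():
    unit = _branching_unit(1)
    assert unit.labels_present == {LMA, D(0), SegmentLabel("BIFURCATION", 0), D(1)}
    assert len(unit.segments_with(D(1))) == 2  # both children are depth 1


def test_deep_tree_reaches_d6_then_pools_deeper():
    unit = _branching_unit(8)
    labels = unit.labels_present
    assert D(6) in labels and DEEPER in labels
    # order along any root-to-leaf path is non-decreasing: check via a walk
    ch = unit.children_map()
    seg_of = {}
    for seg in unit.segments:
        for p in map(tuple, seg.polyline):
            seg_of.setdefault(p, seg.label)

    def walk(nid, best):
        lab = seg_of.get(tuple(unit.nodes[nid].position))
        if lab is not None:
            assert lab.order >= best - 1e-9
            best = max(best, lab.order)
        for c in ch[nid]:
            walk(c, best)

    walk(unit.root_id, -1.0)


def test_labeled_lengths_partition_the_intraparenchymal_centerline(desk_cohort):
    for unit in desk_cohort.units[:50]:
        if unit.excluded_reason:
            continue
        seg_sum = sum(s.length_um for s in unit.segments if s.label != LMA)
        pn, cn = unit.truth["entry_edge"]
        ch = unit.children_map()
        total = float(np.linalg.norm(unit.nodes[cn].position - unit.entry_point))
        stack = [cn]
        while stack:
            n = stack.pop()
            for k in ch[n]:
                total += float(
                    np.linalg.norm(unit.nodes[k].position - unit.nodes[n].position)
                )
                stack.append(k)
        assert seg_sum == pytest.approx(total, rel=1e-6)


# ----------------------------------------------------------------------
# lengths and diameters
# ----------------------------------------------------------------------

def test_segment_length_examples_and_oracle():
    assert segment_length(np.array([[0, 0, 0], [100, 0, 0.0]])) == pytest.approx(100)
    stair = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0], [2, 2, 0.0]])
    assert segment_length(stair) == pytest.approx(4.0)
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 100, (40, 3))
    oracle = sum(
        float(np.sqrt(((pts[i + 1] - pts[i]) ** 2).sum())) for i in range(39)
    )
    assert segment_length(pts) == pytest.approx(oracle, abs=1e-9)


def test_d0_diameter_is_twice_the_median_radius():
    unit = straight_unit(36.0)
    assert d0_external_diameter(unit) == pytest.approx(36.0)
    seg = unit.segments_with(D(0))[0]
    seg.radii = np.array([10.0, 16.0, 40.0])  # bulge outlier
    assert d0_external_diameter(unit) == pytest.approx(32.0)


def test_units_without_d0_have_undefined_diameter():
    nodes = {
        0: VesselNode(0, np.array([0.0, 0.0, -30.0]), 5.0, None),
        1: VesselNode(1, np.array([0.0, 0.0, -10.0]), 5.0, 0),
    }
    unit = VascularUnit(0, nodes, 0)
    assert d0_external_diameter(unit) is None
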