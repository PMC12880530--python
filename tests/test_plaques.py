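"""Spot detection, artifact exclusion, band filtering, density, dyshoric."""

import numpy as np
import pytest

from caa3d.labels import D
from caa3d.plaques import (
    PlaqueSpot,
    detect_spots,
    exclude_artifacts,
    exclude_wm_units,
    flag_dyshoric,
    min_distance_to_polylines,
    perivascular_spots,
    plaque_density,
    point_polyline_distance,
)
from caa3d.raster import rasterize
from caa3d.synthetic import DyshoricSleeve

from conftest import scene, scene_params, straight_unit


# ----------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------

def test_point_polyline_distance_examples():
    seg = [np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1000.0]])]
    assert point_polyline_distance(np.array([30.0, 0.0, 500.0]), seg) == pytest.approx(30.0)
    # beyond an endpoint the projection clamps to the endpoint
    assert point_polyline_distance(np.array([0.0, 0.0, 1040.0]), seg) == pytest.approx(40.0)


def test_point_polyline_distance_matches_dense_sampling():
    rng = np.random.default_rng(1)
    for _ in range(100):
        pts = np.cumsum(rng.uniform(-20, 20, (8, 3)), axis=0)
        p = rng.uniform(-50, 50, 3)
        exact = point_polyline_distance(p, [pts])
        dense = []
        for a, b in zip(pts[:-1], pts[1:]):
            ts = np.linspace(0, 1, int(np.linalg.norm(b - a) / 0.1) + 2)
            dense.append(np.linalg.norm(p - (a + ts[:, None] * (b - a)), axis=1).min())
        assert abs(exact - min(dense)) < 0.05


def test_min_distance_shortlist_matches_direct_computation():
    rng = np.random.default_rng(2)
    polylines = [np.cumsum(rng.uniform(-15, 15, (30, 3)), axis=0) + rng.uniform(0, 400, 3)
                 for _ in range(40)]
    points = rng.uniform(-50, 450, (300, 3))
    fast = min_distance_to_polylines(points, polylines)
    direct = np.array([min(point_polyline_distance(p, [pl]) for pl in polylines)
                       for p in points])
    assert np.allclose(fast, direct, atol=1e-9)


# ----------------------------------------------------------------------
# band filtering and density
# ----------------------------------------------------------------------

def band_unit():
    return straight_unit(16.0, x=200.0, y=200.0, length_um=300.0)


@pytest.mark.parametrize(
    "lateral, included",
    [(5.0, False), (10.0, True), (55.0, True), (100.0, True), (150.0, False)],
)
def test_band_bounds_are_inclusive(lateral, included):
    unit = band_unit()
    spot = PlaqueSpot(center=np.array([200.0 + lateral, 200.0, 150.0]), radius_um=25.0)
    got = perivascular_spots(unit, [spot])
    assert (len(got) == 1) == included


def test_band_filter_matches_brute_force_on_a_cohort(desk_cohort):
    sample = desk_cohort
    cortical = exclude_wm_units(sample.units, sample.params.cortex_thickness_um)
    from caa3d.plaques import parenchymal_polylines

    for unit in cortical[:25]:
        got = {id(s) for s in perivascular_spots(unit, sample.spots)}
        brute = set()
        pls = parenchymal_polylines(unit)
        for s in sample.spots:
            if s.is_artifact:
                continue
            d = min(point_polyline_distance(s.center, [pl]) for pl in pls)
            if 10.0 <= d <= 100.0:
                brute.add(id(s))
        assert got == brute


def test_density_is_count_over_length():
    unit = band_unit()
    spots = [PlaqueSpot(center=np.array([250.0, 200.0, z]), radius_um=20.0)
             for z in np.linspace(10, 290, 30)]
    rec = plaque_density(unit, spots)
    assert rec.density_per_um == pytest.approx(30 / rec.filament_length_um)
    assert plaque_density(unit, []).density_per_um == 0.0
    assert plaque_density(unit, spots + spots).density_per_um == pytest.approx(
        2 * rec.density_per_um
    )


def test_wm_unit_exclusion_uses_any_node_beyond_the_boundary():
    shallow = straight_unit(16.0, length_um=200.0)
    deep = straight_unit(16.0, length_um=320.0, unit_id=1)
    kept = exclude_wm_units([shallow, deep], cortex_boundary=300.0)
    assert [u.unit_id for u in kept] == [0]
    artifact = straight_unit(16.0, unit_id=2, length_um=200.0)
    artifact.excluded_reason = "perivascular-artifact"
    assert exclude_wm_units([artifact], 300.0) == []


# ----------------------------------------------------------------------
# detection and artifacts
# ----------------------------------------------------------------------

def _blank_unit(uid=0):
    u = straight_unit(16.0, x=40.0, y=40.0, unit_id=uid, length_um=100.0)
    return u


def test_blank_volume_has_no_spots():
    vol = rasterize(scene([_blank_unit()]))
    spots = [s for s in detect_spots(vol) if np.linalg.norm(s.center[:2] - 40.0) > 30]
    assert spots == []


def test_two_blobs_far_apart_are_resolved_and_close_ones_merge():
    a = PlaqueSpot(center=np.array([120.0, 120.0, 150.0]), radius_um=22.0)
    b = PlaqueSpot(center=np.array([220.0, 120.0, 150.0]), radius_um=22.0)  # 100 μm
    vol = rasterize(scene([_blank_unit()], spots=[a, b]))
    dets = [s for s in detect_spots(vol) if s.center[1] < 200]
    assert len(dets) == 2
    for truth in (a, b):
        assert min(np.linalg.norm(d.center - truth.center) for d in dets) < 10.0

    c = PlaqueSpot(center=np.array([120.0, 280.0, 150.0]), radius_um=22.0)
    d = PlaqueSpot(center=np.array([140.0, 280.0, 150.0]), radius_um=22.0)  # 20 μm
    vol2 = rasterize(scene([_blank_unit()], spots=[c, d]))
    dets2 = [s for s in detect_spots(vol2) if s.center[1] > 200]
    # inside the suppression radius a pair is never reported twice: it is
    # merged, or dropped entirely when the fused profile fails the
    # sphericity screen (documented behavior)
    assert len(dets2) <= 1


def test_spot_diameter_below_two_voxels_is_a_configuration_error():
    vol = rasterize(scene([_blank_unit()]))
    with pytest.raises(ValueError, match="2 voxels"):
        detect_spots(vol, diameter_um=3.0)


def test_dual_channel_puncta_are_flagged_and_true_spots_retained():
    spots = [
        PlaqueSpot(center=np.array([120.0, 280.0, 150.0]), radius_um=22.0),
        PlaqueSpot(center=np.array([300.0, 100.0, 80.0]), radius_um=25.0),
        PlaqueSpot(center=np.array([90.0, 90.0, 250.0]), radius_um=19.0),
    ]
    params = scene_params(artifact_puncta_density=5e-7)
    vol = rasterize(scene([_blank_unit()], spots=spots, params=params, seed=1))
    dets = exclude_artifacts(detect_spots(vol), vol)
    matched = [
        d for d in dets
        if min(np.linalg.norm(d.center - s.center) for s in spots) < 15.0
    ]
    matched_ids = {id(m) for m in matched}
    puncta = [d for d in dets if id(d) not in matched_ids]
    assert len(matched) == 3 and not any(d.is_artifact for d in matched)
    assert puncta and np.mean([d.is_artifact for d in puncta]) >= 0.95


def test_spot_with_zero_sma_is_kept_and_equal_sma_removed():
    spots = [PlaqueSpot(center=np.array([200.0, 200.0, 150.0]),
                        radius_um=25.0, quality=50.0)]

    class FakeVol:
        sma = np.zeros((8, 8, 8))
        voxel_size_um = 50.0
        origin_um = (0.0, 0.0, 0.0)

    out = exclude_artifacts(spots, FakeVol())
    assert not out[0].is_artifact
    FakeVol.sma = np.full((8, 8, 8), 50.0)
    out = exclude_artifacts(spots, FakeVol())
    assert out[0].is_artifact  # SMA == quality is removed at alpha <= 1


# ----------------------------------------------------------------------
# dyshoric flagging
# ----------------------------------------------------------------------

def _sleeved_scene():
    unit = straight_unit(20.0)
    unit.truth["abeta"] = {lab: lab == D(0) for lab in unit.labels_present}
    unit.truth["abeta_positive"] = True
    unit.truth["coverage"] = {lab: 1.0 for lab in unit.labels_present}
    iseg = next(i for i, sg in enumerate(unit.segments) if sg.label == D(0))
    sleeve = DyshoricSleeve(0, D(0), 30.0, 120.0, (5.0, 20.0), iseg)
    return unit, sleeve


def test_dyshoric_sleeve_is_flagged_on_its_segment():
    unit, sleeve = _sleeved_scene()
    vol = rasterize(scene([unit], dyshoric=[sleeve]))
    assert flag_dyshoric(vol, unit) == [D(0)]


def test_dyshoric_sleeves_are_never_counted_as_spots():
    unit, sleeve = _sleeved_scene()
    vol = rasterize(scene([unit], dyshoric=[sleeve]))
    assert detect_spots(vol) == []


def test_isolated_blob_near_the_wall_is_not_dyshoric():
    unit = straight_unit(20.0)
    unit.truth["abeta_positive"] = True
    blob = PlaqueSpot(center=np.array([225.0, 200.0, 150.0]), radius_um=12.0)
    vol = rasterize(scene([unit], spots=[blob]))
    assert flag_dyshoric(vol, unit) == []


def test_no_perivascular_signal_flags_nothing():
    unit = straight_unit(20.0)
    vol = rasterize(scene([unit]))
    assert flag_dyshoric(vol, unit) == []
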