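"""Rasterization and image-based morphometry/classification."""

import numpy as np
import pytest

from caa3d.classify import classify_segment_abeta, classify_segment_sma
from caa3d.labels import D
from caa3d.raster import VolumeSizeError, rasterize
from caa3d.synthetic import GroundTruthSample
from caa3d.topology import estimate_radius_profile

from conftest import scene, scene_params, straight_unit


@pytest.fixture(scope="module")
def positive_tube_volume():
    """One straight vessel, Aβ-positive along its full D0, noise-free."""
    unit = straight_unit(24.0)
    unit.truth["abeta"] = {lab: lab == D(0) for lab in unit.labels_present}
    unit.truth["abeta_positive"] = True
    unit.truth["coverage"] = {lab: 1.0 for lab in unit.labels_present}
    sample = scene([unit])
    return unit, rasterize(sample)


def test_empty_sample_renders_pure_background():
    params = scene_params()
    vol = rasterize(GroundTruthSample([], [], [], params, 0))
    assert vol.sma.max() <= params.imaging.background + 1
    assert vol.abeta.max() <= params.imaging.background + 1


def test_volume_cap_error_includes_a_voxel_size_hint():
    params = scene_params(slab_dims_um=(4000.0, 4000.0, 4000.0), voxel_size_um=2.0)
    with pytest.raises(VolumeSizeError, match="voxel_size_um >="):
        rasterize(GroundTruthSample([], [], [], params, 0))


@pytest.mark.parametrize("diameter", [8.0, 16.0, 32.0, 48.0, 60.0])
def test_cylinder_diameter_recovered_within_one_voxel(diameter):
    rng = np.random.default_rng(int(diameter))
    unit = straight_unit(
        diameter, x=200.0 + rng.uniform(-1, 1), y=200.0 + rng.uniform(-1, 1),
        length_um=200.0,
    )
    sample = scene([unit])
    vol = rasterize(sample)
    seg = unit.segments_with(D(0))[0]
    prof = estimate_radius_profile(vol, seg.polyline[2:-2], 50.0)
    est = 2.0 * float(np.median(prof))
    assert abs(est - diameter) <= sample.params.voxel_size_um


def test_radius_profile_is_zero_in_background():
    unit = straight_unit(24.0)
    vol = rasterize(scene([unit]))
    pts = np.array([[40.0, 40.0, 100.0], [60.0, 330.0, 200.0]])
    assert np.allclose(estimate_radius_profile(vol, pts, 50.0), 0.0)


def test_radius_profile_warns_on_empty_foreground():
    unit = straight_unit(24.0)
    vol = rasterize(scene([unit]))
    with pytest.warns(UserWarning, match="empty SMA foreground"):
        prof = estimate_radius_profile(vol, np.zeros((2, 3)), 1e9)
    assert np.allclose(prof, 0.0)


def test_voxel_size_consistency_of_the_diameter_estimate():
    ests = []
    for vs in (2.0, 4.0):
        unit = straight_unit(32.0, length_um=200.0)
        sample = scene([unit], params=scene_params(voxel_size_um=vs))
        vol = rasterize(sample)
        seg = unit.segments_with(D(0))[0]
        prof = estimate_radius_profile(vol, seg.polyline[2:-2], 50.0)
        ests.append(2.0 * float(np.median(prof)))
    assert abs(ests[0] - ests[1]) <= 4.0  # one voxel at the coarser sampling


# ----------------------------------------------------------------------
# raster-path classification
# ----------------------------------------------------------------------

def test_positive_wall_classifies_positive_and_threshold_is_monotone(
    positive_tube_volume,
):
    unit, vol = positive_tube_volume
    seg = unit.segments_with(D(0))[0]
    positives = []
    for thr in (60.0, 140.0, 250.0):
        st = classify_segment_abeta(vol, seg, intensity_threshold=thr)
        positives.append(st.abeta_positive)
    assert positives[0]  # detected at the default threshold
    # raising the threshold never converts negative back to positive
    for earlier, later in zip(positives, positives[1:]):
        assert earlier or not later


def test_zero_abeta_channel_classifies_negative(positive_tube_volume):
    unit, vol = positive_tube_volume
    blank = type(vol)(
        sma=vol.sma, abeta=np.zeros_like(vol.abeta),
        voxel_size_um=vol.voxel_size_um, origin_um=vol.origin_um,
    )
    seg = unit.segments_with(D(0))[0]
    st = classify_segment_abeta(blank, seg)
    assert not st.abeta_positive and st.abeta_coverage == 0.0


def test_sma_gap_rule_is_inclusive_at_the_boundary(positive_tube_volume):
    unit, vol = positive_tube_volume
    seg = unit.segments_with(D(0))[0]
    st = classify_segment_sma(vol, seg)
    assert st.sma_present and st.sma_longest_gap_um <= 20.0
    # a rendered gap longer than gap_max is lost
    unit2 = straight_unit(24.0, unit_id=1)
    unit2.truth["sma_lost"] = {D(0)}
    vol2 = rasterize(scene([unit2]))
    st2 = classify_segment_sma(vol2, unit2.segments_with(D(0))[0])
    assert not st2.sma_present


def test_centerline_outside_the_volume_raises(positive_tube_volume):
    from caa3d.classify import OutOfBoundsError

    unit, vol = positive_tube_volume
    seg = unit.segments_with(D(0))[0]
    shifted = type(seg)(
        seg.unit_id, seg.label, seg.polyline + np.array([5000.0, 0, 0]), seg.radii
    )
    with pytest.raises(OutOfBoundsError, match="outside"):
        classify_segment_abeta(vol, shifted)


def test_tiff_round_trip_preserves_channels_and_metadata(tmp_path):
    from caa3d.raster import TwoChannelVolume, read_volume, write_volume

    rng = np.random.default_rng(0)
    vol = TwoChannelVolume(
        sma=rng.integers(0, 1000, (20, 16, 12)).astype(np.uint16),
        abeta=rng.integers(0, 1000, (20, 16, 12)).astype(np.uint16),
        voxel_size_um=2.0,
        origin_um=(0.0, 0.0, -30.0),
    )
    write_volume(vol, tmp_path, stem="t")
    back = read_volume(tmp_path, stem="t")
    assert np.array_equal(back.sma, vol.sma)
    assert np.array_equal(back.abeta, vol.abeta)
    assert back.voxel_size_um == 2.0 and back.origin_um == (0.0, 0.0, -30.0)


def test_rasterization_is_deterministic():
    unit = straight_unit(24.0)
    a = rasterize(scene([unit], seed=5))
    b = rasterize(scene([unit], seed=5))
    assert np.array_equal(a.abeta, b.abeta) and np.array_equal(a.sma, b.sma)
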