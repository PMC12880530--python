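"""Generator statistics: determinism, contiguity, nesting, calibration."""

import numpy as np
import pytest

from caa3d.classify import (
    apply_truth_statuses,
    detect_skip_pattern,
    most_superficial_sma_loss,
    vascular_load,
)
from caa3d.labels import LMA, D
from caa3d.params import CohortParams
from caa3d.synthetic import generate_cohort, generate_unit_geometry
from caa3d.topology import write_swc


def stat_params(**overrides):
    """Conditions for label-statistics experiments: geometry plays no role,
    so spatial constraints are off and plaques are not drawn."""
    base = dict(
        plaque_lambda0=0.0,
        p_dyshoric_unit=0.0,
        avoid_collisions=False,
        min_entry_sep_um=0.0,
    )
    base.update(overrides)
    return CohortParams(**base)


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(p_unit_abeta=1.5), "outside"),
        (dict(front_reach_probs=(0.9, 0.95, 0.1, 0.1, 0.1, 0.1, 0.0)), "non-increasing"),
        (dict(diameter_floor_um=4.0), "inclusion"),
        (dict(cortex_thickness_um=5000.0), "slab"),
        (dict(plaque_lambda0=-1.0), "non-negative"),
        (dict(sma_onset_dist={"LMA": 0.5, "D0": 0.2}), "sum to 1"),
    ],
)
def test_invalid_params_are_rejected(kwargs, match):
    with pytest.raises(ValueError, match=match):
        CohortParams(**kwargs)


def test_nonmonotone_front_requires_override():
    probs = (0.995, 0.458, 0.198, 0.100, 0.045, 0.063, 0.0)
    with pytest.raises(ValueError):
        CohortParams(front_reach_probs=probs)
    CohortParams(front_reach_probs=probs, allow_nonmonotone=True)


# ----------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------

def test_branchless_growth_yields_lma_and_d0_only():
    params = stat_params(branch_prob=0.0, max_depth=0, n_units=3, seed=1)
    sample = generate_cohort(params)
    for unit in sample.units:
        assert unit.labels_present <= {LMA, D(0)}


def test_taper_respects_the_inclusion_floor():
    params = stat_params(seed=2, taper=0.8, max_depth=6)
    rng = np.random.default_rng(0)
    unit = generate_unit_geometry(params, rng, root_diameter=40.0)
    radii = [n.radius for n in unit.nodes.values()]
    assert min(radii) >= params.diameter_floor_um / 2.0 - 1e-9
    assert max(radii) == pytest.approx(20.0)


def test_fixed_seed_gives_byte_identical_swc(tmp_path):
    params = stat_params(n_units=10, seed=33)
    a, b = generate_cohort(params), generate_cohort(params)
    write_swc(a.units, tmp_path / "a.swc")
    write_swc(b.units, tmp_path / "b.swc")
    assert (tmp_path / "a.swc").read_bytes() == (tmp_path / "b.swc").read_bytes()
    assert len(a.spots) == len(b.spots)


def test_wm_penetration_matches_the_drawn_rate():
    from caa3d.plaques import exclude_wm_units

    params = stat_params(n_units=600, p_penetrate_wm=0.3, seed=4)
    sample = generate_cohort(params)
    kept = exclude_wm_units(sample.units, params.cortex_thickness_um)
    frac = len(kept) / len(sample.units)
    sd = np.sqrt(0.3 * 0.7 / 600)
    assert abs(frac - 0.7) < 3 * sd
    for u in sample.units:
        assert u.penetrates_wm == u.truth["penetrates_wm_drawn"]


# ----------------------------------------------------------------------
# deposition statuses
# ----------------------------------------------------------------------

def test_all_negative_when_p_unit_abeta_is_zero():
    sample = generate_cohort(stat_params(n_units=40, p_unit_abeta=0.0, seed=5))
    for u in sample.units:
        assert not u.truth["abeta_positive"]
        assert not any(u.truth["abeta"].values())
        assert u.truth["sma_lost"] == set()


def test_positive_labels_form_a_contiguous_prefix_without_skips():
    params = stat_params(
        n_units=2000, p_unit_abeta=1.0, p_skip=0.0, p_wm_confined=0.0, seed=6
    )
    sample = generate_cohort(params)
    for u in sample.units:
        apply_truth_statuses(u)
        st = u.truth["abeta"]
        orders = sorted(lab.order for lab in st if lab.order >= 0)
        pos = [st[lab] for lab in sorted(st) if lab.order >= 0]
        # once a label is negative, every deeper label is negative
        seen_negative = False
        for flag in pos:
            if seen_negative:
                assert not flag
            seen_negative = seen_negative or not flag
        assert not detect_skip_pattern(u)


def test_sma_loss_is_nested_inside_the_abeta_extent():
    sample = generate_cohort(stat_params(n_units=500, p_sma_loss=0.8, seed=7))
    for u in sample.units:
        st, lost = u.truth["abeta"], u.truth["sma_lost"]
        assert all(st[lab] for lab in lost)
        if lost:
            onset = min(lost)
            assert lost == {lab for lab in st if st[lab] and lab.order >= onset.order}


def test_front_calibration_round_trip_at_2000_units():
    probs = (0.995, 0.46, 0.20, 0.10, 0.05, 0.05, 0.0)
    params = stat_params(
        n_units=2000, p_unit_abeta=1.0, p_skip=0.0, p_wm_confined=0.0,
        front_reach_probs=probs, seed=8,
    )
    sample = generate_cohort(params)
    for u in sample.units:
        apply_truth_statuses(u)
    rates = vascular_load(sample.units).per_segment_rates
    for d, target in ((1, 0.46), (2, 0.20)):
        n = sum(
            1 for u in sample.units
            if u.truth["abeta_positive"] and D(d) in u.labels_present
        )
        sd = np.sqrt(target * (1 - target) / n)
        assert abs(rates[f"D{d}"] - target) < 3 * sd


def test_sma_onset_distribution_round_trip():
    from caa3d.pipeline import _onset_category

    params = stat_params(
        n_units=1000, p_unit_abeta=1.0, p_sma_loss=1.0, p_skip=0.0,
        p_wm_confined=0.0, front_reach_probs=(1.0,) * 7, seed=9,
    )
    sample = generate_cohort(params)
    counts: dict[str, int] = {}
    n = 0
    for u in sample.units:
        apply_truth_statuses(u)
        onset = most_superficial_sma_loss(u)
        if onset is not None:
            counts[_onset_category(onset)] = counts.get(_onset_category(onset), 0) + 1
            n += 1
    for cat, target in params.sma_onset_dist.items():
        sd = np.sqrt(max(target * (1 - target), 1e-4) / n)
        assert abs(counts.get(cat, 0) / n - target) < 3 * sd + 0.01


# ----------------------------------------------------------------------
# plaques and dyshoric sleeves
# ----------------------------------------------------------------------

def test_zero_intensity_gives_no_plaques():
    sample = generate_cohort(stat_params(n_units=5, seed=10))
    assert sample.spots == []


def test_unthinned_plaque_count_matches_the_poisson_oracle():
    params = stat_params(
        n_units=5, plaque_lambda0=6.4e-7, plaque_thinning_theta=1.0, seed=11
    )
    sample = generate_cohort(params)
    X, Y, _ = params.slab_dims_um
    lam = params.plaque_lambda0 * X * Y * params.cortex_thickness_um
    assert abs(len(sample.spots) - lam) < 3 * np.sqrt(lam)
    for s in sample.spots:
        assert 0 <= s.center[2] < params.cortex_thickness_um


def test_dyshoric_placement_recovers_rate_and_d0_share():
    params = stat_params(
        n_units=700, p_unit_abeta=1.0, p_dyshoric_unit=0.127,
        dyshoric_d0_share=0.915, p_penetrate_wm=0.0, p_skip=0.0,
        p_wm_confined=0.0, seed=12,
    )
    sample = generate_cohort(params)
    n_eligible = sum(
        1 for u in sample.units
        if u.truth["abeta_positive"] and not u.penetrates_wm
    )
    rate = len(sample.dyshoric) / n_eligible
    assert abs(rate - 0.127) < 3 * np.sqrt(0.127 * 0.873 / n_eligible)
    if sample.dyshoric:
        share = np.mean([d.label == D(0) for d in sample.dyshoric])
        sd = np.sqrt(0.915 * 0.085 / len(sample.dyshoric))
        assert abs(share - 0.915) < 3 * sd + 0.02


def test_skip_pattern_units_are_detected_and_keep_superficial_deposit():
    params = stat_params(
        n_units=400, p_unit_abeta=1.0, p_skip=0.5, p_wm_confined=0.0, seed=13
    )
    sample = generate_cohort(params)
    n_skip_truth = 0
    for u in sample.units:
        apply_truth_statuses(u)
        if u.truth["pattern"] == "skip":
            n_skip_truth += 1
            st = u.truth["abeta"]
            assert st.get(LMA, False) or st.get(D(0), False)
            assert detect_skip_pattern(u)
    assert n_skip_truth > 50
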