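import numpy as np
import pytest

from caa3d.labels import D
from caa3d.params import CohortParams, ImagingParams
from caa3d.synthetic import GroundTruthSample
from caa3d.topology import VascularUnit, VesselNode, find_entry_point, label_depths


def straight_unit(
    diameter_um: float,
    x: float = 200.0,
    y: float = 200.0,
    length_um: float = 250.0,
    lma_um: float = 50.0,
    unit_id: int = 0,
) -> VascularUnit:
    """A vertical unbranched vessel crossing the surface plane at (x, y)."""
    nodes = {}
    zs = np.arange(-lma_um, length_um, 10.0)
    for i, z in enumerate(zs):
        nodes[i] = VesselNode(
            i, np.array([x, y, z]), diameter_um / 2.0, None if i == 0 else i - 1
        )
    unit = VascularUnit(unit_id, nodes, 0)
    find_entry_point(unit, 0.0)
    label_depths(unit, 0.0, cortex_z=1e9)
    unit.truth.update(
        abeta={lab: False for lab in unit.labels_present},
        abeta_positive=False,
        coverage={lab: 0.0 for lab in unit.labels_present},
        sma_lost=set(),
    )
    return unit


def scene_params(**overrides) -> CohortParams:
    """Small noise-free imaging scene for raster-level tests."""
    base = dict(
        slab_dims_um=(400.0, 400.0, 360.0),
        cortex_thickness_um=300.0,
        n_units=1,
        lma_len_um=60.0,
        artifact_puncta_density=0.0,
        imaging=ImagingParams(read_noise_sd=0.0, shot_noise=False),
    )
    base.update(overrides)
    return CohortParams(**base)


def scene(units, spots=(), dyshoric=(), params=None, seed=0) -> GroundTruthSample:
    return GroundTruthSample(
        units=list(units),
        spots=list(spots),
        dyshoric=list(dyshoric),
        params=params or scene_params(),
        seed=seed,
    )


@pytest.fixture(scope="session")
def desk_cohort():
    """A mid-sized truth-only cohort at default study conditions."""
    from caa3d.synthetic import generate_cohort
    from caa3d.classify import apply_truth_statuses

    params = CohortParams(n_units=200, seed=314)
    sample = generate_cohort(params)
    for u in sample.units:
        apply_truth_statuses(u)
    return sample
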