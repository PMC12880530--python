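"""Synthetic cohort generator.

Emulates the statistical structure of the study's imaging data so every
downstream stage is testable without any acquisition: bifurcating arterial
trees entering a flat cortical slab from the surface plane, anatomically
contiguous Aβ deposition concentrated in leptomeningeal/superficial
segments (with rare skip and white-matter-confined patterns), SMA loss
nested inside the Aβ-positive extent, a cortical plaque point process
thinned near Aβ-positive vessels, linear dyshoric perivascular sleeves,
and dual-channel autofluorescent puncta (rendered by :mod:`caa3d.raster`).

The deposition front is a survival function over depth labels D0..D6:
a single uniform draw U per positive unit sets the front depth
F = max{d : U < front_reach_probs[d]}, which reproduces the observed
contiguity of vascular Aβ load exactly (an independent-Bernoulli mode is
available for null experiments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .labels import DEEPER, LMA, D, SegmentLabel
from .params import ONSET_CATEGORIES, CohortParams
from .plaques import PlaqueSpot, min_distance_to_polylines
from .topology import VascularUnit, VesselNode, find_entry_point, label_depths


@dataclass
class DyshoricSleeve:
    """A linear perivascular Aβ deposit hugging one segment."""

    unit_id: int
    label: SegmentLabel
    start_um: float  # arclength offset along the chosen segment record
    length_um: float
    annulus_um: tuple[float, float]  # radial band outside the vessel wall
    segment_index: int  # index into unit.segments


@dataclass
class GroundTruthSample:
    units: list[VascularUnit]
    spots: list[PlaqueSpot]
    dyshoric: list[DyshoricSleeve]
    params: CohortParams
    seed: int

    @property
    def dyshoric_segments(self) -> list[tuple[int, SegmentLabel]]:
        return [(s.unit_id, s.label) for s in self.dyshoric]


# ----------------------------------------------------------------------
# tree geometry
# ----------------------------------------------------------------------

class SpatialHash:
    """Coarse-grid occupancy index so growing vessels avoid each other."""

    def __init__(self, cell_um: float = 40.0) -> None:
        self.cell = cell_um
        self.grid: dict[tuple[int, int, int], list[tuple[np.ndarray, float]]] = {}

    def _key(self, p: np.ndarray) -> tuple[int, int, int]:
        return (int(p[0] // self.cell), int(p[1] // self.cell), int(p[2] // self.cell))

    def insert(self, p: np.ndarray, radius: float, tag: int = -1) -> None:
        self.grid.setdefault(self._key(p), []).append((p, radius, tag))

    def collides(
        self,
        p: np.ndarray,
        radius: float,
        clearance: float,
        tag: int = -1,
        exempt_center: np.ndarray | None = None,
        exempt_radius: float = 0.0,
    ) -> bool:
        """True when p comes within (radius + r_other + clearance) of an
        occupied point.  Occupancy from the same unit (``tag``) near
        ``exempt_center`` — the current chain's own origin, i.e. the
        parent tail and sibling starts — is ignored; other units always
        block."""
        kx, ky, kz = self._key(p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for q, rq, tq in self.grid.get((kx + dx, ky + dy, kz + dz), ()):
                        d = p - q
                        if float(d @ d) ** 0.5 < radius + rq + clearance:
                            if tq == tag and exempt_center is not None:
                                e = q - exempt_center
                                if float(e @ e) ** 0.5 <= exempt_radius:
                                    continue
                            return True
        return False


def _unit_vector(v: np.ndarray) -> np.ndarray:
    n = float(v @ v) ** 0.5
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def generate_unit_geometry(
    params: CohortParams,
    rng: np.random.Generator,
    unit_id: int = 0,
    root_diameter: float | None = None,
    penetrate_wm: bool | None = None,
    existing_entries: list[tuple[float, float]] | None = None,
    occupancy: SpatialHash | None = None,
) -> VascularUnit:
    """Grow one vascular-unit skeleton.

    The unit has an LMA stub above the surface plane, an entry point on
    z=0, and downward-biased bifurcating growth with diameters tapering by
    ``params.taper`` per generation down to the ≥8 μm inclusion floor.
    Units drawn non-penetrating are truncated above the cortex/white-matter
    boundary; penetrating units are guaranteed to cross it.
    """
    X, Y, Z = params.slab_dims_um
    if penetrate_wm is None:
        penetrate_wm = bool(rng.random() < params.p_penetrate_wm)
    if root_diameter is None:
        med = np.sqrt(
            params.diameter_root_median_pos_um * params.diameter_root_median_neg_um
        )
        root_diameter = float(med * np.exp(rng.normal(0.0, 0.17)))
    root_diameter = max(root_diameter, params.diameter_floor_um)

    margin = max(params.lma_len_um * 0.7 + 10.0, min(150.0, X / 6, Y / 6))
    # penetrating arterioles keep a characteristic spacing; resample entry
    # sites that fall too close to previously drawn ones
    taken = existing_entries if existing_entries is not None else []
    for _ in range(30):
        x0 = rng.uniform(margin, X - margin)
        y0 = rng.uniform(margin, Y - margin)
        if not taken or min(
            (x0 - ex) ** 2 + (y0 - ey) ** 2 for ex, ey in taken
        ) >= params.min_entry_sep_um**2:
            break
    step = params.step_um

    nodes: dict[int, VesselNode] = {}
    next_id = [0]

    def add_node(pos: np.ndarray, radius: float, parent: int | None) -> int:
        nid = next_id[0]
        next_id[0] += 1
        nodes[nid] = VesselNode(nid, pos.copy(), radius, parent)
        return nid

    # LMA stub: runs along the surface then dips to the entry point; try a
    # few headings so stubs of neighbouring units do not overlap
    n_lma = max(2, int(round(params.lma_len_um / step)))
    entry_xy = np.array([x0, y0, 0.0])
    stub_pts: list[np.ndarray] | None = None
    best_score = -1.0
    for _attempt in range(12):
        lma_dir = _unit_vector(
            np.array([rng.normal(), rng.normal(), rng.uniform(0.15, 0.7)])
        )
        top = entry_xy - lma_dir * params.lma_len_um
        top[2] = min(top[2], -5.0)
        top[0] = np.clip(top[0], 10.0, X - 10.0)
        top[1] = np.clip(top[1], 10.0, Y - 10.0)
        cand = []
        for k in range(1, n_lma):
            t = k / n_lma
            pos = top + t * (entry_xy - top)
            pos[2] = min(pos[2], -1.0)  # strictly leptomeningeal
            cand.append(pos)
        if occupancy is None:
            stub_pts = cand
            break
        n_clear = sum(
            not occupancy.collides(pos, root_diameter / 2, 4.0, tag=unit_id)
            for pos in cand
        )
        if n_clear > best_score:  # heading with the least overlap wins
            best_score, stub_pts = n_clear, cand
        if n_clear == len(cand):
            break
    parent = add_node(top, root_diameter / 2, None)
    for pos in stub_pts:
        parent = add_node(pos, root_diameter / 2, parent)
        if occupancy is not None:
            occupancy.insert(pos.copy(), root_diameter / 2, tag=unit_id)

    stop_z = None if penetrate_wm else params.cortex_thickness_um - 5.0

    def radius_at(depth: int) -> float:
        return max(
            root_diameter / 2 * params.taper**depth, params.diameter_floor_um / 2
        )

    # chains to grow: (parent node id, start position, direction, depth, deep flag)
    stack = [
        (parent, np.array([x0, y0, 0.0]), np.array([0.0, 0.0, 1.0]), 0, penetrate_wm)
    ]
    deepest_leaf: tuple[int, float] = (parent, -np.inf)
    while stack:
        par, pos, direction, depth, deep = stack.pop()
        r = radius_at(depth)
        length = max(40.0, rng.normal(params.seg_len_mean_um, params.seg_len_sd_um))
        if depth == 0:
            # penetrating arterioles run unbranched through the upper
            # cortical layers; keep the entry stretch anatomically long
            length = max(length, 100.0 + 2 * params.bif_radius_factor * r)
        n_steps = max(3, int(round(length / step)))
        truncated = False
        chain_start = pos.copy()
        chain_pts: list[np.ndarray] = []
        for _ in range(n_steps):
            bias = 1.0 if deep else 0.45
            nxt = None
            cand_dir = direction
            for _try in range(5):  # steer around occupied tissue
                jitter = rng.normal(0.0, 0.35 * (1.0 + 0.8 * _try), 3)
                cand_dir = _unit_vector(
                    direction + jitter + np.array([0, 0, bias]) * 0.5
                )
                cand = pos + cand_dir * step
                cand[0] = min(max(cand[0], 20.0), X - 20.0)
                cand[1] = min(max(cand[1], 20.0), Y - 20.0)
                cand[2] = max(cand[2], 1.0)  # never re-surface
                if occupancy is None or not occupancy.collides(
                    cand, r, 4.0, tag=unit_id,
                    exempt_center=chain_start, exempt_radius=4.0 * r + 2.0 * step,
                ):
                    nxt = cand
                    break
            if nxt is None:
                # boxed in on all sides; vessels do not interpenetrate
                truncated = True
                break
            direction = cand_dir
            if stop_z is not None and nxt[2] > stop_z:
                truncated = True
                break
            if nxt[2] > Z - 30.0:
                truncated = True
                break
            pos = nxt
            par = add_node(pos, r, par)
            chain_pts.append(pos.copy())
        if occupancy is not None:
            # register the finished chain only now, so a chain does not
            # trip over its own freshly laid points
            for cp in chain_pts:
                occupancy.insert(cp, r, tag=unit_id)
        if pos[2] > deepest_leaf[1]:
            deepest_leaf = (par, pos[2])
        if truncated or depth >= params.max_depth:
            continue
        # penetrating arterioles reliably branch in the upper layers;
        # deeper, branching thins out toward the configured base rate
        p_branch = (
            0.95 if depth == 0 else 0.85 if depth == 1 else params.branch_prob
        )
        if rng.random() < p_branch:
            axis = _unit_vector(rng.normal(size=3))
            for sign, child_deep in ((+1, deep), (-1, False)):
                ang = np.deg2rad(rng.uniform(20.0, 45.0)) * sign
                child_dir = _unit_vector(
                    direction * np.cos(ang) + np.cross(axis, direction) * np.sin(ang)
                )
                if child_dir[2] < 0:
                    child_dir[2] = abs(child_dir[2])
                    child_dir = _unit_vector(child_dir)
                stack.append((par, pos.copy(), child_dir, depth + 1, child_deep))

    # guarantee white-matter penetration when drawn
    if penetrate_wm:
        leaf, zmax = deepest_leaf
        if zmax <= params.cortex_thickness_um:
            pos = nodes[leaf].position.copy()
            r = nodes[leaf].radius
            target = min(params.cortex_thickness_um + 40.0, Z - 30.0)
            while pos[2] < target:
                nxt = None
                for _try in range(6):  # steer around occupied tissue
                    lateral = rng.normal(0, 2.0 + 6.0 * _try, 2)
                    cand = pos + np.array([lateral[0], lateral[1], step])
                    cand[0] = np.clip(cand[0], 20.0, X - 20.0)
                    cand[1] = np.clip(cand[1], 20.0, Y - 20.0)
                    if occupancy is None or not occupancy.collides(
                        cand, r, 4.0, tag=unit_id,
                        exempt_center=pos, exempt_radius=2 * step,
                    ):
                        nxt = cand
                        break
                pos = nxt if nxt is not None else cand
                leaf = add_node(pos, r, leaf)
                if occupancy is not None:
                    occupancy.insert(pos.copy(), r, tag=unit_id)

    unit = VascularUnit(unit_id=unit_id, nodes=nodes, root_id=0)
    unit.truth["penetrates_wm_drawn"] = penetrate_wm
    unit.truth["root_diameter_um"] = root_diameter
    unit.truth["entry_point_true"] = np.array([x0, y0, 0.0])
    return unit


# ----------------------------------------------------------------------
# deposition statuses
# ----------------------------------------------------------------------

def _draw_front_depth(params: CohortParams, rng: np.random.Generator) -> tuple[int, float]:
    """Front depth F with P(F >= d) = front_reach_probs[d] (single-U draw)."""
    u = rng.random()
    fr = params.front_reach_probs
    front = -1
    for d in range(len(fr)):
        if u < fr[d]:
            front = d
    return front, u


def assign_abeta(
    unit: VascularUnit,
    params: CohortParams,
    rng: np.random.Generator,
    force_positive: bool | None = None,
) -> VascularUnit:
    """Draw per-label Aβ truth statuses for one labeled unit.

    A positive unit gets an independent LMA status, a deposition front over
    D0..D6 (contiguous prefix), and — rarely and mutually exclusively — a
    skip pattern (one deep segment positive over negative cortical
    intermediates, LMA/D0 retained) or a white-matter-confined pattern.
    A drawn-positive unit that ends up with no positive label (possible
    when both the LMA draw and the front miss) is recorded negative.
    """
    labels = sorted(unit.labels_present)
    positive = (
        bool(rng.random() < params.p_unit_abeta)
        if force_positive is None
        else force_positive
    )
    status: dict[SegmentLabel, bool] = {lab: False for lab in labels}
    front = -1
    pattern = "none"
    if positive:
        lma_pos = bool(rng.random() < params.p_lma_abeta)
        r = rng.random()
        if r < params.p_skip:
            pattern = "skip"
        elif r < params.p_skip + params.p_wm_confined and any(
            s.in_white_matter for s in unit.segments
        ):
            pattern = "wm_confined"
        else:
            pattern = "front"

        if params.independent_bernoulli_front:
            for lab in labels:
                if lab.kind == "DEPTH":
                    status[lab] = bool(
                        rng.random() < params.front_reach_probs[lab.depth]
                    )
                elif lab.kind == "BIFURCATION":
                    status[lab] = status.get(D(lab.depth), False)
        else:
            front, u = _draw_front_depth(params, rng)
            for lab in labels:
                if lab.kind == "DEPTH":
                    status[lab] = lab.depth <= front
                elif lab.kind == "BIFURCATION":
                    if params.front_reach_probs_bif is not None:
                        status[lab] = u < params.front_reach_probs_bif[lab.depth]
                    else:  # tie to the shallower depth
                        status[lab] = lab.depth <= front

        if LMA in status:
            status[LMA] = lma_pos

        if pattern == "skip":
            deep = [lab for lab in labels if lab.order >= 2.0]
            if deep:
                target = deep[rng.integers(len(deep))]
                for lab in labels:
                    if 0.0 < lab.order < target.order:
                        status[lab] = False
                status[target] = True
                if not status.get(LMA, False):
                    if D(0) in status:
                        status[D(0)] = True
                    elif LMA in status:
                        status[LMA] = True
            else:
                pattern = "front"
        elif pattern == "wm_confined":
            wm_labels = {s.label for s in unit.segments if s.in_white_matter}
            for lab in labels:
                if lab.order > 0.0:
                    status[lab] = lab in wm_labels
            if not any(status.values()) and D(0) in status:
                status[D(0)] = True

        if not any(status.values()):
            positive = False
            pattern = "none"

    unit.truth["abeta"] = status
    unit.truth["abeta_positive"] = positive
    unit.truth["front_depth"] = front
    unit.truth["pattern"] = pattern
    unit.truth["coverage"] = {
        lab: (params.sporadic_fill if pos else 0.0) for lab, pos in status.items()
    }
    return unit


def assign_sma_loss(
    unit: VascularUnit, params: CohortParams, rng: np.random.Generator
) -> VascularUnit:
    """Draw SMA-loss truth nested inside the Aβ-positive extent.

    Only Aβ-positive units may lose SMA.  The most superficial lost label
    (onset) is drawn from ``sma_onset_dist`` restricted to the unit's
    positive labels; loss then runs contiguously from the onset through
    every deeper Aβ-positive label.
    """
    abeta: dict[SegmentLabel, bool] = unit.truth.get("abeta", {})
    lost: set[SegmentLabel] = set()
    onset: SegmentLabel | None = None
    if unit.truth.get("abeta_positive") and rng.random() < params.p_sma_loss:
        pos_labels = sorted(lab for lab, p in abeta.items() if p)
        available: dict[str, SegmentLabel] = {}
        for cat in ONSET_CATEGORIES:
            if cat == "LMA" and LMA in pos_labels:
                available["LMA"] = LMA
            elif cat == "D0" and D(0) in pos_labels:
                available["D0"] = D(0)
            elif cat == "D1" and D(1) in pos_labels:
                available["D1"] = D(1)
            elif cat == "deeper":
                deeper = [lab for lab in pos_labels if lab.order > 1.0]
                if deeper:
                    available["deeper"] = deeper[0]
        if available:
            cats = list(available)
            w = np.array([params.sma_onset_dist[c] for c in cats])
            if w.sum() <= 0:
                w = np.ones(len(cats))
            onset_cat = cats[rng.choice(len(cats), p=w / w.sum())]
            onset = available[onset_cat]
            lost = {lab for lab in pos_labels if lab.order >= onset.order}
    unit.truth["sma_lost"] = lost
    unit.truth["sma_onset"] = onset
    return unit


# ----------------------------------------------------------------------
# plaques and dyshoric sleeves
# ----------------------------------------------------------------------

def sample_plaques(
    units: Sequence[VascularUnit], params: CohortParams, rng: np.random.Generator
) -> list[PlaqueSpot]:
    """Homogeneous Poisson plaque candidates in the cortex, thinned near
    Aβ-positive units.

    Candidates fall with intensity ``plaque_lambda0`` per μm³ in the
    cortical sub-volume; a candidate within 100 μm of any Aβ-positive
    unit's centerline survives with probability ``plaque_thinning_theta``,
    otherwise with probability 1.
    """
    X, Y, Z = params.slab_dims_um
    vol = X * Y * params.cortex_thickness_um
    n = rng.poisson(params.plaque_lambda0 * vol)
    if n == 0:
        return []
    pts = np.column_stack(
        [
            rng.uniform(0, X, n),
            rng.uniform(0, Y, n),
            rng.uniform(0, params.cortex_thickness_um, n),
        ]
    )
    radii = np.clip(
        rng.normal(params.plaque_radius_mean_um, params.plaque_radius_sd_um, n),
        8.0,
        45.0,
    )
    pos_polylines = [
        s.polyline
        for u in units
        if u.truth.get("abeta_positive")
        for s in u.segments
    ]
    if pos_polylines and params.plaque_thinning_theta < 1.0:
        dist = min_distance_to_polylines(pts, pos_polylines)
        near = dist <= 100.0
        keep = ~near | (rng.random(n) < params.plaque_thinning_theta)
    else:
        keep = np.ones(n, dtype=bool)
    return [
        PlaqueSpot(center=pts[i], radius_um=float(radii[i]))
        for i in range(n)
        if keep[i]
    ]


def place_dyshoric(
    units: Sequence[VascularUnit], params: CohortParams, rng: np.random.Generator
) -> list[DyshoricSleeve]:
    """Assign dyshoric sleeves to Aβ-positive cortical units.

    Each Aβ-positive unit confined to the cortex is affected with
    probability ``p_dyshoric_unit``; the affected segment is D0 with
    probability ``dyshoric_d0_share``, otherwise uniform among the unit's
    other Aβ-positive cortical labels.
    """
    sleeves: list[DyshoricSleeve] = []
    for unit in units:
        if not unit.truth.get("abeta_positive") or unit.penetrates_wm:
            continue
        if rng.random() >= params.p_dyshoric_unit:
            continue
        abeta = unit.truth["abeta"]
        cortical_pos = sorted(
            lab
            for lab, p in abeta.items()
            if p and lab.order >= 0.0
        )
        if not cortical_pos:
            continue
        others = [lab for lab in cortical_pos if lab != D(0)]
        if D(0) in cortical_pos and (
            rng.random() < params.dyshoric_d0_share or not others
        ):
            label = D(0)
        elif others:
            label = others[rng.integers(len(others))]
        else:
            label = cortical_pos[0]
        candidates = [
            (i, s) for i, s in enumerate(unit.segments) if s.label == label
        ]
        idx, seg = max(candidates, key=lambda t: t[1].length_um)
        ext = min(params.dyshoric_len_um, seg.length_um)
        start = rng.uniform(0.0, seg.length_um - ext) if seg.length_um > ext else 0.0
        sleeves.append(
            DyshoricSleeve(
                unit_id=unit.unit_id,
                label=label,
                start_um=float(start),
                length_um=float(ext),
                annulus_um=params.dyshoric_annulus_um,
                segment_index=idx,
            )
        )
    return sleeves


# ----------------------------------------------------------------------
# cohort orchestration
# ----------------------------------------------------------------------

def generate_cohort(
    params: CohortParams,
    seed: int | None = None,
    force_all_positive: bool = False,
) -> GroundTruthSample:
    """Generate one fully annotated synthetic sample.

    Pure function of ``(params, seed)``: unit geometry (root diameters
    drawn from the status-conditional lognormals), depth labeling, Aβ and
    SMA truth statuses, plaque spots, and dyshoric sleeves.
    """
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    units: list[VascularUnit] = []
    entries: list[tuple[float, float]] = []
    occupancy = SpatialHash() if params.avoid_collisions else None
    for i in range(params.n_units):
        positive = True if force_all_positive else bool(
            rng.random() < params.p_unit_abeta
        )
        if positive:
            med, sig = (
                params.diameter_root_median_pos_um,
                params.diameter_sigma_log_pos,
            )
        else:
            med, sig = (
                params.diameter_root_median_neg_um,
                params.diameter_sigma_log_neg,
            )
        root_d = float(med * np.exp(rng.normal(0.0, sig)))
        unit = generate_unit_geometry(
            params, rng, unit_id=i, root_diameter=root_d,
            existing_entries=entries, occupancy=occupancy,
        )
        ep = unit.truth["entry_point_true"]
        entries.append((float(ep[0]), float(ep[1])))
        find_entry_point(unit, 0.0)
        label_depths(
            unit,
            0.0,
            bif_radius_factor=params.bif_radius_factor,
            cortex_z=params.cortex_thickness_um,
        )
        assign_abeta(unit, params, rng, force_positive=positive)
        assign_sma_loss(unit, params, rng)
        units.append(unit)
    spots = sample_plaques(units, params, rng)
    sleeves = place_dyshoric(units, params, rng)
    return GroundTruthSample(
        units=units, spots=spots, dyshoric=sleeves, params=params, seed=seed
    )
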