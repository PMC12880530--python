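"""Vessel skeletons: SWC I/O, entry points, depth labeling, morphometry.

A *vascular unit* is one anatomically continuous arterial tree rooted at a
leptomeningeal artery (LMA).  World coordinates are in μm with the cortical
surface plane at ``z = surface_z`` (0 by default) and depth increasing with
``+z``.  Skeletons are exchanged as standard 7-column SWC with the radius
column in μm; we require parents to be declared before children and write
type code 7 for vessels.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
from scipy import ndimage

from .labels import DEEPER, LMA, SegmentLabel

SWC_VESSEL_TYPE = 7


@dataclass
class VesselNode:
    id: int
    position: np.ndarray  # (3,) world μm, (x, y, z)
    radius: float
    parent_id: int | None  # None for the root

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.radius <= 0:
            raise ValueError(f"node {self.id}: non-positive radius {self.radius}")


@dataclass
class VesselSegment:
    """A labeled stretch of centerline with per-point radii."""

    unit_id: int
    label: SegmentLabel
    polyline: np.ndarray  # (K, 3) world μm, K >= 2
    radii: np.ndarray  # (K,)
    in_white_matter: bool = False
    status: Any = None  # SegmentStatus, filled by classification

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.polyline.shape[0] < 2:
            raise ValueError("segment polyline needs >= 2 points")

    @property
    def length_um(self) -> float:
        return segment_length(self.polyline)


@dataclass
class VascularUnit:
    unit_id: int
    nodes: dict[int, VesselNode]
    root_id: int
    segments: list[VesselSegment] = field(default_factory=list)
    entry_point: np.ndarray | None = None
    has_lma_stub: bool = False
    penetrates_wm: bool = False
    excluded_reason: str | None = None  # None | "no-entry" | "perivascular-artifact"
    # ground-truth annotations attached by the synthetic cohort generator
    truth: dict[str, Any] = field(default_factory=dict)

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for n in self.nodes.values():
            if n.parent_id is not None:
                ch[n.parent_id].append(n.id)
        return ch

    @property
    def labels_present(self) -> set[SegmentLabel]:
        return {s.label for s in self.segments}

    def segments_with(self, label: SegmentLabel) -> list[VesselSegment]:
        return [s for s in self.segments if s.label == label]

    def max_z(self) -> float:
        return max(n.position[2] for n in self.nodes.values())


class SWCParseError(ValueError):
    pass


def read_swc(path: str | Path | io.TextIOBase) -> list[VascularUnit]:
    """Parse an SWC file into one unit per root.

    Dialect: 7 whitespace-separated columns ``id type x y z radius parent``;
    ``#`` comments; parent id -1 marks a root; parents must be declared
    before children (forward references are an error); radius must be > 0.
    """
    if isinstance(path, (str, Path)):
        lines = Path(path).read_text().splitlines()
    else:
        lines = path.read().splitlines()
    nodes: dict[int, VesselNode] = {}
    root_of: dict[int, int] = {}  # node id -> root id of its tree
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(cols)}")
        try:
            nid = int(cols[0])
            x, y, z, r = (float(c) for c in cols[2:6])
            pid = int(cols[6])
        except ValueError as exc:
            raise SWCParseError(f"line {lineno}: {exc}") from None
        if nid in nodes:
            raise SWCParseError(f"line {lineno}: duplicate node id {nid}")
        if r <= 0:
            raise SWCParseError(f"line {lineno}: non-positive radius {r}")
        if pid == -1:
            parent = None
        else:
            if pid == nid:
                raise SWCParseError(f"line {lineno}: node {nid} is its own parent")
            if pid not in nodes:
                raise SWCParseError(
                    f"line {lineno}: parent {pid} of node {nid} not declared before use"
                )
            parent = pid
        nodes[nid] = VesselNode(nid, np.array([x, y, z]), r, parent)
        root_of[nid] = nid if parent is None else root_of[pid]

    units: list[VascularUnit] = []
    for i, root in enumerate(sorted({root_of[n] for n in nodes})):
        sub = {nid: n for nid, n in nodes.items() if root_of[nid] == root}
        units.append(VascularUnit(unit_id=i, nodes=sub, root_id=root))
    return units


def write_swc(units: Sequence[VascularUnit], path: str | Path) -> None:
    """Serialize units to one SWC file, renumbering nodes sequentially."""
    out: list[str] = ["# SWC vessel skeleton (type 7); coordinates and radii in um"]
    new_id = 0
    for unit in units:
        remap: dict[int, int] = {}
        for nid in _topo_order(unit):
            n = unit.nodes[nid]
            new_id += 1
            remap[nid] = new_id
            pid = -1 if n.parent_id is None else remap[n.parent_id]
            x, y, z = n.position
            out.append(
                f"{new_id} {SWC_VESSEL_TYPE} {x:.6f} {y:.6f} {z:.6f} "
                f"{n.radius:.6f} {pid}"
            )
    Path(path).write_text("\n".join(out) + "\n")


def _topo_order(unit: VascularUnit) -> list[int]:
    """Node ids root-first so every parent precedes its children."""
    ch = unit.children_map()
    order: list[int] = []
    stack = [unit.root_id]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(sorted(ch[nid], reverse=True))
    return order


def segment_length(polyline: np.ndarray) -> float:
    """Total Euclidean length of an ordered polyline (μm)."""
    pts = np.asarray(polyline, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("polyline needs >= 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def find_entry_point(unit: VascularUnit, surface_z: float = 0.0) -> np.ndarray | None:
    """Locate the parenchymal entry point on the surface plane.

    Returns the linear interpolation of the first root-to-descendant edge
    crossing ``surface_z`` (in root-first order) and stores it on the unit.
    Units that never cross the plane cannot be confirmed to penetrate the
    parenchyma and are flagged ``excluded_reason='no-entry'``.
    """
    ch = unit.children_map()
    for nid in _topo_order(unit):
        n = unit.nodes[nid]
        for cid in ch[nid]:
            c = unit.nodes[cid]
            z0, z1 = n.position[2], c.position[2]
            if z0 < surface_z <= z1:
                t = (surface_z - z0) / (z1 - z0)
                entry = n.position + t * (c.position - n.position)
                unit.entry_point = entry
                unit.truth.setdefault("entry_edge", (nid, cid))
                unit.has_lma_stub = True
                unit.excluded_reason = None
                return entry
    unit.excluded_reason = "no-entry"
    unit.entry_point = None
    return None


def _cut_polyline(
    pts: np.ndarray, radii: np.ndarray, s0: float, s1: float
) -> tuple[np.ndarray, np.ndarray] | None:
    """Sub-polyline between arclengths s0..s1, interpolating the cut points."""
    if s1 - s0 <= 1e-12:
        return None
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    total = cum[-1]
    s0, s1 = max(0.0, s0), min(total, s1)
    if s1 - s0 <= 1e-12:
        return None

    def interp(s: float) -> tuple[np.ndarray, float]:
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(steps) - 1)
        t = 0.0 if steps[i] == 0 else (s - cum[i]) / steps[i]
        p = pts[i] + t * (pts[i + 1] - pts[i])
        r = radii[i] + t * (radii[i + 1] - radii[i])
        return p, r

    inner = (cum > s0 + 1e-9) & (cum < s1 - 1e-9)
    p0, r0 = interp(s0)
    p1, r1 = interp(s1)
    out_pts = np.vstack([p0, pts[inner], p1])
    out_r = np.concatenate([[r0], radii[inner], [r1]])
    return out_pts, out_r


def label_depths(
    unit: VascularUnit,
    surface_z: float = 0.0,
    bif_radius_factor: float = 2.0,
    cortex_z: float | None = None,
) -> list[VesselSegment]:
    """Partition a unit's centerline into labeled segments.

    The portion above the entry point is LMA.  Below it the branch-order
    counter starts at D0 and increments at every branch node; the arc
    within ``bif_radius_factor x local radius`` of a branch node between
    depths d and d+1 forms the bifurcation segment D{d}-D{d+1} (emitted as
    one record per arc: parent tail plus each child head).  Orders beyond 6
    pool into DEEPER.  Trifurcations count as a single depth increment.
    Segment lengths partition the total centerline length exactly.
    """
    if unit.entry_point is None and unit.excluded_reason is None:
        find_entry_point(unit, surface_z)
    if unit.excluded_reason == "no-entry":
        return []
    entry = unit.entry_point
    pn, cn = unit.truth["entry_edge"]
    ch = unit.children_map()
    segments: list[VesselSegment] = []

    def emit(label: SegmentLabel, pts: np.ndarray, radii: np.ndarray) -> None:
        # drop zero-length steps (e.g. a chain start coinciding with its node)
        keep = np.concatenate(
            [[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12]
        )
        pts, radii = pts[keep], radii[keep]
        if pts.shape[0] < 2:
            return
        seg = VesselSegment(unit.unit_id, label, pts, radii)
        if cortex_z is not None:
            seg.in_white_matter = bool((seg.polyline[:, 2] > cortex_z).any())
        segments.append(seg)

    # --- LMA side: everything reachable from the root without the entry edge
    entry_r = float(
        np.interp(
            np.linalg.norm(entry - unit.nodes[pn].position),
            [0.0, np.linalg.norm(unit.nodes[cn].position - unit.nodes[pn].position)],
            [unit.nodes[pn].radius, unit.nodes[cn].radius],
        )
    )
    for first, start_pt, start_r in _lma_chain_starts(unit, ch, pn, cn):
        pts, radii, _terminal = _follow_chain(unit, ch, first, start_pt, start_r, skip=cn)
        if pts.shape[0] >= 2 and segment_length(pts) > 1e-9:
            emit(LMA, pts, radii)
    # append the stub from the crossing parent to the entry point itself
    stub = np.vstack([unit.nodes[pn].position, entry])
    if segment_length(stub) > 1e-9:
        emit(LMA, stub, np.array([unit.nodes[pn].radius, entry_r]))

    # --- parenchymal side: chain walk with depth counter
    # stack items: (first node, start point, start radius, depth, head_cut, head_label)
    stack: list[tuple[int, np.ndarray, float, int, float, SegmentLabel | None]] = [
        (cn, entry, entry_r, 0, 0.0, None)
    ]
    while stack:
        first, start_pt, start_r, depth, head_cut, head_label = stack.pop()
        pts, radii, terminal = _follow_chain(unit, ch, first, start_pt, start_r)
        total = segment_length(pts)
        kids = ch[terminal]
        tail_cut = 0.0
        if len(kids) >= 2:  # ends at a branch node
            tail_cut = bif_radius_factor * unit.nodes[terminal].radius
        head_cut = min(head_cut, total)
        tail_cut = min(tail_cut, total - head_cut)
        # a sliver of a depth segment between two bifurcation arcs is a
        # slicing artifact; absorb it into the adjacent bifurcation arc
        mid = total - head_cut - tail_cut
        if 0.0 < mid < 6.0:
            if len(kids) >= 2:
                tail_cut += mid
            elif head_label is not None:
                head_cut += mid
        if head_label is not None:
            piece = _cut_polyline(pts, radii, 0.0, head_cut)
            if piece:
                emit(head_label, *piece)
        piece = _cut_polyline(pts, radii, head_cut, total - tail_cut)
        if piece:
            emit(SegmentLabel.for_depth(depth), *piece)
        if len(kids) >= 2:
            bif_label = SegmentLabel.for_bifurcation(depth)
            piece = _cut_polyline(pts, radii, total - tail_cut, total)
            if piece:
                emit(bif_label, *piece)
            bpos = unit.nodes[terminal].position
            brad = unit.nodes[terminal].radius
            for kid in kids:
                stack.append(
                    (kid, bpos, brad, depth + 1, bif_radius_factor * brad, bif_label)
                )

    unit.segments = segments
    if cortex_z is not None:
        unit.penetrates_wm = any(s.in_white_matter for s in segments)
    return segments


def _lma_chain_starts(
    unit: VascularUnit, ch: dict[int, list[int]], pn: int, cn: int
) -> Iterable[tuple[int, np.ndarray, float]]:
    """Chain start nodes covering the root-side (leptomeningeal) component."""
    root = unit.nodes[unit.root_id]
    yield unit.root_id, root.position, root.radius


def _follow_chain(
    unit: VascularUnit,
    ch: dict[int, list[int]],
    first: int,
    start_pt: np.ndarray,
    start_r: float,
    skip: int | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Walk from ``start_pt`` through ``first`` until a leaf or branch node.

    ``skip`` drops one child id (used to stop the LMA walk at the entry
    edge).  Returns (points, radii, terminal node id).
    """
    pts = [np.asarray(start_pt, dtype=float)]
    radii = [start_r]
    nid = first
    while True:
        n = unit.nodes[nid]
        pts.append(n.position)
        radii.append(n.radius)
        kids = [k for k in ch[nid] if k != skip]
        if len(kids) != 1:
            return np.asarray(pts), np.asarray(radii), nid
        nid = kids[0]


def estimate_radius_profile(
    volume: Any,
    polyline: np.ndarray,
    binarize_threshold: float,
) -> np.ndarray:
    """Vessel radius (μm) at each centerline point from the SMA channel.

    The SMA channel is binarized at ``binarize_threshold`` and the
    Euclidean distance transform (EDT) of the foreground computed.  The
    EDT peaks on the tube axis but voxel centers rarely sit exactly there,
    so at each centerline point p the radius is recovered from the tight
    triangle-inequality bound ``min over nearby voxel centers v of
    (EDT(v) + |v - p|)``, minus a quarter voxel for the discretized
    boundary (the nearest background voxel *center* lies up to half a
    voxel beyond the true surface).  Points in background get radius 0.
    """
    import warnings

    sma = np.asarray(volume.sma)
    vs = float(volume.voxel_size_um)
    fg = sma >= binarize_threshold
    pts = np.asarray(polyline, dtype=float)
    if not fg.any():
        warnings.warn("empty SMA foreground; radius profile is all zero")
        return np.zeros(pts.shape[0])
    edt = ndimage.distance_transform_edt(fg) * vs  # μm
    origin = np.asarray(getattr(volume, "origin_um", (0.0, 0.0, 0.0)), dtype=float)
    idx = (pts - origin) / vs  # fractional voxel index, world (x,y,z) order
    base = np.floor(idx).astype(int)
    shape_xyz = np.array(edt.shape)[::-1]
    offsets = np.array(
        [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]
        + [(i, j, k) for i in (-1, 0, 1, 2) for j in (-1, 0, 1, 2)
           for k in (-1, 0, 1, 2) if not ({i, j, k} <= {0, 1})]
    )
    best = np.full(pts.shape[0], np.inf)
    inside_any = np.zeros(pts.shape[0], dtype=bool)
    for off in offsets:
        nb = np.clip(base + off, 0, shape_xyz - 1)
        vals = edt[nb[:, 2], nb[:, 1], nb[:, 0]]
        d = np.linalg.norm((nb + 0.0) * vs + origin - pts + 0.0, axis=1)
        cand = vals + d
        in_fg = vals > 0
        inside_any |= in_fg & (d <= vs * np.sqrt(3))
        best = np.minimum(best, cand)
    out = np.clip(best - 0.25 * vs, 0.0, None)
    out[~inside_any] = 0.0
    return out


def d0_external_diameter(
    unit: VascularUnit, radii_source: str = "truth"
) -> float | None:
    """External diameter (μm) of the D0 segment: twice the median radius.

    ``radii_source='truth'`` uses the skeleton's radius column;
    ``'measured'`` uses radii previously written by radius-profile
    estimation into ``segment.status``.  Units without a D0 segment with at
    least 3 radius samples yield None and are excluded from diameter
    statistics.  The median keeps the estimate robust to focal bulges.
    """
    from .labels import D

    segs = unit.segments_with(D(0))
    samples: list[float] = []
    for s in segs:
        if radii_source == "measured" and s.status is not None and getattr(
            s.status, "measured_radii", None
        ) is not None:
            samples.extend(np.asarray(s.status.measured_radii).tolist())
        else:
            samples.extend(s.radii.tolist())
    if len(samples) < 3:
        return None
    return float(2.0 * np.median(samples))
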