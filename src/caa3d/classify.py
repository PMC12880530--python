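"""Aβ / SMA segment classification and vascular-load statistics.

Statuses are semiquantitative at the (unit, label) level, mirroring how
segments are scored by eye: an Aβ-positive segment carries any contiguous
wall deposit of meaningful extent; a segment loses SMA when its wall can
no longer be traced continuously in the SMA channel.  The *vascular Aβ
load* of a sample is the percentage of Aβ-positive vascular units, classed
low (<40%), moderate (40–60%, closed interval), or high (>60%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import ndimage

from .labels import LMA, SegmentLabel
from .plaques import _ring_basis, resample_polyline
from .topology import VascularUnit, VesselSegment


@dataclass
class SegmentStatus:
    abeta_positive: bool = False
    sma_present: bool = True
    abeta_coverage: float = 0.0
    sma_longest_gap_um: float = 0.0
    measured_radii: np.ndarray | None = None


@dataclass
class LoadSummary:
    n_units_total: int
    n_units_abeta_pos: int
    load_fraction: float
    load_class: str  # low | moderate | high
    per_segment_rates: dict[str, float]

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_units_total": self.n_units_total,
            "n_units_abeta_pos": self.n_units_abeta_pos,
            "load_fraction": self.load_fraction,
            "load_class": self.load_class,
            "per_segment_rates": dict(self.per_segment_rates),
        }


class OutOfBoundsError(ValueError):
    pass


def _sample_volume(img: np.ndarray, origin: np.ndarray, vs: float,
                   pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear samples at world points; returns (values, inside mask)."""
    idx = ((pts - origin) / vs)[:, ::-1].T  # world (x,y,z) -> index (z,y,x)
    shape = np.array(img.shape)
    inside = np.all((idx >= 0) & (idx <= (shape - 1)[:, None]), axis=0)
    vals = np.zeros(pts.shape[0])
    if inside.any():
        vals[inside] = ndimage.map_coordinates(
            img, idx[:, inside], order=1, mode="constant", cval=0.0
        )
    return vals, inside


def _longest_run_um(flags: np.ndarray, step_um: float) -> float:
    """Length spanned by the longest contiguous True run of stations."""
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return max(0, best - 1) * step_um if best > 1 else (step_um * 0.5 if best else 0.0)


def classify_segment_abeta(
    volume_abeta: Any,
    segment: VesselSegment,
    wall_band: tuple[float, float] = (0.0, 6.0),
    intensity_threshold: float = 60.0,
    run_min_um: float = 10.0,
    step_um: float = 2.0,
    sma_ratio: float = 0.8,
    ignore_spots: Sequence[Any] = (),
    far_control: bool = True,
) -> SegmentStatus:
    """Score one segment's mural Aβ from the raster.

    Aβ intensity is sampled on a thin annulus just outside the local vessel
    radius at stations every ``step_um`` along the centerline.  A sample
    counts as deposit only when it is Aβ-specific: above the intensity
    threshold and, when an SMA channel is available on the volume, not
    matched by comparable SMA intensity (``sma >= sma_ratio × aβ`` marks
    dual-channel autofluorescence).  Samples inside a detected plaque
    sphere (``ignore_spots``) are masked, so parenchymal blobs hugging the
    wall are not mistaken for mural deposit.  A station is deposit-bearing
    when at least half of its usable circumferential samples are deposit —
    a one-sided bright patch does not wrap the wall.  The segment is
    positive iff deposit stations form a contiguous run of at least
    ``run_min_um`` (capped at the segment length, so a fully covered short
    segment is positive).  Raises :class:`OutOfBoundsError` when the
    centerline leaves the volume.
    """
    img = np.asarray(volume_abeta.abeta, dtype=float)
    sma_img = getattr(volume_abeta, "sma", None)
    if sma_img is not None:
        sma_img = np.asarray(sma_img, dtype=float)
    vs = float(volume_abeta.voxel_size_um)
    origin = np.asarray(getattr(volume_abeta, "origin_um", (0.0, 0.0, 0.0)), float)
    pts, tang, radii = resample_polyline(segment.polyline, segment.radii, step_um)
    center_vals, center_inside = _sample_volume(img, origin, vs, pts)
    if not center_inside.all():
        raise OutOfBoundsError(
            f"unit {segment.unit_id} segment {segment.label}: centerline outside volume"
        )
    spot_centers = (
        np.array([s.center for s in ignore_spots]) if len(ignore_spots) else None
    )
    # mask only the bright core of a detected spot (a Gaussian blob of
    # this scale falls below the deposit threshold well inside its nominal
    # radius), so one spot does not blanket a whole short segment
    spot_radii = (
        np.array([s.radius_um for s in ignore_spots]) * 0.8
        if len(ignore_spots)
        else None
    )
    n_az = 8
    n_rad = 3
    angles = np.linspace(0, 2 * np.pi, n_az, endpoint=False)
    r_off = np.linspace(wall_band[0] + 0.5, wall_band[1] - 0.5, n_rad)
    K = pts.shape[0]
    # build every ring sample point for the whole segment in one array
    basis = np.array([_ring_basis(t) for t in tang])  # (K, 2, 3)
    dirs = (
        np.cos(angles)[None, :, None] * basis[:, None, 0, :]
        + np.sin(angles)[None, :, None] * basis[:, None, 1, :]
    )  # (K, A, 3)
    rr = radii[:, None] + r_off[None, :]  # (K, R)
    sp = (
        pts[:, None, None, :]
        + dirs[:, :, None, :] * rr[:, None, :, None]
    ).reshape(-1, 3)  # (K*A*R, 3)
    vals, _ = _sample_volume(img, origin, vs, sp)
    bright = vals > intensity_threshold
    clean = bright
    conflicted = np.zeros_like(bright)
    if sma_img is not None:
        # wall tissue sits inboard of the band; a sample about as bright
        # in SMA as in Aβ (another vessel's wall, a dual-channel punctum)
        # is ambiguous, not Aβ-specific deposit
        sma_vals, _ = _sample_volume(sma_img, origin, vs, sp)
        sma_ok = sma_vals < np.maximum(sma_ratio * vals, intensity_threshold)
        clean = bright & sma_ok
        conflicted = bright & ~sma_ok
    masked = np.zeros(sp.shape[0], dtype=bool)
    if spot_centers is not None:
        d2 = ((sp[:, None, :] - spot_centers[None]) ** 2).sum(axis=2)
        masked = (d2 <= (spot_radii**2)[None, :]).any(axis=1)
    clean = (clean & ~masked).reshape(K, n_az, n_rad)
    conflicted = (conflicted & ~masked).reshape(K, n_az, n_rad)
    masked = masked.reshape(K, n_az, n_rad)
    # mural deposit is a thin shell hugging the wall; a far control sample
    # beyond the band separates it from extended structures (parenchymal
    # blobs, sleeves, crossing vessels) that happen to enter the annulus
    if far_control:
        far = (
            pts[:, None, :] + dirs * (radii[:, None] + wall_band[1] + 5.0)[:, :, None]
        ).reshape(-1, 3)
        far_vals, _ = _sample_volume(img, origin, vs, far)
        far_ok = (far_vals <= intensity_threshold).reshape(K, n_az)
    else:  # e.g. under a dyshoric sleeve, which explains the far signal
        far_ok = np.ones((K, n_az), dtype=bool)
    az_deposit = clean.any(axis=2) & far_ok
    # an azimuth is unusable when it cannot be judged: everything masked,
    # only dual-channel-conflicted signal, or an extended structure behind
    az_unusable = (
        masked.all(axis=2)
        | ~far_ok
        | (conflicted.any(axis=2) & ~clean.any(axis=2))
    ) & ~az_deposit
    az_usable = (~az_unusable).sum(axis=1)
    n_deposit = az_deposit.sum(axis=1)
    # mural deposit leaves the lumen dark; Aβ on the centerline itself
    # means a parenchymal blob swallowed the vessel locally — unjudgeable
    lumen_dark = center_vals <= intensity_threshold
    station_known = (az_usable >= 4) & lumen_dark
    station_pos = station_known & (n_deposit >= 0.5 * az_usable)
    seg_len = segment.length_um
    # longest contiguous deposit run; unknown stations (too few usable
    # azimuths) bridge a run rather than breaking it
    s = np.linspace(0.0, seg_len, K)
    run = 0.0
    start = None
    for i in range(K):
        if not station_known[i]:
            continue
        if station_pos[i]:
            if start is None:
                start = s[i]
            run = max(run, s[i] - start + step_um)
        else:
            start = None
    run = min(run, seg_len)
    effective_min = min(run_min_um, seg_len)
    status = segment.status or SegmentStatus()
    status.abeta_positive = bool(run >= effective_min - 1e-9)
    status.abeta_coverage = float(station_pos.mean())
    segment.status = status
    return status


def classify_segment_sma(
    volume_sma: Any,
    segment: VesselSegment,
    intensity_threshold: float = 60.0,
    gap_max_um: float = 20.0,
    step_um: float = 2.0,
) -> SegmentStatus:
    """Score SMA continuity along the centerline.

    The wall is traceable (``sma_present``) iff the longest contiguous
    below-threshold run is at most ``gap_max_um`` (inclusive boundary).
    An untraceable Aβ-positive segment is the Aβ+/SMA− class.
    """
    img = np.asarray(volume_sma.sma, dtype=float)
    vs = float(volume_sma.voxel_size_um)
    origin = np.asarray(getattr(volume_sma, "origin_um", (0.0, 0.0, 0.0)), float)
    pts, _, _ = resample_polyline(segment.polyline, segment.radii, step_um)
    vals, inside = _sample_volume(img, origin, vs, pts)
    if not inside.all():
        raise OutOfBoundsError(
            f"unit {segment.unit_id} segment {segment.label}: centerline outside volume"
        )
    gap = _longest_run_um(vals <= intensity_threshold, step_um)
    status = segment.status or SegmentStatus()
    status.sma_longest_gap_um = float(gap)
    status.sma_present = bool(gap <= gap_max_um + 1e-9)
    segment.status = status
    return status


def apply_truth_statuses(unit: VascularUnit) -> None:
    """Fill per-segment statuses from the generator's ground truth."""
    abeta = unit.truth.get("abeta", {})
    lost = unit.truth.get("sma_lost", set())
    coverage = unit.truth.get("coverage", {})
    for seg in unit.segments:
        seg.status = SegmentStatus(
            abeta_positive=bool(abeta.get(seg.label, False)),
            sma_present=seg.label not in lost,
            abeta_coverage=float(coverage.get(seg.label, 0.0)),
        )


def classify_unit(
    unit: VascularUnit,
    volume: Any,
    wall_band: tuple[float, float] = (0.0, 6.0),
    intensity_threshold: float = 60.0,
    run_min_um: float = 10.0,
    gap_max_um: float = 20.0,
    spots: Sequence[Any] = (),
) -> None:
    """Raster-path classification of every segment of one unit.

    ``spots`` (detected plaques) are masked out of the mural-Aβ scoring.
    Segments carrying a dyshoric sleeve (flagged first) are scored without
    the far-control check, since the sleeve explains the extended
    perivascular signal.
    """
    from .plaques import flag_dyshoric, min_distance_to_polylines

    # a "spot" sitting on this unit's own wall is mural deposit picked up
    # by the blob detector, not a parenchymal plaque: the 10 μm inner band
    # bound applies to classification masking too
    spots = list(spots)
    if spots:
        centers = np.array([s.center for s in spots])
        d = min_distance_to_polylines(
            centers, [seg.polyline for seg in unit.segments]
        )
        spots = [s for s, di in zip(spots, d) if di >= 10.0]
    sleeved = set(flag_dyshoric(volume, unit, retained_spots=spots))
    for seg in unit.segments:
        classify_segment_abeta(
            volume, seg, wall_band, intensity_threshold, run_min_um,
            ignore_spots=spots, far_control=seg.label not in sleeved,
        )
        classify_segment_sma(volume, seg, intensity_threshold, gap_max_um)


def unit_label_status(unit: VascularUnit) -> dict[SegmentLabel, bool]:
    """Label-level Aβ status: a label is positive iff any of its segment
    records is positive (requires statuses to be filled)."""
    out: dict[SegmentLabel, bool] = {}
    for seg in unit.segments:
        if seg.status is None:
            raise ValueError("segment statuses not set; classify or apply truth first")
        out[seg.label] = out.get(seg.label, False) or seg.status.abeta_positive
    return out


def unit_abeta_status(unit_or_segments: VascularUnit | Sequence[VesselSegment]) -> bool:
    """A unit is Aβ-positive iff any segment — the LMA included — is positive."""
    segs = (
        unit_or_segments.segments
        if isinstance(unit_or_segments, VascularUnit)
        else list(unit_or_segments)
    )
    if not segs:
        return False
    for seg in segs:
        if seg.status is None:
            raise ValueError("segment statuses not set; classify or apply truth first")
    return any(seg.status.abeta_positive for seg in segs)


def load_class(fraction: float) -> str:
    """low < 0.40 <= moderate <= 0.60 < high (closed moderate interval)."""
    if fraction < 0.40:
        return "low"
    if fraction <= 0.60:
        return "moderate"
    return "high"


def vascular_load(
    units: Sequence[VascularUnit], denominator: str = "possessing"
) -> LoadSummary:
    """Sample-level vascular Aβ load and per-segment load rates.

    ``per_segment_rates[L]`` is the fraction of Aβ-positive units carrying
    an Aβ-positive segment labeled L; the denominator is the positive units
    *possessing* label L (default) or all positive units
    (``denominator='all'``).
    """
    if not units:
        raise ValueError("vascular_load needs at least one unit")
    if denominator not in ("possessing", "all"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    statuses = [unit_label_status(u) for u in units]
    pos_mask = [any(st.values()) for st in statuses]
    n_total = len(units)
    n_pos = int(sum(pos_mask))
    fraction = n_pos / n_total
    rates: dict[str, float] = {}
    all_labels = sorted({lab for st in statuses for lab in st})
    for lab in all_labels:
        num = sum(
            1 for st, p in zip(statuses, pos_mask) if p and st.get(lab, False)
        )
        if denominator == "possessing":
            den = sum(1 for st, p in zip(statuses, pos_mask) if p and lab in st)
        else:
            den = n_pos
        if den > 0:
            rates[str(lab)] = num / den
    return LoadSummary(
        n_units_total=n_total,
        n_units_abeta_pos=n_pos,
        load_fraction=fraction,
        load_class=load_class(fraction),
        per_segment_rates=rates,
    )


def most_superficial_sma_loss(unit: VascularUnit) -> SegmentLabel | None:
    """Most superficial label with SMA loss, or None if SMA is intact."""
    lost = [
        seg.label
        for seg in unit.segments
        if seg.status is not None and not seg.status.sma_present
    ]
    return min(lost) if lost else None


def detect_skip_pattern(unit: VascularUnit) -> bool:
    """True iff some Aβ-positive cortical label lies deeper than an
    Aβ-negative label on its path to the entry point (LMA excluded).

    Statuses are label-level, and on any root-to-leaf path every more
    superficial cortical label occurs exactly once, so the path test
    reduces to comparing label orders.
    """
    st = unit_label_status(unit)
    pos_orders = [lab.order for lab, p in st.items() if p and lab.order >= 0.0]
    if not pos_orders:
        return False
    deepest_pos = max(pos_orders)
    return any(
        not p and 0.0 <= lab.order < deepest_pos for lab, p in st.items()
    )
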