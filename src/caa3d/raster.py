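"""Rasterize a ground-truth sample into a two-channel volume.

Emulates the appearance of a cleared-tissue light-sheet acquisition well
enough to exercise the image-based operations: solid SMA tubes (the wall
plus lumen render as one bright cross-section at this resolution), mural
Aβ shells on positive stretches, Gaussian blobs for parenchymal plaques,
elongated annular sleeves for dyshoric change, dual-channel
autofluorescent puncta, then PSF blur and optional shot/read noise.

Axis order is depth-major ``(z, y, x)``; the volume origin sits above the
surface plane (negative z) so the leptomeningeal stubs are inside the
volume and classifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .labels import LMA
from .plaques import resample_polyline

if TYPE_CHECKING:  # pragma: no cover
    from .params import CohortParams
    from .synthetic import GroundTruthSample

VOXEL_CAP = 512**3


@dataclass
class TwoChannelVolume:
    sma: np.ndarray  # (z, y, x)
    abeta: np.ndarray
    voxel_size_um: float
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.sma.shape != self.abeta.shape:
            raise ValueError("channel shapes differ")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel size must be positive")


class VolumeSizeError(ValueError):
    pass


def _voxel_grid(shape_zyx: tuple[int, int, int], origin: np.ndarray, vs: float,
                lo: np.ndarray, hi: np.ndarray):
    """Voxel-center world coordinates for the sub-box [lo, hi] (world μm).

    Returns (index slices, (N,3) world points, box shape).
    """
    lo_idx = np.maximum(np.floor((lo - origin) / vs).astype(int), 0)
    hi_idx = np.minimum(
        np.ceil((hi - origin) / vs).astype(int) + 1, np.array(shape_zyx)[::-1]
    )
    if np.any(hi_idx <= lo_idx):
        return None
    xs, ys, zs = (
        origin[k] + np.arange(lo_idx[k], hi_idx[k]) * vs for k in range(3)
    )
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    sl = (
        slice(lo_idx[2], hi_idx[2]),
        slice(lo_idx[1], hi_idx[1]),
        slice(lo_idx[0], hi_idx[0]),
    )
    return sl, pts, (hi_idx - lo_idx)[::-1]


def _paint_tube(
    channel: np.ndarray,
    origin: np.ndarray,
    vs: float,
    polyline: np.ndarray,
    radii: np.ndarray,
    band: tuple[float, float],
    intensity: float,
    sub_start: float | None = None,
    sub_len: float | None = None,
) -> None:
    """Set voxels whose distance d to the centerline satisfies
    band[0] <= d - r_local <= band[1] (solid tube: band = (-inf, 0)).

    When a sub-interval is painted (mural deposit blocks, dyshoric
    sleeves), the interval ends with a flat annular face rather than a
    spherical cap: voxels are assigned to their nearest centerline sample
    over a margin-extended sample set and painted only when that nearest
    sample lies inside the core interval.  Deposits therefore terminate
    cleanly at segment boundaries instead of spilling radially onto the
    neighbouring stretch.
    """
    pts, _, r = resample_polyline(polyline, radii, vs / 2.0)
    core = np.ones(pts.shape[0], dtype=bool)
    if sub_start is not None:
        h = vs / 2.0
        margin = float(r.max()) + max(band[1], 0.0) + 2 * vs
        n_ext = int(np.ceil(margin / h))
        # extrapolate straight continuations past both polyline ends so a
        # sub-interval reaching an end still gets a flat face there
        head_dir = pts[0] - pts[1]
        tail_dir = pts[-1] - pts[-2]
        head_dir /= max(np.linalg.norm(head_dir), 1e-9)
        tail_dir /= max(np.linalg.norm(tail_dir), 1e-9)
        ks = np.arange(1, n_ext + 1)[:, None] * h
        pts = np.vstack([pts[0] + ks[::-1] * head_dir, pts, pts[-1] + ks * tail_dir])
        r = np.concatenate([np.full(n_ext, r[0]), r, np.full(n_ext, r[-1])])
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(steps)]) - n_ext * h
        ext = (cum >= sub_start - margin) & (
            cum <= sub_start + (sub_len or 0.0) + margin
        )
        if ext.sum() < 2:
            return
        core = (cum >= sub_start) & (cum <= sub_start + (sub_len or 0.0))
        core = core[ext]
        pts, r = pts[ext], r[ext]
        if core.sum() < 2:
            return
    rmax = float(r.max()) + max(band[1], 0.0) + vs
    cpts = pts[core]
    grid = _voxel_grid(
        channel.shape, origin, vs, cpts.min(axis=0) - rmax, cpts.max(axis=0) + rmax
    )
    if grid is None:
        return
    sl, vox, box_shape = grid
    tree = cKDTree(pts)
    dist, idx = tree.query(vox, k=1)
    phi = dist - r[idx]  # signed distance to the wall surface
    mask = (phi >= band[0]) & (phi <= band[1]) & core[idx]
    view = channel[sl]
    np.maximum(view, mask.reshape(box_shape) * intensity, out=view)


def _paint_blob(
    channel: np.ndarray,
    origin: np.ndarray,
    vs: float,
    center: np.ndarray,
    sigma_um: float,
    intensity: float,
) -> None:
    reach = 3.5 * sigma_um
    grid = _voxel_grid(channel.shape, origin, vs, center - reach, center + reach)
    if grid is None:
        return
    sl, vox, box_shape = grid
    d2 = np.sum((vox - center) ** 2, axis=1)
    blob = intensity * np.exp(-d2 / (2 * sigma_um**2))
    view = channel[sl]
    np.maximum(view, blob.reshape(box_shape).astype(view.dtype), out=view)


def rasterize(
    sample: "GroundTruthSample", params: "CohortParams | None" = None
) -> TwoChannelVolume:
    """Render one sample into a two-channel 16-bit volume.

    Deterministic given ``(sample.params, sample.seed)``.  Raises
    :class:`VolumeSizeError` (with a voxel-size hint) when the slab would
    exceed the 512³-voxel cap.
    """
    params = params or sample.params
    im = params.imaging
    vs = params.voxel_size_um
    X, Y, Z = params.slab_dims_um
    headspace = params.lma_len_um + 30.0
    origin = np.array([0.0, 0.0, -headspace])
    shape_zyx = (
        int(np.ceil((Z + headspace) / vs)),
        int(np.ceil(Y / vs)),
        int(np.ceil(X / vs)),
    )
    n_vox = int(np.prod(shape_zyx))
    if n_vox > VOXEL_CAP:
        need = vs * (n_vox / VOXEL_CAP) ** (1 / 3)
        raise VolumeSizeError(
            f"{shape_zyx} = {n_vox} voxels exceeds the {VOXEL_CAP} cap; "
            f"use voxel_size_um >= {need:.2f}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([sample.seed, 0xA5]))
    sma = np.zeros(shape_zyx, dtype=np.float32)
    abeta = np.zeros(shape_zyx, dtype=np.float32)

    for unit in sample.units:
        lost = unit.truth.get("sma_lost", set())
        abeta_truth = unit.truth.get("abeta", {})
        coverage = unit.truth.get("coverage", {})
        for seg in unit.segments:
            if seg.label not in lost:
                _paint_tube(
                    sma, origin, vs, seg.polyline, seg.radii,
                    (-np.inf, 0.0), im.sma_intensity,
                )
            if abeta_truth.get(seg.label, False):
                L = seg.length_um
                fill = float(coverage.get(seg.label, 1.0))
                # deposit block: at least a detectable run, at most the
                # segment; bifurcation arcs are too short for sporadic
                # gaps and deposit all-or-none
                if seg.label.kind == "BIFURCATION":
                    block = L
                else:
                    block = min(L, max(fill * L, min(L, 12.0)))
                start = rng.uniform(0.0, L - block) if L > block else 0.0
                _paint_tube(
                    abeta, origin, vs, seg.polyline, seg.radii,
                    (-1.0, 4.0), im.abeta_wall_intensity,
                    sub_start=start, sub_len=block,
                )
    for spot in sample.spots:
        _paint_blob(
            abeta, origin, vs, np.asarray(spot.center), spot.radius_um / 2.0,
            im.spot_intensity,
        )
    by_id = {u.unit_id: u for u in sample.units}
    for sleeve in sample.dyshoric:
        unit = by_id[sleeve.unit_id]
        seg = unit.segments[sleeve.segment_index]
        _paint_tube(
            abeta, origin, vs, seg.polyline, seg.radii,
            sleeve.annulus_um, im.dyshoric_intensity,
            sub_start=sleeve.start_um, sub_len=sleeve.length_um,
        )
    # dual-channel autofluorescent puncta (comparable intensity in both)
    if params.artifact_puncta_density > 0:
        vol_world = X * Y * Z
        n_puncta = rng.poisson(params.artifact_puncta_density * vol_world)
        for _ in range(n_puncta):
            c = np.array(
                [rng.uniform(0, X), rng.uniform(0, Y), rng.uniform(0, Z)]
            )
            ratio = rng.uniform(0.9, 1.1)
            _paint_blob(abeta, origin, vs, c, 8.0, im.puncta_intensity)
            _paint_blob(sma, origin, vs, c, 8.0, im.puncta_intensity * ratio)

    out = []
    for ch in (sma, abeta):
        img = ch.astype(np.float64)
        if im.psf_sigma_um > 0:
            img = ndimage.gaussian_filter(img, im.psf_sigma_um / vs)
        img += im.background
        if im.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if im.read_noise_sd > 0:
            img += rng.normal(0.0, im.read_noise_sd, img.shape)
        out.append(np.clip(img, 0, 65535).astype(np.uint16))
    return TwoChannelVolume(
        sma=out[0], abeta=out[1], voxel_size_um=vs,
        origin_um=tuple(origin.tolist()),
    )


def write_volume(volume: TwoChannelVolume, out_dir, stem: str = "sample") -> None:
    """Write one multi-page TIFF per channel plus a voxel-size sidecar JSON."""
    import json
    from pathlib import Path

    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = 1e4 / volume.voxel_size_um  # pixels per cm, TIFF RESUNIT centimeter
    for name, arr in (("sma", volume.sma), ("abeta", volume.abeta)):
        tifffile.imwrite(
            out / f"{stem}_{name}.tif",
            arr,
            resolution=(res, res),
            resolutionunit="CENTIMETER",
        )
    (out / f"{stem}_volume.json").write_text(
        json.dumps(
            {
                "voxel_size_um": volume.voxel_size_um,
                "origin_um": list(volume.origin_um),
                "shape_zyx": list(volume.sma.shape),
                "axis_order": "zyx",
            },
            indent=2,
        )
    )


def read_volume(out_dir, stem: str = "sample") -> TwoChannelVolume:
    import json
    from pathlib import Path

    import tifffile

    out = Path(out_dir)
    meta = json.loads((out / f"{stem}_volume.json").read_text())
    return TwoChannelVolume(
        sma=tifffile.imread(out / f"{stem}_sma.tif"),
        abeta=tifffile.imread(out / f"{stem}_abeta.tif"),
        voxel_size_um=meta["voxel_size_um"],
        origin_um=tuple(meta["origin_um"]),
    )
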