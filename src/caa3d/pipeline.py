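"""Run orchestration: simulate → label → classify → plaques → stats.

A run is a pure function of ``(config, seed)``.  Each synthetic sample
(one brain region of one donor) gets its own sub-seed derived from the
root seed; every stage writes plain-text artifacts (SWC, CSV, JSON, TOML)
under the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import classify as cls
from . import plaques as plq
from . import stats as st
from .labels import LMA, SegmentLabel
from .params import CohortParams, ImagingParams, dumps_toml
from .synthetic import GroundTruthSample, generate_cohort
from .topology import d0_external_diameter, write_swc


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 0
    cohort: CohortParams = field(default_factory=CohortParams)
    #: one entry per sample: {"id", "region", "caa_type", optional overrides}
    samples: list[dict[str, Any]] = field(
        default_factory=lambda: [{"id": "S1", "region": "frontal", "caa_type": 1}]
    )
    band_um: tuple[float, float] = (10.0, 100.0)
    raster: bool = False  # rasterize + image-based classification
    verbosity: int = 1

    @classmethod
    def from_toml(cls_, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        run = data.get("run", {})
        cohort = CohortParams.from_dict(data.get("cohort", {}))
        samples = data.get("samples", None)
        kwargs: dict[str, Any] = {"cohort": cohort}
        for key in ("out_dir", "seed", "raster", "verbosity"):
            if key in run:
                kwargs[key] = run[key]
        if "band_um" in run:
            kwargs["band_um"] = tuple(run["band_um"])
        if samples is not None:
            kwargs["samples"] = list(samples)
        unknown = set(run) - {"out_dir", "seed", "raster", "verbosity", "band_um"}
        if unknown:
            raise ValueError(f"unknown [run] config fields: {sorted(unknown)}")
        return cls_(**kwargs)

    def to_toml(self, path: str | Path) -> None:
        doc = {
            "run": {
                "out_dir": str(self.out_dir),
                "seed": self.seed,
                "raster": self.raster,
                "verbosity": self.verbosity,
                "band_um": list(self.band_um),
            },
            "cohort": self.cohort.to_dict(),
        }
        text = dumps_toml(doc)
        text += "\n" + "\n".join(
            "[[samples]]\n"
            + "\n".join(f"{k} = {json.dumps(v)}" for k, v in s.items())
            for s in self.samples
        ) + "\n"
        Path(path).write_text(text)


@dataclass
class SampleSummary:
    sample_id: str
    region: str
    caa_type: int
    load_summary: cls.LoadSummary
    unit_table: pd.DataFrame
    sma_onset_counts: dict[str, int]
    dyshoric_fraction: float | None
    seed: int


def _sample_params(base: CohortParams, meta: dict[str, Any]) -> CohortParams:
    overrides = {
        k: v for k, v in meta.items() if k not in ("id", "region", "caa_type")
    }
    if not overrides:
        return base
    d = base.to_dict()
    d.update(overrides)
    return CohortParams.from_dict(d)


def summarize_sample(
    sample: GroundTruthSample,
    meta: dict[str, Any],
    band_um: tuple[float, float] = (10.0, 100.0),
    volume: Any = None,
) -> SampleSummary:
    """Classify one generated sample and roll it up.

    With ``volume=None`` statuses come from the generator ground truth and
    densities use the truth spot table; otherwise spots are detected and
    artifact-filtered from the raster and every segment re-scored from the
    image.
    """
    params = sample.params
    # units whose parenchymal penetration cannot be confirmed are excluded
    # from analysis, mirroring the study's inclusion rule
    sample = dataclasses.replace(
        sample,
        units=[
            u
            for u in sample.units
            if u.excluded_reason is None and plq.parenchymal_length(u) > 0
        ],
    )
    if volume is None:
        for unit in sample.units:
            cls.apply_truth_statuses(unit)
        spots = sample.spots
    else:
        spots = plq.exclude_artifacts(plq.detect_spots(volume), volume)
        retained = [s for s in spots if not s.is_artifact]
        for unit in sample.units:
            cls.classify_unit(unit, volume, spots=retained)
    load = cls.vascular_load(sample.units)
    cortical = plq.exclude_wm_units(sample.units, params.cortex_thickness_um)
    records = {
        r.unit_id: r
        for r in plq.density_records(cortical, spots, band_um)
    }
    dys_units = {s.unit_id for s in sample.dyshoric}
    onset_counts: dict[str, int] = {}
    rows = []
    for unit in sample.units:
        onset = cls.most_superficial_sma_loss(unit)
        if onset is not None:
            key = _onset_category(onset)
            onset_counts[key] = onset_counts.get(key, 0) + 1
        rec = records.get(unit.unit_id)
        rows.append(
            {
                "sample_id": meta["id"],
                "region": meta.get("region", "na"),
                "caa_type": meta.get("caa_type", 0),
                "unit_id": unit.unit_id,
                "abeta_positive": cls.unit_abeta_status(unit),
                "penetrates_wm": unit.penetrates_wm,
                "d0_diameter_um": d0_external_diameter(unit) or np.nan,
                "density_per_um": rec.density_per_um if rec else np.nan,
                "n_spots_in_band": rec.n_spots_in_band if rec else 0,
                "filament_length_um": plq.parenchymal_length(unit),
                "dyshoric": unit.unit_id in dys_units,
            }
        )
    table = pd.DataFrame(rows)
    table["load_class"] = load.load_class
    cortical_pos = table[table.abeta_positive & ~table.penetrates_wm]
    dys_frac = (
        float(cortical_pos.dyshoric.mean()) if len(cortical_pos) else None
    )
    return SampleSummary(
        sample_id=meta["id"],
        region=meta.get("region", "na"),
        caa_type=int(meta.get("caa_type", 0)),
        load_summary=load,
        unit_table=table,
        sma_onset_counts=onset_counts,
        dyshoric_fraction=dys_frac,
        seed=sample.seed,
    )


def _onset_category(label: SegmentLabel) -> str:
    if label == LMA:
        return "LMA"
    if label.order == 0.0:
        return "D0"
    if label.order <= 1.0:
        return "D1"
    return "deeper"


def write_sample_artifacts(
    sample: GroundTruthSample, summary: SampleSummary, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_swc(sample.units, out / "units.swc")
    sample.params.to_toml(out / "params.toml")
    summary.unit_table.to_csv(out / "units.csv", index=False)
    seg_rows = [
        {
            "unit_id": u.unit_id,
            "label": str(s.label),
            "length_um": s.length_um,
            "mean_radius_um": float(np.mean(s.radii)),
            "in_white_matter": s.in_white_matter,
            "abeta_positive": s.status.abeta_positive if s.status else None,
            "sma_present": s.status.sma_present if s.status else None,
        }
        for u in sample.units
        for s in u.segments
    ]
    pd.DataFrame(seg_rows).to_csv(out / "segments.csv", index=False)
    pd.DataFrame(
        [
            {
                "x_um": s.center[0],
                "y_um": s.center[1],
                "z_um": s.center[2],
                "radius_um": s.radius_um,
                "quality": s.quality,
                "sma_intensity": s.sma_intensity,
                "is_artifact": s.is_artifact,
            }
            for s in sample.spots
        ]
    ).to_csv(out / "spots.csv", index=False)
    pd.DataFrame(
        [{"unit_id": d.unit_id, "label": str(d.label)} for d in sample.dyshoric]
    ).to_csv(out / "dyshoric.csv", index=False)
    (out / "load_summary.json").write_text(
        json.dumps(
            {"seed": summary.seed, **summary.load_summary.to_dict()}, indent=2
        )
    )


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every stage for every sample and write the grouped report.

    Returns the report dict; artifacts land under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_toml(out / "config.toml")
    summaries: list[SampleSummary] = []
    for i, meta in enumerate(config.samples):
        params = _sample_params(config.cohort, meta)
        seed = int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31))
        sample = generate_cohort(params, seed=seed)
        volume = None
        if config.raster:
            from .raster import rasterize, write_volume

            volume = rasterize(sample)
            write_volume(volume, out / str(meta["id"]))
        summary = summarize_sample(sample, meta, config.band_um, volume=volume)
        write_sample_artifacts(sample, summary, out / str(meta["id"]))
        summaries.append(summary)
        if config.verbosity:
            print(
                f"[{meta['id']}] {summary.load_summary.n_units_abeta_pos}/"
                f"{summary.load_summary.n_units_total} Aβ+ "
                f"({summary.load_summary.load_class})"
            )
    report = st.build_report(summaries)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    pd.concat([s.unit_table for s in summaries], ignore_index=True).to_csv(
        out / "units_all.csv", index=False
    )
    return report


# ----------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------

def tiny_params(**overrides: Any) -> CohortParams:
    """5 units, no raster: sub-second geometry/labeling fixtures."""
    base = dict(
        slab_dims_um=(800.0, 800.0, 700.0),
        cortex_thickness_um=500.0,
        n_units=5,
        artifact_puncta_density=0.0,
        imaging=ImagingParams(read_noise_sd=0.0, shot_noise=False),
    )
    base.update(overrides)
    return CohortParams(**base)


def small_params(**overrides: Any) -> CohortParams:
    """16 units in a ~256³-voxel slab with a noise-free raster.

    16 entry points on a 0.26 mm² surface patch (~60 arterioles/mm²) is at
    the dense end of what cortex shows; more would make trees overlap in
    ways real vasculature does not.
    """
    base = dict(
        slab_dims_um=(512.0, 512.0, 420.0),
        cortex_thickness_um=320.0,
        n_units=16,
        seg_len_mean_um=110.0,
        seg_len_sd_um=30.0,
        lma_len_um=80.0,
        plaque_radius_mean_um=22.0,
        plaque_radius_sd_um=2.0,
        imaging=ImagingParams(read_noise_sd=0.0, shot_noise=False),
    )
    base.update(overrides)
    return CohortParams(**base)


def density_cohort_params(**overrides: Any) -> CohortParams:
    """Study conditions for the perivascular-density experiments.

    A sparse slab at the traced-unit spacing the study's numbers imply
    (~1600 units over twelve 0.5 cm³ blocks is roughly two units per mm²
    of cortical surface), cortical units only, and no collision steering:
    the density analysis runs on skeleton truth, and steering couples tree
    shape to vessel diameter — hence to Aβ status — which would confound a
    point-process comparison.
    """
    base = dict(
        slab_dims_um=(10000.0, 10000.0, 1200.0),
        cortex_thickness_um=900.0,
        n_units=300,
        p_penetrate_wm=0.0,
        min_entry_sep_um=600.0,
        seg_len_mean_um=120.0,
        avoid_collisions=False,
    )
    base.update(overrides)
    return CohortParams(**base)


def make_fixtures(size: str, out_dir: str | Path, seed: int = 0) -> Path:
    """Write versioned SWC/TIFF/CSV fixtures used by the test suite."""
    if size == "tiny":
        params, raster = tiny_params(seed=seed), False
    elif size == "small":
        params, raster = small_params(seed=seed), True
    else:
        raise ValueError("size must be 'tiny' or 'small'")
    config = RunConfig(
        out_dir=str(Path(out_dir) / size),
        seed=seed,
        cohort=params,
        samples=[{"id": f"{size}-fixture", "region": "frontal", "caa_type": 1}],
        raster=raster,
        verbosity=0,
    )
    run_all(config)
    return Path(config.out_dir)
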