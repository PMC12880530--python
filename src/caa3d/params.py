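"""Cohort-generation and imaging parameters.

``CohortParams`` is the full generative model specification for one
synthetic sample: slab geometry, tree growth, the Aβ deposition front,
SMA-loss coupling, plaque point process, dyshoric sleeves, and imaging.
Defaults are calibrated to the printed study quantities where those exist
(deposition-front profile, diameter medians, dyshoric rates, the ≥8 μm
vessel-inclusion floor); tree-growth statistics are invented and documented
as such in the config docs.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

#: Per-segment vascular Aβ load profile of the study cohort, as a survival
#: function over depths D0..D6 (probability the deposition front reaches at
#: least that depth, among Aβ-positive units).  Note the D5 entry exceeds D4
#: — a denominator artifact of how few units possess a D5 segment — so this
#: exact profile needs ``allow_nonmonotone=True``.
PRINTED_FRONT_PROFILE = (0.995, 0.458, 0.198, 0.100, 0.045, 0.063, 0.0)

#: Monotone default profile (D5 clamped to the D4 value).
DEFAULT_FRONT_PROFILE = (0.995, 0.458, 0.198, 0.100, 0.045, 0.045, 0.0)

ONSET_CATEGORIES = ("LMA", "D0", "D1", "deeper")


@dataclass
class ImagingParams:
    """Rasterization / noise model for the two-channel volume."""

    psf_sigma_um: float = 1.0
    background: float = 10.0
    sma_intensity: float = 200.0
    abeta_wall_intensity: float = 200.0
    spot_intensity: float = 180.0
    dyshoric_intensity: float = 160.0
    puncta_intensity: float = 220.0
    read_noise_sd: float = 0.0  # Gaussian read noise (counts); 0 = noise-free
    shot_noise: bool = False  # Poisson shot noise on top of the mean image


@dataclass
class CohortParams:
    # --- slab geometry (world μm; surface plane at z=0, depth = +z)
    slab_dims_um: tuple[float, float, float] = (1500.0, 1500.0, 1200.0)
    voxel_size_um: float = 2.0
    cortex_thickness_um: float = 900.0

    # --- cohort composition
    n_units: int = 100
    p_unit_abeta: float = 0.674  # cohort fraction of Aβ-positive units
    p_lma_abeta: float = 0.962
    front_reach_probs: tuple[float, ...] = DEFAULT_FRONT_PROFILE
    front_reach_probs_bif: tuple[float, ...] | None = None  # D0-D1..D5-D6
    p_skip: float = 0.01  # 11 of 1104 positive units
    p_wm_confined: float = 0.062
    sporadic_fill: float = 0.6
    independent_bernoulli_front: bool = False  # null-model mode
    allow_nonmonotone: bool = False

    # --- SMA loss
    p_sma_loss: float = 0.495  # 547 of 1104 positive units
    sma_onset_dist: dict[str, float] = field(
        default_factory=lambda: {"LMA": 0.62, "D0": 0.33, "D1": 0.03, "deeper": 0.02}
    )

    # --- morphometry
    diameter_root_median_pos_um: float = 36.73
    diameter_root_median_neg_um: float = 25.94
    diameter_sigma_log_pos: float = 0.15
    diameter_sigma_log_neg: float = 0.18
    diameter_floor_um: float = 8.0  # vessel-inclusion rule: diameter >= 8 μm
    taper: float = 0.8  # child/parent diameter ratio per generation

    # --- tree growth (invented defaults; no branching statistics published)
    branch_prob: float = 0.6
    seg_len_mean_um: float = 150.0
    seg_len_sd_um: float = 50.0
    max_depth: int = 6
    step_um: float = 12.0  # centerline sampling step
    lma_len_um: float = 150.0  # leptomeningeal stub above the surface
    p_penetrate_wm: float = 0.3
    bif_radius_factor: float = 2.0  # bifurcation-segment arc, x local radius
    min_entry_sep_um: float = 100.0  # penetrating-arteriole spacing
    #: steer growing branches around occupied tissue so rendered vessels
    #: never interpenetrate.  Collision steering couples tree shape to
    #: vessel diameter — and hence to Aβ status — so skeleton-only
    #: point-process experiments switch it off.
    avoid_collisions: bool = True

    # --- parenchymal plaques
    plaque_lambda0: float = 6.4e-7  # candidates per μm³ of cortex
    plaque_thinning_theta: float = 0.85  # retention within 100 μm of Aβ+ units
    plaque_radius_mean_um: float = 25.0  # 50 μm spot diameter
    plaque_radius_sd_um: float = 4.0

    # --- dyshoric change
    p_dyshoric_unit: float = 0.127
    dyshoric_d0_share: float = 0.915
    dyshoric_len_um: float = 120.0  # sleeve longitudinal extent
    dyshoric_annulus_um: tuple[float, float] = (5.0, 20.0)  # outside the wall

    # --- artifacts / imaging
    artifact_puncta_density: float = 2.0e-7  # dual-channel puncta per μm³
    imaging: ImagingParams = field(default_factory=ImagingParams)

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        probs = {
            "p_unit_abeta": self.p_unit_abeta,
            "p_lma_abeta": self.p_lma_abeta,
            "p_skip": self.p_skip,
            "p_wm_confined": self.p_wm_confined,
            "sporadic_fill": self.sporadic_fill,
            "p_sma_loss": self.p_sma_loss,
            "p_penetrate_wm": self.p_penetrate_wm,
            "plaque_thinning_theta": self.plaque_thinning_theta,
            "p_dyshoric_unit": self.p_dyshoric_unit,
            "dyshoric_d0_share": self.dyshoric_d0_share,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        fr = tuple(self.front_reach_probs)
        if len(fr) != 7:
            raise ValueError("front_reach_probs must have 7 entries (D0..D6)")
        if any(not 0.0 <= p <= 1.0 for p in fr):
            raise ValueError("front_reach_probs outside [0, 1]")
        if not self.allow_nonmonotone and any(
            fr[i + 1] > fr[i] + 1e-12 for i in range(6)
        ):
            raise ValueError(
                "front_reach_probs must be non-increasing over D0..D6 (a survival "
                "function); pass allow_nonmonotone=True to override"
            )
        if self.front_reach_probs_bif is not None and len(self.front_reach_probs_bif) != 6:
            raise ValueError("front_reach_probs_bif must have 6 entries (D0-D1..D5-D6)")
        if abs(sum(self.sma_onset_dist.values()) - 1.0) > 1e-6:
            raise ValueError("sma_onset_dist must sum to 1")
        if set(self.sma_onset_dist) - set(ONSET_CATEGORIES):
            raise ValueError(f"sma_onset_dist keys must be {ONSET_CATEGORIES}")
        if self.diameter_floor_um < 8.0:
            raise ValueError("diameter_floor_um must be >= 8 (vessel-inclusion rule)")
        if any(d <= 0 for d in self.slab_dims_um) or self.voxel_size_um <= 0:
            raise ValueError("slab dimensions and voxel size must be positive")
        if not 0 < self.cortex_thickness_um < self.slab_dims_um[2]:
            raise ValueError("cortex_thickness_um must lie inside the slab z-extent")
        if self.plaque_lambda0 < 0:
            raise ValueError("plaque_lambda0 must be non-negative")
        if not 0 < self.taper <= 1:
            raise ValueError("taper must be in (0, 1]")

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["slab_dims_um"] = list(self.slab_dims_um)
        d["front_reach_probs"] = list(self.front_reach_probs)
        if self.front_reach_probs_bif is not None:
            d["front_reach_probs_bif"] = list(self.front_reach_probs_bif)
        d["dyshoric_annulus_um"] = list(self.dyshoric_annulus_um)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CohortParams":
        d = dict(d)
        if "imaging" in d and isinstance(d["imaging"], dict):
            d["imaging"] = ImagingParams(**d["imaging"])
        for key in ("slab_dims_um", "front_reach_probs", "front_reach_probs_bif",
                    "dyshoric_annulus_um"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown CohortParams fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_toml(cls, path: str | Path) -> "CohortParams":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_dict(data.get("cohort", data))

    def to_toml(self, path: str | Path) -> None:
        Path(path).write_text(dumps_toml({"cohort": self.to_dict()}))


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dumps_toml(data: dict[str, Any]) -> str:
    """Minimal TOML writer for nested dicts of scalars/lists (config echo)."""
    lines: list[str] = []

    def walk(table: dict[str, Any], prefix: str) -> None:
        scalars = {k: v for k, v in table.items() if not isinstance(v, dict)}
        subtables = {k: v for k, v in table.items() if isinstance(v, dict)}
        if prefix:
            lines.append(f"[{prefix}]")
        for k, v in scalars.items():
            if v is None:
                continue
            lines.append(f"{k} = {_toml_value(v)}")
        if scalars or prefix:
            lines.append("")
        for k, v in subtables.items():
            walk(v, f"{prefix}.{k}" if prefix else k)

    walk(data, "")
    return "\n".join(lines)
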