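# caa3d — 3D surface-to-depth quantification of cerebral amyloid angiopathy

Cerebral amyloid angiopathy (CAA) is the deposition of amyloid-β (Aβ) in
the walls of leptomeningeal and cortical arteries. Conventional thin-slice
histopathology sees only fragments of the vascular tree, so the question
of *where along a vessel* Aβ accumulates — and whether it spreads
contiguously from the brain surface into the depth — needs 3D analysis of
whole vascular trees imaged by cleared-tissue light-sheet microscopy with
smooth-muscle-actin (SMA) and Aβ labeling.

`caa3d` implements that analysis as a tested Python package for
researchers working with such volumes (or wanting to prototype against
realistic synthetic ones):

- **Vascular units and depth labels.** A *vascular unit* is one
  anatomically continuous arterial tree branching from a common
  leptomeningeal artery (LMA). Below its parenchymal entry point,
  segments are labeled by branch order — D0 from entry to the first
  branch, the bifurcation arc D0-D1, then D1, … up to D6 (deeper pooled).
- **Segment-wise Aβ/SMA classification** from two-channel volumes or from
  ground-truth tables, unit-level status roll-up, and the *vascular Aβ
  load* of a sample: the percentage of Aβ-positive units, classed low
  (<40 %), moderate (40–60 %), high (>60 %).
- **Morphometry**: the D0 external diameter (twice the median D0 radius,
  measured on the SMA channel via a distance transform).
- **Perivascular plaque density**: parenchymal plaques detected as 50 μm
  spots (Laplacian-of-Gaussian + sphericity screen), dual-channel
  autofluorescent puncta excluded by an intensity-ratio rule, spots kept
  when their center lies 10–100 μm from a unit's filament, and density
  reported as spots per μm of filament length. Linear perivascular
  (*dyshoric*) deposits are flagged separately by a circumferential
  coverage-run test.
- **Statistics**: quartile summaries, Mann–Whitney U (exact for small
  tie-free samples), Kruskal–Wallis, and all-pairs Steel–Dwass multiple
  comparisons via the studentized-range asymptotic null.
- **A synthetic cohort generator** that emulates the statistical structure
  of the imaging data — contiguous deposition fronts, SMA loss nested in
  the Aβ extent, a plaque point process thinned near Aβ-positive vessels,
  dyshoric sleeves, puncta artifacts — and a rasterizer producing
  two-channel 16-bit volumes, so every image-facing operation is testable
  without any acquisition.

## Worked example

Recover the per-segment vascular Aβ load profile by simulation: draw
2,500 Aβ-positive units whose deposition front follows the published
survival profile over D0..D6, label their skeletons by branch order, apply
truth-status classification, and tabulate per-segment load rates among
positive units possessing each label:

```bash
python analysis/02_segment_load_profile.py --seed 1
```

```
label  published_pct  measured_pct  n_positive_units_with_label
  LMA           96.2     96.040000                         2500
   D0           99.5     99.480000                         2500
D0-D1           97.9     99.451014                         2368
   D1           45.8     47.161017                         2360
   D2           19.8     20.155709                         2312
   D3           10.0      9.750462                         2164
   D4            4.5      6.320431                         2041
   D5            6.3      6.459817                         1966
   D6            0.0      0.000000                         1891
D0: measured 99.48% vs 99.5% (3 SD = 0.42) -> OK
D1: measured 47.16% vs 45.8% (3 SD = 3.08) -> OK
```

The profile drops steeply from the surface (D0 ≈ 99.5 %) to D1 (≈ 46 %)
and keeps falling with depth — the surface-to-deep gradient the analysis
is designed to quantify. (D0-D1 tracks D0 because the bifurcation arc is
tied to the shallower depth in the front model; D4 is mildly inflated by
the non-monotone published profile, see `docs/methods.md`.)

The other numbered scripts under `analysis/` run the remaining analyses:
`01_simulate_cohort.py` (a twelve-sample cohort with the full pipeline and
grouped report), `03_d0_diameters.py` (Aβ-positive units are wider:
medians ≈ 36.5 vs 25.6 μm, Mann–Whitney p ≈ 1e-82 at n = 800),
`04_perivascular_density.py` (density around Aβ-positive units is lower
under thinning θ = 0.85, p ≈ 3e-4; no difference at θ = 1), and
`05_dyshoric.py` (≈ 12–13 % of cortical Aβ-positive units affected, ≈ 92 %
of sleeves on D0). Each writes its tables under `results/`.

A `caa3d` command-line interface wraps the same library for file-based
workflows: `caa3d simulate`, `caa3d label --swc units.swc`,
`caa3d run-all --config run.toml`, `caa3d make-fixtures`.

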