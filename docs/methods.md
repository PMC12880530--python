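# Methods

This note records the models, conventions, and numerical choices behind
`caa3d`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate frame and data model

World coordinates are in μm. The cortical surface is the plane `z = 0`
and depth increases with `+z`; the cortex/white-matter boundary is a
second plane `z = cortex_thickness_um`. Skeletons are exchanged as
7-column SWC (`id type x y z radius parent`, radius in μm, type code 7 on
write); the dialect requires parents to be declared before children and
rejects non-positive radii, duplicate ids, and self-parenting, naming the
offending line. Volumes are depth-major `(z, y, x)` arrays with a voxel
size and a world-space origin. The origin is *not* pinned to `(0,0,0)`:
the rasterizer places it above the surface plane so the leptomeningeal
(LMA) stubs are inside the volume and classifiable — without this the
LMA, which carries the highest deposition rates, would be invisible to
the image path.

## Depth labeling

A vascular unit is one tree rooted at an LMA. The entry point is the
linear interpolation of the first root-to-descendant edge crossing the
surface plane; units that never cross are excluded (`no-entry`), matching
the study-design rule that units without a confirmable penetration point
cannot be analyzed. Above the entry everything is `LMA`. Below it a
branch-order counter starts at D0 and increments at every branch node
(trifurcations count once). The *bifurcation segment* between depths d
and d+1 is the arc within `bif_radius_factor × local radius` (default 2)
of the branch node — one record for the parent tail and one per child
head — so its extent scales with vessel caliber and the records partition
the centerline length exactly. Depth slivers shorter than 6 μm between
two bifurcation cuts are absorbed into the adjacent bifurcation arc; they
are slicing artifacts, and a μm-scale "segment" would otherwise make the
run-length classification rule degenerate. Orders beyond D6 pool into
`DEEPER`.

## Synthetic cohort generator

The generator defines the study conditions for every simulation-based
check. Where the literature gives a number it is used as the default;
everything else is an invented, documented choice.

**Geometry.** Entry points are drawn uniformly with a minimum spacing
(`min_entry_sep_um`, default 100 μm — penetrating arterioles keep a
characteristic spacing); each unit gets an LMA stub of ~150 μm whose
heading is chosen to avoid already-placed stubs. Growth is a
downward-biased random walk in chains of mean length 150 μm (SD 50),
with the D0 stretch forced to at least ~100 μm (penetrating arterioles
run unbranched through the upper layers). Branching probability is 0.95
at D0, 0.85 at D1, and `branch_prob` (default 0.6) deeper, to a maximum
order of 6. These growth statistics are invented: no branching statistics
are published for the traced trees; the defaults were chosen once to
bring the unit length distribution near the published median ≈ 1.55 mm
with IQR ≈ 1.0–2.3 mm. Root diameters are lognormal with
status-conditional medians 36.73 μm (Aβ-positive) and 25.94 μm
(negative), log-SDs 0.15/0.18 back-computed from the published IQRs;
child diameters taper by 0.8 per generation with an 8 μm floor (the
vessel-inclusion rule). A fraction `p_penetrate_wm` (default 0.3) of
units crosses into white matter; non-penetrating units are truncated
above the boundary and penetrating ones are guaranteed to cross.

**Collision steering.** By default a growing chain checks a coarse
spatial hash of already-occupied tissue and deflects (or, boxed in,
terminates) rather than interpenetrating another vessel — required for
rasters to be physically sensible. Steering couples tree shape to vessel
radius, and hence to Aβ status; skeleton-only point-process experiments
therefore switch it off (`avoid_collisions=False`), because that coupling
acts as a diameter→geometry confound on the density comparison.

**Deposition front.** Per positive unit a single uniform draw U sets the
front depth `F = max{d : U < front_reach_probs[d]}`, so the positive
depth labels are a contiguous prefix by construction — the observed
anatomic contiguity of vascular Aβ — and the per-segment positivity
rates converge to the survival profile. The default profile is the
published per-segment load profile with the D5 entry clamped to D4
(the published value is non-monotone there, a denominator artifact of how
few units possess a D5 segment; the exact profile can be used with
`allow_nonmonotone=True`, at the cost of a mildly inflated D4 marginal).
LMA positivity is an independent Bernoulli (0.962): the published LMA
rate is *lower* than D0's, so the LMA is not simply "front ≥ −1".
Bifurcation arcs tie to the shallower depth (positive iff `F ≥ d`),
consistent with the published D0-D1 rate tracking D0; an explicit
per-bifurcation survival override exists. Rare patterns are mutually
exclusive alternatives: a *skip* unit (default 0.01 ≈ 11/1104) keeps LMA
or D0 positive, one deep segment positive, and intermediate cortical
segments negative; a *white-matter-confined* unit (0.062) restricts
deposition to WM segments plus LMA/D0. Within-segment coverage is
`sporadic_fill` (default 0.6; "sometimes sporadic" is published without a
fraction).

**SMA loss** only occurs on Aβ-positive units (probability 0.495 ≈
547/1104). The onset label is drawn from a categorical over
{LMA, D0, D1, deeper} (default 0.62/0.33/0.03/0.02, calibrated to the
published most-superficial-loss medians 40 %/21 %/0 %), restricted to the
unit's positive labels; loss then runs contiguously from the onset
through every deeper positive label, so the lost set is always nested in
the Aβ extent.

**Plaques** are a homogeneous Poisson process in the cortical sub-volume
with intensity `plaque_lambda0 = 6.4e-7 /μm³` (back-computed from the
published density ≈ 0.02 spots/μm and the 10–100 μm band annulus);
candidates within 100 μm of any Aβ-positive unit's centerline survive
with probability `plaque_thinning_theta` (default 0.85), others always.
Spot radii are normal (25 ± 4 μm, clipped). **Dyshoric sleeves** affect
each cortical Aβ-positive unit with probability 0.127; the affected
segment is D0 with probability 0.915, else uniform among the unit's other
positive cortical labels; a sleeve is an annulus 5–20 μm outside the wall
over ~120 μm of the segment.

## Rasterization

SMA tubes render *solid* (at 2 μm voxels the wall and lumen are not
resolved separately); mural Aβ renders as a thin shell (−1 to +4 μm about
the wall radius) over one contiguous block per positive segment covering
the `sporadic_fill` fraction (whole bifurcation arcs — they are too short
for sporadic gaps). Painted sub-intervals end in *flat* annular faces
rather than spherical caps, so a deposit terminating at a segment
boundary does not spill radially onto its neighbor. Plaques are Gaussian
blobs (σ = radius/2), sleeves full annuli, and autofluorescent puncta
σ = 8 μm blobs placed in *both* channels at an intensity ratio ~1.
A Gaussian PSF (default σ = 1 μm), a constant background, optional
Poisson shot noise and Gaussian read noise (both off in the noise-free
test scenes; the noise model itself is an invention — none is published)
produce 16-bit channels. A 512³-voxel cap guards memory; exceeding it
raises an error carrying the minimum workable voxel size.

## Image-based classification

Mural Aβ is scored at stations every 2 μm along a segment: 8 azimuths ×
3 radial offsets spanning the wall band (default 0–6 μm outside the local
radius). A sample is *deposit* only when it is Aβ-specific (above
threshold, and not matched by comparable SMA — the dual-channel rule that
also defines puncta artifacts). Three context checks keep nearby
structures from masquerading as wall deposit, each making an azimuth or
station *unusable* rather than negative: a far control ~5 μm beyond the
band must be dark (mural deposit is a thin shell; blobs, sleeves and
crossing vessels are extended), the station's centerline sample must be
dark (a blob swallowing the vessel lights the lumen; real mural deposit
does not), and samples inside the bright core of a detected spot are
masked (with the 10 μm inner-band rule applied per unit, so a "spot"
sitting on the unit's own wall — mural deposit picked up by the blob
detector — does not mask its own segment). Segments flagged as carrying a
dyshoric sleeve are scored without the far control, which the sleeve
explains. A station is deposit-bearing when at least half its usable
azimuths are (≥ 4 usable required); the segment is positive when deposit
stations form a contiguous run of `run_min_um` (default 10 μm, capped at
the segment length so a fully covered short segment counts), with
unknown stations bridging rather than breaking runs. Raising the
intensity threshold can only shrink the deposit set, so classification is
monotone in the threshold. SMA presence uses the centerline profile: the
wall is traceable iff the longest below-threshold run is ≤ `gap_max_um`
(default 20 μm, boundary inclusive); an untraceable Aβ-positive segment
is the Aβ+/SMA− class.

With these rules the truth-status path and the noise-free raster path
produce identical load summaries on the 16-unit test fixture; across
other seeds residual disagreement is of order one label per several
hundred, always traceable to genuinely ambiguous geometry (e.g. two
stubs forced together on a congested surface patch).

## Spot detection, artifacts, densities

Detection mirrors a sphere-fitting spot tool: Laplacian of Gaussian at
σ = diameter/(2√3) (50 μm spots), non-maximum suppression at half the
diameter, "quality" = detection-scale-smoothed intensity at the maximum
(the published instrument-specific quality range does not transfer; the
default cutoff 30 was calibrated once on the synthetic fixtures and is
config-exposed). A Hessian *sphericity* screen (|λ|min/|λ|max of the
local Hessian, all eigenvalues concave) rejects elongated structures:
judged at a fine scale (σ/3), or accepted at the detection scale when the
envelope is strongly compact. This is what keeps dyshoric sleeves and
mural-deposit caps out of the spot list — the published pipeline used a
trained classifier for the same purpose, deliberately replaced here by
reproducible rules. One consequence: two blobs closer than the
suppression radius are *merged or dropped* (their fused profile can fail
the screen), never double-counted. Artifact exclusion flags a spot when
its same-location SMA intensity is ≥ 0.8 × its quality; flagged spots
stay in the output with `is_artifact=True` but never enter densities.

Perivascular density for a cortical unit counts non-artifact spots whose
center-to-filament distance (exact clamped-projection distance to the
parenchymal centerline; LMA stretches take part in load rates but not in
density or diameter metrics) lies in the inclusive 10–100 μm band,
divided by the unit's parenchymal filament length. Units reaching white
matter, units flagged as perivascular-artifact, and units without a
confirmed entry are excluded first. Large cohorts shortlist candidates
with a KD-tree; the accepted set is always decided by the exact distance.

The D0 external diameter is twice the *median* D0 radius — robust to
focal Aβ bulges — from skeleton radii or from the SMA-channel distance
transform. The image-based radius at a centerline point is the tight
triangle-inequality bound `min over nearby voxel centers v of
(EDT(v) + |v − p|)` minus a quarter voxel (the nearest background voxel
center lies up to half a voxel beyond the true surface); plain
interpolation of the EDT cannot reach the on-axis peak and biases the
radius low by up to a voxel.

## Statistics

Quartiles use linear interpolation between order statistics (the source
software's quantile convention is unpublished). Mann–Whitney U is
two-sided, exact by enumeration when both n ≤ 8 without ties, otherwise
the tie-corrected normal approximation with continuity correction
(delegated to scipy); identical pooled samples return p = 1 with a
warning. Kruskal–Wallis uses the tie-corrected H against χ²(k−1).
Steel–Dwass ranks each unordered pair separately (mid-ranks), forms the
tie-corrected standardized Mann–Whitney z without continuity correction,
and refers |z|·√2 to the studentized-range distribution with k groups and
infinite degrees of freedom — the classical asymptotic; exact
small-sample tables are out of scope and numerical parity with the
original analysis software is not claimed. At k = 2 the procedure reduces
to the two-sided normal-approximation Mann–Whitney test exactly.

## Study conditions for the simulation experiments

- *Label statistics* (segment-load profile, dyshoric share, contiguity):
  spatial constraints off (`avoid_collisions=False, min_entry_sep_um=0`)
  since statuses are drawn independently of geometry; 2,500 positive
  units for the front round-trip, 1,300 for the dyshoric share, 10,000
  for the contiguity sweep.
- *Density experiments*: 300 cortical units in a 10 × 10 × 1.2 mm slab at
  600 μm entry spacing — the spacing implied by the published tracing
  density (~1,600 units over twelve 0.5 cm³ blocks ≈ 2 units per mm² of
  surface) — with collision steering off (see above). Territories of
  distinct units then barely overlap, which is what gives the thinning
  signal its published ~15 % contrast and keeps the θ = 1 null calm.
- *Raster fixture*: 16 units in a 512 × 512 × 420 μm slab at 2 μm voxels
  (≈ 256³), noise-free imaging. Sixteen entries on 0.26 mm² is already
  the dense end of physiological arteriole spacing; more would force
  interpenetrating trees.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure the analysis relies
on: contiguous fronts, nested SMA loss, calibrated diameters, thinned
point processes, sleeve geometry, dual-channel puncta. It does not model
cortical curvature, veins or capillaries, haemodynamics, Aβ kinetics,
real noise spectra, or the spatial inhomogeneity of plaque density across
layers. Passing tests therefore validate the pipeline's operations and
their statistical behavior under known truth — not the biological claims
themselves, which require real volumes. Published specimen-dependent
numbers (per-segment rates on real vessels, density medians, printed
p-values) are targets only where a calibrated round-trip makes them
recoverable; absolute density levels, for instance, come out below the
published 0.02 /μm because overlapping branch bands of one tree share
spots (union, not sum).

## Known limitations

- Classification is label-level and semiquantitative by design; a unit
  with one positive D1 record counts D1-positive regardless of its other
  D1 records.
- Very short SMA-lost segments (shorter than `gap_max_um`) cannot be
  distinguished from present ones by the gap rule.
- The D0 diameter is measured on the SMA channel; mural Aβ thickening
  outside the SMA wall is not included, and solid-tube rendering means
  the estimate tracks the outer wall radius at voxel resolution.
- Spot detection undercounts plaque pairs closer than the suppression
  radius (merged or dropped, see above).
- On-wall "spots" of one unit may fall in the 10–100 μm band of a
  *neighboring* unit and contribute to its density.
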