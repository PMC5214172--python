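# Methods

## Quantities and conventions

The package tracks three dimensionless quantities. The recovery
coefficient `R = A_M / A_K` compares a measured activity concentration
(ROI mean, kBq/mL) or assayed activity (MBq) with the traceable
certificate value decayed to the measurement time. The SUV bias
`b = R_P / R_D − 1` combines the scanner's and the dose calibrator's
recovery coefficients; a scale common to both instruments cancels exactly,
which is the property the metric exists to interrogate. COV is
`100 · SD / mean` in percent.

Two standard-deviation conventions coexist deliberately and are fixed:

* **within one ROI** the population SD (divide by N) describes the
  enclosed voxel set itself; the intra-ROI uniformity metric `u` uses it;
* **across repeated measurements** the sample SD (divide by N − 1)
  estimates variability; `cov`, `summarize` and the time-series report use
  it.

Percent values compared against printed report numbers are rounded half
away from zero at the printed precision (`sources.round_half_away`).

Timestamps are timezone-aware everywhere; naive datetimes are rejected at
construction. Durations are computed in seconds. All internal activity
math is in kBq/mL, MBq and kg; SUV carries g/mL.

## Decay model

Sealed Ge-68/Ga-68 sources are governed by the parent half-life; the
daughter's secular equilibrium is not modelled separately. The decay
factor is `2^(−Δt / T½)`, multiplicative over concatenated intervals and
defined for negative Δt (back-correction). Defaults: Ge-68 T½ = 270.95 d,
F-18 T½ = 109.77 min (standard reference values); both are plain
`DecaySpec` parameters and can be overridden, since every traceable-value
computation depends on them.

The dose-calibrator source is assayed on the instrument's F-18 setting, so
the expected reading is `A_ref · decay · response_factor`, where the
relative response factor converts the stated Ge-68 activity to equivalent
F-18 activity. That factor is protocol-specific and deliberately has **no
default** anywhere a dose-calibrator recovery is computed; example values
in docs and tests are marked illustrative.

## Automated ROI extraction

The published behavior being matched is: fully automatic location of the
phantom's compact hot region, and an ROI of only whole voxels fitting
inside a cubic bounding box small enough to avoid partial-volume effects
at the phantom edges. The internal steps are this package's own documented
choices, with every knob exposed in `RoiConfig`:

1. robust maximum = 99.9th percentile of the volume (a single hot voxel
   cannot define the phantom);
2. threshold at 50% of it; 26-connected components; keep the largest;
   reject it if smaller than 5 mL (→ "phantom not found");
3. center = intensity-weighted centroid of that component in physical
   space.

The cubic box (default side 15 mm) selects, along each axis,
`n = floor(box / pitch)` voxels — the contiguous run whose centers lie
nearest the detected center, ties resolved toward lower indices for
determinism. A cube of side 1.5 cm on the 2.7 × 2.7 × 3.3 mm grid gives
5 × 5 × 4 = 100 voxels; 10 and 20 mm boxes give 27 and 294. The floor rule
equals the brute-force maximum number of whole voxels a box of that length
can cover on the lattice (property-tested against a sliding-placement
enumeration). A tiny epsilon (1e-9) in the floor guards exact integer
ratios against floating-point loss.

The PET/CT alignment check runs the same centroid machinery on the CT,
windowed to the epoxy/acrylic HU range (exclusive-low 0, inclusive-high
300 by default — the lower bound is exclusive so water at exactly 0 HU is
excluded). In-window voxels are weighted by their HU excess above the
window floor, which makes boundary partial-volume voxels pull the centroid
sub-voxel accurately when the surrounding medium sits at the floor. The
offset (PET minus CT center) is flagged beyond a configurable tolerance
(default 3 mm).

## Simulator

The synthetic scene is a 45-mm (diameter and height) active cylinder,
nominally 250 kBq/mL, coaxial with a 20-cm water flood cylinder; the
background medium can be water, air, or radioactive water at 15% of the
insert concentration. Two reconstruction grids are built in:
5.5 × 5.5 × 3.3 mm and 2.7 × 2.7 × 3.3 mm voxels; the default grid is
84 × 84 × 46 voxels of the finer pitch, covering the flood phantom with
margin. The flood cylinder's height (120 mm) and the grid extents are
package choices — large enough that the insert, its PSF tails and all
tested mispositions stay well inside.

Rendering: boundary voxels get analytic partial-volume fractions from
2 × 2 × 2 sub-voxel sampling (cheap, and adequate because analysis ROIs
keep ≥ 3 PSF sigmas from edges); interior voxels hold the concentration
exactly. The companion CT assigns water 0 HU, epoxy/acrylic +150 HU, air
−1000 HU (configurable). Smoothing is separable Gaussian convolution with
FWHM 8 mm transaxial / 4.6 mm axial (σ = FWHM / 2.3548, converted to voxel
units per axis).

Noise is applied to the smoothed image: i.i.d. Gaussian with SD equal to
`magnitude` × the plateau value (99.9th percentile), default magnitude
0.01. This default is calibrated so the intra-ROI uniformity u on the
default grid lands near 1%, the level reported for real reconstructions of
this phantom class; it keeps u comfortably under the 2% acceptance bound.
A `scaled-poisson` model is available for count-limited studies. What the
simulator does **not** emulate: tomographic reconstruction (OSEM),
attenuation- and scatter-correction physics (their net effect is a single
multiplicative `recon_bias` knob), spatially correlated post-reconstruction
noise texture (noise here is i.i.d.), randoms/dead-time, and CT beam
physics. Tests passing on these scenes therefore validate the *analysis
chain* — geometry, decay algebra, ROI rules, metric identities — not
scanner physics.

Mispositioning: translations add to the insert center ("directly upward" =
transaxial-y); rotations move the center about the flood cylinder's axis.
The insert is rotationally symmetric about its own (axial) axis, so
rotating a centered insert is an exact no-op, and center recovery under
rotation is tested with the insert mounted off-axis.

Series output: minimal-but-valid single-frame DICOM (activity stored as
BQML with a 16-bit rescale slope — values round-trip within 0.1% of the
volume maximum; geometry, acquisition and decay-reference datetimes
embedded) or float32 NIfTI with a JSON sidecar that carries modality,
units, timestamps, provenance and full-precision geometry (the NIfTI
header is float32, so the sidecar is authoritative and cross-checked
against the header).

## Pairing and reporting

A phantom scan and a dose-calibrator assay form a calibration pair when
taken within a configurable window (default 24 h and the same UTC calendar
day); `force` overrides. Each record stores R_P, R_D and b; b is always
recomputed from the stored recovery coefficients on load and a mismatch is
a hard error. Longitudinal series are split into segments per site
wherever the scanner's ACF changes by more than a relative tolerance
(default 1e-6, i.e. any change), because recovery coefficients track the
ACF; within-segment and overall COV of R are reported side by side.
Summary groups are ordered lexicographically; COV is omitted for
single-measurement groups.

## Numerical and degenerate-input choices

* `decay_factor` uses `exp2`, exact at integer half-life multiples.
* `density_from_weighing` accepts the neutral-buoyancy limit
  (mass under water = 0 → density of water) and rejects
  mass_air ≤ mass_water.
* An all-zero or signal-free volume raises "phantom not found" rather than
  returning a centroid of noise; so does a largest component under the
  minimum volume.
* ROI boxes that hold no whole voxel along an axis, or extend outside the
  grid, are errors — never silently clipped.
* Record CSVs are written deterministically (no wall-clock content):
  identical inputs give byte-identical files.

## Testing problem sizes

Unit and acceptance tests run the full chain on the default
84 × 84 × 46 grid (one shared noiseless render per session) plus a handful
of per-test renders for translations/rotations; property suites use a few
hundred random draws with fixed seeds. The frame-averaging check uses 24
repeats of 1- and 4-frame averages at 5% noise, wide-banded around the
expected 1/√n COV scaling.
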