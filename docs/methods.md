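# Methods

## Dose model

CTDI_vol is a scanner-output quantity referenced to a standard acrylic
phantom (32 cm for body, 16 cm for head protocols). The size-specific
dose estimate rescales it by a conversion factor that decays
exponentially in a patient-size metric D (cm):

    f(D) = a · exp(−b·D),      SSDE = f(D) · CTDI_vol.

Two size metrics are supported:

* **Effective diameter** ED = √(AP·LAT) — the diameter of the circle
  with the area of the elliptical approximation of the section. Pure
  geometry; implicitly assumes the section is water-equivalent.
* **Water-equivalent diameter** WED = 2·√(A_w/π) with
  A_w = (mean HU/1000 + 1)·A — the diameter of the water cylinder with
  the same X-ray attenuation as the section. The weight HU/1000 + 1 is
  the standard linear mapping of CT number to attenuation relative to
  water (air −1000 → 0, water 0 → 1).

Both routes to A_w — the pixelwise sum over a mask and the
(mean HU, area) ROI summary — are algebraically identical on the same
mask, and the package tests them against each other to machine
precision.

### Conversion coefficients

The exponential fits to the AAPM TG-204 conversion tables are shipped as
an editable TSV keyed by phantom diameter (`src/ssdekit/data/`):

| phantom | a | b | valid D range |
|---|---|---|---|
| 32 cm | 3.704369 | 0.03671937 | 6–55 cm |
| 16 cm | 1.874799 | 0.03871313 | 6–45 cm |

f crosses 1 at D = ln(a)/b ≈ 35.7 cm (32-cm phantom), so every adult
torso diameter in the supported range has SSDE > CTDI_vol. Diameters
outside the fitted range warn and extrapolate rather than fail, since
audit cohorts occasionally contain subjects near or beyond the phantom
diameter. Coefficients are data, not code; alternative fits (e.g.
TG-220-style WED fits) can be swapped in by editing the table or
constructing `ConversionCoefficients` directly.

Because f is convex in D, the group mean of per-patient SSDE differs
from f(group-mean D)·(group-mean CTDI_vol) by a Jensen-type gap
(measured below 3% at the default dispersions; tested). The package
always aggregates per-patient first; the product-of-means shortcut is
only ever used as a consistency diagnostic.

## Image pipeline

Segmentation thresholds the slice at −250 HU (above air, below any soft
tissue, keeping the low-density skin margin), labels connected
components, keeps the largest (which discards the thin patient-table
slab), and fills interior holes so lungs and bowel gas belong to the
body ROI — the image analogue of a workstation ROI "whole section except
the table". For uniform phantoms any threshold in [−900, −300] HU yields
the identical mask (tested). A mask touching the image border sets a
truncation warning flag.

AP/LAT are the mask's bounding-box extents (axis 0 = anteroposterior,
axis 1 = lateral) times pixel spacing — the orthogonal-extent convention
of workstation measurements, not caliper diameters through the centroid.
On rasterized ellipses this is exact to ±1 pixel per side.

Units are cm/cm²/mGy everywhere; DICOM mm spacing is converted at read
time, and rescale slope/intercept are applied to produce HU. A portable
plain-text grid format (header `rows cols spacing_ap spacing_lat`, then
HU rows) lets the whole pipeline run without pydicom.

## Synthetic phantoms

A phantom is an axis-aligned ellipse of constant HU on air, with
optional disjoint elliptical inclusions and an optional table slab
(300 HU, 0.4 cm thick, 0.3 cm below the body). Rendering samples pixel
centers with no anti-aliasing, so the analytic formulas (ellipse areas,
region-weighted A_w) are exact up to discretization; convergence tests
bound the discretization error (body area within 1% at 0.05 cm pixels,
round-trip ED/WED within 1% at 0.1 cm and 0.3% at 0.05 cm). The table
slab is excluded from analytic ground truth by construction — it exists
only to exercise the largest-component rule.

Limitations: 2-D single slices only; no noise texture, beam hardening,
partial-volume blur, arms, or non-elliptical anatomy. Passing the
round-trip tests shows the arithmetic and segmentation logic are
correct, not that the segmentation is robust to clinical image quality.

## Cohort simulator

`chest_cohort_spec()` / `abdomen_cohort_spec()` encode the study
conditions of a 200-patient adult audit (100 per region) split into
three BMI groups (<20, 20–24.9, >24.9 kg/m²; n = 30/36/34 chest,
31/35/34 abdomen) with the published group-mean AP, LAT, ED, WED,
conversion factors, CTDI_vol and SSDE values stored in
`CHEST_TABLE`/`ABDOMEN_TABLE`. Per patient the simulator draws:

* AP, LAT: bivariate normal around the group means, correlation 0.7
  (torsos scale roughly isometrically), SD 2.0 cm. The source tables'
  SDs are typographically corrupted, so the dispersion defaults are the
  package's own choice, consistent with the legible digit patterns, and
  every SD is overridable in `CohortSpec`.
* mean ROI HU: normal with SD 60 HU around a group mean *derived* from
  the published WED/ED ratio via hu = 1000·((WED/ED)² − 1) — chest
  groups ≈ −330/−286/−218 HU, abdomen ≈ +77/+119/+223 HU — truncated to
  the region's sign (chest negative, abdomen positive) by bounded
  resampling.
* ROI area: π·AP·LAT/4 (elliptical section, consistent with the
  phantom model).
* CTDI_vol: max(0.5, intercept + slope·ED + N(0, 0.3 mGy)), the linear
  tube-current-modulation proxy fitted by least squares to the three
  published (group-mean ED, group-mean CTDI_vol) pairs per region. No
  published dispersion exists for the dose residual; 0.3 mGy keeps
  group dose CVs in a clinically plausible range.
* BMI: uniform within the group's range (16–20, 20–24.9, 24.9–35).

What the simulator reproduces: the monotone size/dose trends across BMI
groups, the sign of the chest/abdomen WED−ED split and hence the
SSDE_WED/SSDE_ED orderings, and group means recoverable to ~2 SE at the
study's group sizes (all tested, including a 100-seed trend-recovery
rate ≥95%). What it does not reproduce: the source tables' exact SDs and
p-values (the per-patient data are unavailable and the printed SDs are
corrupted), any AP/LAT–BMI correlation within groups, and non-normal
body-size distributions.

## Statistical analysis

Group summaries use the sample SD (n−1). Across-group comparisons use
one-way ANOVA computed explicitly from between/within sums of squares
(checked against hand-worked examples and against an independent library
implementation on random inputs); within-group comparisons of
SSDE_ED/SSDE_WED/CTDI_vol use the paired t-test, since the metrics are
computed on the same patients (an unpaired Welch variant is available
behind a flag for sensitivity analysis). α = 0.05 with no
multiple-comparison correction by default, matching common audit
practice; a Bonferroni option exists and is logged in the report when
enabled. Degenerate cases: identical constant groups give (F, p) =
(0, 1); an all-zero difference vector sets an exact-tie flag instead of
a t statistic.

BMI boundary convention: exactly 24.9 kg/m² falls in the middle group;
anything strictly above goes to the high group.

## Design choices and numerical notes

* A_w ≤ 0 (an ROI of pure air) is an error, never clamped.
* The ED formula is the geometric mean; the identity ED = √(AP·LAT)
  holds for all six published group-mean rows to 0.01 cm, which the
  acceptance checks recompute.
* The 32-cm phantom is the default for both regions: every published
  conversion factor is consistent with the 32-cm coefficients.
* Default ROI is the full body mask (parameter-free); for elliptical
  bodies it coincides with an elliptical ROI.
* Problem sizes in the test suite (grids ≤ ~350², cohorts of 100–3000,
  100 simulation seeds) were chosen so the full suite completes in a few
  seconds while still bounding discretization and sampling error
  meaningfully.
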