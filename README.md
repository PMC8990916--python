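# ssdekit

Size-specific dose estimates (SSDE) for adult chest and abdominal CT.

The volume CT dose index CTDI_vol (mGy) that a scanner reports is
referenced to a fixed acrylic phantom (32 cm diameter for body protocols)
and says nothing about the patient on the table: for almost every adult
torso it *underestimates* the absorbed dose. The size-specific dose
estimate corrects it with an exponential function of a patient-size
metric D:

```
ED   = sqrt(AP × LAT)                 effective diameter (geometry only)
A_w  = (mean HU / 1000 + 1) × A       water-equivalent area of the section
WED  = 2 · sqrt(A_w / π)              water-equivalent diameter (attenuation-aware)
f(D) = a · e^(−b·D)                   size conversion factor
SSDE = f(D) · CTDI_vol
```

AP and LAT are the anteroposterior and lateral external diameters of the
section in cm; the default (a, b) are the published exponential fits to
the AAPM TG-204 conversion tables (32-cm body phantom:
a = 3.704369, b = 0.03671937, so f crosses 1 at D ≈ 35.7 cm).

Because lungs attenuate far less than water, a chest section has a
negative mean CT number, WED < ED, and therefore SSDE_WED > SSDE_ED;
abdominal soft tissue is slightly denser than water, so the ordering
flips. `ssdekit` implements the full pipeline — body segmentation from a
CT slice, both size metrics, the conversion to SSDE, and a BMI-stratified
group comparison (one-way ANOVA across groups, paired t-tests within
groups) — together with a synthetic elliptical-phantom renderer and a
cohort simulator so that every stage is testable against closed-form
ground truth without any patient data.

Intended users: medical-physics and radiology-informatics people running
CT dose audits, and anyone who needs a tested reference implementation of
the ED/WED/SSDE arithmetic.

## Worked example

```python
from ssdekit import (simulate_cohort, chest_cohort_spec, abdomen_cohort_spec)
from ssdekit.analysis import apply_ssde, build_report, render_text

records = apply_ssde(
    simulate_cohort(chest_cohort_spec(seed=7))
    + simulate_cohort(abdomen_cohort_spec(seed=8))
)
print(render_text(build_report(records)))
```

prints, among the four tables (trimmed):

```
== chest: dose metrics (mean ± SD; * = ANOVA p < 0.05 across groups) ==
group   n   ctdi_vol*      ssde_ed*       ssde_wed*
A       30  3.79 ± 1.24    5.34 ± 1.46    6.39 ± 1.85
B       36  4.88 ± 1.23    6.52 ± 1.32    7.64 ± 1.63
C       34  6.51 ± 1.48    7.98 ± 1.30    9.10 ± 1.57

== chest: within-group paired comparisons ==
A: ssde_ed vs ctdi_vol: t=34.782 p=3.373e-25*
A: ssde_wed vs ssde_ed: t=13.519 p=4.747e-14*
...
```

Reading it: groups A/B/C are the BMI strata (<20, 20–24.9, >24.9 kg/m²);
dose rises with BMI (tube-current modulation); within every group both
SSDE columns exceed CTDI_vol (every adult is smaller than the 32-cm
reference phantom), and for the chest SSDE_WED > SSDE_ED because the
air-bearing thorax attenuates less than its geometry suggests. The
abdomen tables show the reversed SSDE ordering.

The same pipeline is scriptable from the shell:

```
ssdekit simulate --region both --seed 7 --out cohort.csv
ssdekit ssde     --in cohort.csv --phantom 32 --out cohort_ssde.csv
ssdekit report   --in cohort.csv --out tables/
ssdekit metrics  slice.grid ct.dcm        # AP/LAT/ED/WED from images
```

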