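"""Synthetic patient cohorts for chest and abdominal CT dose studies.

Simulates per-patient records (AP, LAT, mean ROI HU, ROI area, BMI,
CTDI_vol) with the statistical structure of a BMI-stratified clinical
dose audit: three BMI groups per region (<20, 20-24.9, >24.9 kg/m²),
body size increasing with BMI, chest sections attenuating less than
water (mean HU < 0, so WED < ED) and abdominal sections slightly more
(mean HU > 0, WED > ED), and CTDI_vol rising with body size through
tube-current modulation.

The default group parameters are the published group means of a
200-patient adult chest/abdomen audit (100 patients per region); they are
exposed as :data:`CHEST_TABLE` / :data:`ABDOMEN_TABLE` and drive both the
simulator defaults and parameter-recovery tests.  Each group's mean ROI
HU is derived from its WED/ED ratio via hu = 1000*((WED/ED)² - 1), and
the CTDI_vol model is a least-squares line in ED through the three group
mean (ED, CTDI_vol) pairs per region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .body_metrics import SizeMetrics, effective_diameter
from .ssde import SSDEResult
from .wed import wed_from_roi_stats

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "PatientRecord",
    "simulate_cohort",
    "chest_cohort_spec",
    "abdomen_cohort_spec",
    "CHEST_TABLE",
    "ABDOMEN_TABLE",
]

#: Published group means of the reference audit, by BMI group.
#: Keys: n, ap/lat/ed/wed (cm), f_ed/f_wed (dimensionless),
#: ctdi/ssde_ed/ssde_wed (mGy), bmi_range (kg/m²; simulation draw range).
CHEST_TABLE: dict[str, dict] = {
    "A": dict(n=30, ap=21.63, lat=30.19, ed=25.55, f_ed=1.44, wed=20.91,
              f_wed=1.71, ctdi=3.74, ssde_ed=5.32, ssde_wed=6.34,
              bmi_range=(16.0, 20.0)),
    "B": dict(n=36, ap=22.65, lat=32.17, ed=26.99, f_ed=1.37, wed=22.81,
              f_wed=1.59, ctdi=4.36, ssde_ed=5.89, ssde_wed=6.90,
              bmi_range=(20.0, 24.9)),
    "C": dict(n=34, ap=24.99, lat=35.04, ed=29.59, f_ed=1.25, wed=26.17,
              f_wed=1.41, ctdi=6.53, ssde_ed=8.03, ssde_wed=9.12,
              bmi_range=(24.9, 35.0)),
}

ABDOMEN_TABLE: dict[str, dict] = {
    "D": dict(n=31, ap=18.92, lat=27.84, ed=22.95, f_ed=1.59, wed=23.82,
              f_wed=1.54, ctdi=3.52, ssde_ed=5.52, ssde_wed=5.35,
              bmi_range=(16.0, 20.0)),
    "E": dict(n=35, ap=20.16, lat=29.23, ed=24.28, f_ed=1.51, wed=25.68,
              f_wed=1.44, ctdi=4.19, ssde_ed=6.28, ssde_wed=5.96,
              bmi_range=(20.0, 24.9)),
    "F": dict(n=34, ap=21.75, lat=31.49, ed=26.17, f_ed=1.41, wed=28.94,
              f_wed=1.27, ctdi=6.09, ssde_ed=8.50, ssde_wed=7.67,
              bmi_range=(24.9, 35.0)),
}

_MAX_RESAMPLES = 200


@dataclass(frozen=True)
class GroupSpec:
    """Simulation parameters for one BMI group."""

    label: str
    n: int
    ap_mean: float
    ap_sd: float
    lat_mean: float
    lat_sd: float
    hu_mean: float
    hu_sd: float
    bmi_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be positive")
        if min(self.ap_sd, self.lat_sd, self.hu_sd) < 0:
            raise ValueError("SDs must be non-negative")
        if not self.bmi_range[0] < self.bmi_range[1]:
            raise ValueError(f"BMI range must be ordered, got {self.bmi_range}")


@dataclass(frozen=True)
class CohortSpec:
    """Full simulation spec for one region's cohort.

    ``ctdi_slope``/``ctdi_intercept`` define the tube-current-modulation
    dose model CTDI_vol = intercept + slope*ED + noise (mGy, mGy/cm);
    ``ap_lat_corr`` is the AP-LAT correlation (body shapes scale roughly
    isometrically).
    """

    region: str
    groups: tuple[GroupSpec, GroupSpec, GroupSpec]
    ctdi_slope: float
    ctdi_intercept: float
    ctdi_noise_sd: float = 0.3
    ap_lat_corr: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region not in ("chest", "abdomen"):
            raise ValueError(f"region must be chest|abdomen, got {self.region!r}")
        if not -1.0 < self.ap_lat_corr < 1.0:
            raise ValueError("AP-LAT correlation must be in (-1, 1)")
        if self.ctdi_noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        ranges = [g.bmi_range for g in self.groups]
        if not all(ranges[i][1] <= ranges[i + 1][0] for i in range(2)):
            raise ValueError("group BMI ranges must be ordered and non-overlapping")


@dataclass
class PatientRecord:
    """One subject: region, BMI, size/attenuation metrics, CTDI_vol, and
    (after the SSDE engine runs) the dose bundle."""

    id: str
    region: str
    bmi: float
    size: SizeMetrics
    ctdi_vol: float
    ssde: SSDEResult | None = None


def _hu_from_wed_ed_ratio(wed: float, ed: float) -> float:
    return 1000.0 * ((wed / ed) ** 2 - 1.0)


def _fit_ctdi_line(table: dict[str, dict]) -> tuple[float, float]:
    eds = [row["ed"] for row in table.values()]
    doses = [row["ctdi"] for row in table.values()]
    slope, intercept = np.polyfit(eds, doses, 1)
    return float(slope), float(intercept)


def _spec_from_table(
    region: str, table: dict[str, dict], seed: int,
    ap_sd: float, lat_sd: float, hu_sd: float,
) -> CohortSpec:
    groups = tuple(
        GroupSpec(
            label=label,
            n=row["n"],
            ap_mean=row["ap"],
            ap_sd=ap_sd,
            lat_mean=row["lat"],
            lat_sd=lat_sd,
            hu_mean=_hu_from_wed_ed_ratio(row["wed"], row["ed"]),
            hu_sd=hu_sd,
            bmi_range=row["bmi_range"],
        )
        for label, row in table.items()
    )
    slope, intercept = _fit_ctdi_line(table)
    return CohortSpec(
        region=region,
        groups=groups,  # type: ignore[arg-type]
        ctdi_slope=slope,
        ctdi_intercept=intercept,
        seed=seed,
    )


def chest_cohort_spec(
    seed: int = 0, ap_sd: float = 2.0, lat_sd: float = 2.0, hu_sd: float = 60.0
) -> CohortSpec:
    """Default chest cohort spec (groups A/B/C, reference-audit means)."""
    return _spec_from_table("chest", CHEST_TABLE, seed, ap_sd, lat_sd, hu_sd)


def abdomen_cohort_spec(
    seed: int = 0, ap_sd: float = 2.0, lat_sd: float = 2.0, hu_sd: float = 60.0
) -> CohortSpec:
    """Default abdomen cohort spec (groups D/E/F)."""
    return _spec_from_table("abdomen", ABDOMEN_TABLE, seed, ap_sd, lat_sd, hu_sd)


def _draw_positive_pair(
    rng: np.random.Generator, g: GroupSpec, corr: float
) -> tuple[float, float]:
    cov = [
        [g.ap_sd**2, corr * g.ap_sd * g.lat_sd],
        [corr * g.ap_sd * g.lat_sd, g.lat_sd**2],
    ]
    for _ in range(_MAX_RESAMPLES):
        ap, lat = rng.multivariate_normal([g.ap_mean, g.lat_mean], cov)
        if ap > 0 and lat > 0:
            return float(ap), float(lat)
    raise RuntimeError(
        f"could not draw positive AP/LAT for group {g.label} after "
        f"{_MAX_RESAMPLES} attempts; check the group means/SDs"
    )


def _draw_signed_hu(rng: np.random.Generator, g: GroupSpec, region: str) -> float:
    # chest sections attenuate less than water, abdominal ones more:
    # the draw is truncated to the region's sign
    for _ in range(_MAX_RESAMPLES):
        hu = rng.normal(g.hu_mean, g.hu_sd)
        if (region == "chest" and -1000.0 < hu < 0.0) or (
            region == "abdomen" and hu > 0.0
        ):
            return float(hu)
    raise RuntimeError(
        f"could not draw a {region}-sign mean HU for group {g.label}"
    )


def simulate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw one cohort; reproducible given ``spec.seed``.

    Per patient: correlated AP/LAT, region-signed mean HU, ROI area from
    the elliptical section, WED from (mean HU, area), BMI uniform within
    the group's range, and CTDI_vol = max(0.5, intercept + slope*ED +
    noise) emulating tube-current modulation.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[PatientRecord] = []
    for g in spec.groups:
        for i in range(g.n):
            ap, lat = _draw_positive_pair(rng, g, spec.ap_lat_corr)
            hu = _draw_signed_hu(rng, g, spec.region)
            bmi = float(rng.uniform(*g.bmi_range))
            area = math.pi * ap * lat / 4.0
            ed = effective_diameter(ap, lat)
            ctdi = max(
                0.5,
                spec.ctdi_intercept
                + spec.ctdi_slope * ed
                + float(rng.normal(0.0, spec.ctdi_noise_sd)),
            )
            size = SizeMetrics(
                ap=ap, lat=lat, ed=ed, roi_area=area, mean_hu=hu,
                wed=wed_from_roi_stats(hu, area),
            )
            records.append(
                PatientRecord(
                    id=f"{spec.region}-{g.label}{i + 1:03d}",
                    region=spec.region,
                    bmi=bmi,
                    size=size,
                    ctdi_vol=ctdi,
                )
            )
    return records
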