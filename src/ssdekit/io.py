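"""File formats: cohort CSV, portable HU grid, DICOM CT slices.

Cohort CSV schema (header required, exact names)::

    patient_id,region,bmi_kg_m2,ap_cm,lat_cm,mean_hu,roi_area_cm2,ctdivol_mgy[,image_path]

All lengths are cm, areas cm², doses mGy.  On read, ED is recomputed
from (ap_cm, lat_cm) and WED from (mean_hu, roi_area_cm2), so a cohort
file is self-contained without images.

The portable grid format is a plain-text raster: one header line
``rows cols spacing_ap_cm spacing_lat_cm`` (a single spacing value means
isotropic pixels) followed by ``rows`` whitespace-separated rows of HU
values.  It exists so the whole pipeline runs without any DICOM
dependency; DICOM single-frame CT reading (rescale slope/intercept
applied, mm spacing converted to cm) is available when pydicom is
installed.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .body_metrics import CTImage, SizeMetrics, effective_diameter
from .cohort import CohortSpec, GroupSpec, PatientRecord, abdomen_cohort_spec, chest_cohort_spec
from .wed import wed_from_roi_stats

__all__ = [
    "COHORT_COLUMNS",
    "CohortFormatError",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_grid",
    "write_grid",
    "read_ct_slice",
    "cohort_spec_from_config",
    "cohort_spec_to_config",
]

COHORT_COLUMNS = [
    "patient_id",
    "region",
    "bmi_kg_m2",
    "ap_cm",
    "lat_cm",
    "mean_hu",
    "roi_area_cm2",
    "ctdivol_mgy",
]
_REGIONS = {"chest", "abdomen"}


class CohortFormatError(ValueError):
    """Schema or row-level problem in a cohort CSV."""


def _row_error(line: int, msg: str) -> CohortFormatError:
    return CohortFormatError(f"line {line}: {msg}")


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    """Read and validate a cohort CSV into patient records.

    WED is computed from (mean_hu, roi_area_cm2); invalid rows raise
    :class:`CohortFormatError` with the 1-based file line number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {COHORT_COLUMNS}"
        )
    records: list[PatientRecord] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        region = row["region"].strip()
        if region not in _REGIONS:
            raise _row_error(
                line, f"region {region!r} not in {sorted(_REGIONS)}"
            )
        vals = {}
        for col in COHORT_COLUMNS[2:]:
            try:
                vals[col] = float(row[col])
            except ValueError:
                raise _row_error(
                    line, f"non-numeric value {row[col]!r} in column {col}"
                ) from None
        if vals["bmi_kg_m2"] <= 0:
            raise _row_error(line, f"BMI must be positive, got {vals['bmi_kg_m2']}")
        if vals["ap_cm"] <= 0 or vals["lat_cm"] <= 0:
            raise _row_error(line, "ap_cm and lat_cm must be positive")
        if vals["roi_area_cm2"] <= 0:
            raise _row_error(line, "roi_area_cm2 must be positive")
        if vals["mean_hu"] <= -1000:
            raise _row_error(line, f"mean_hu must exceed -1000, got {vals['mean_hu']}")
        if vals["ctdivol_mgy"] < 0:
            raise _row_error(line, "ctdivol_mgy cannot be negative")
        size = SizeMetrics(
            ap=vals["ap_cm"],
            lat=vals["lat_cm"],
            ed=effective_diameter(vals["ap_cm"], vals["lat_cm"]),
            roi_area=vals["roi_area_cm2"],
            mean_hu=vals["mean_hu"],
            wed=wed_from_roi_stats(vals["mean_hu"], vals["roi_area_cm2"]),
        )
        records.append(
            PatientRecord(
                id=row["patient_id"],
                region=region,
                bmi=vals["bmi_kg_m2"],
                size=size,
                ctdi_vol=vals["ctdivol_mgy"],
            )
        )
    return records


def write_cohort_csv(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write patient records in the cohort CSV schema (full precision)."""
    rows = [
        {
            "patient_id": r.id,
            "region": r.region,
            "bmi_kg_m2": repr(r.bmi),
            "ap_cm": repr(r.size.ap),
            "lat_cm": repr(r.size.lat),
            "mean_hu": repr(r.size.mean_hu),
            "roi_area_cm2": repr(r.size.roi_area),
            "ctdivol_mgy": repr(r.ctdi_vol),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def write_grid(image: CTImage, path: str | Path) -> None:
    """Write a CT slice in the portable text grid format."""
    rows, cols = image.shape
    sp_ap, sp_lat = image.pixel_spacing
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{rows} {cols} {sp_ap!r} {sp_lat!r}\n")
        np.savetxt(fh, image.values, fmt="%.10g")


def read_grid(path: str | Path) -> CTImage:
    """Read the portable text grid format back into a CT slice."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) == 3:
            rows, cols = int(header[0]), int(header[1])
            spacing = (float(header[2]), float(header[2]))
        elif len(header) == 4:
            rows, cols = int(header[0]), int(header[1])
            spacing = (float(header[2]), float(header[3]))
        else:
            raise ValueError(
                f"{path}: grid header must be 'rows cols spacing[_ap spacing_lat]', "
                f"got {' '.join(header)!r}"
            )
        values = np.loadtxt(fh, ndmin=2)
    if values.shape != (rows, cols):
        raise ValueError(
            f"{path}: header promises {rows}x{cols} but file holds "
            f"{values.shape[0]}x{values.shape[1]}"
        )
    return CTImage(values=values, pixel_spacing=spacing)


def _looks_like_dicom(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def read_dicom_slice(path: str | Path) -> CTImage:
    """Read a single-frame DICOM CT slice into HU with cm spacing."""
    import pydicom

    ds = pydicom.dcmread(path)
    modality = getattr(ds, "Modality", None)
    if modality != "CT":
        raise ValueError(f"{path}: modality {modality!r} is not CT")
    spacing_mm = getattr(ds, "PixelSpacing", None)
    if spacing_mm is None:
        raise ValueError(
            f"{path}: missing PixelSpacing (0028,0030); cannot establish "
            "physical scale"
        )
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = ds.pixel_array.astype(float) * slope + intercept
    spacing_cm = (float(spacing_mm[0]) / 10.0, float(spacing_mm[1]) / 10.0)
    return CTImage(values=hu, pixel_spacing=spacing_cm)


def read_ct_slice(path: str | Path) -> CTImage:
    """Read a CT slice from DICOM or the portable grid format (sniffed)."""
    p = Path(path)
    if _looks_like_dicom(p):
        return read_dicom_slice(p)
    return read_grid(p)


# -- cohort-spec config (flat JSON-style dict) --------------------------------

_SPEC_SCALARS = (
    "region", "ctdi_slope", "ctdi_intercept", "ctdi_noise_sd",
    "ap_lat_corr", "seed",
)


def cohort_spec_to_config(spec: CohortSpec) -> dict:
    """Serialize a cohort spec as a JSON-compatible dict."""
    cfg: dict = {k: getattr(spec, k) for k in _SPEC_SCALARS}
    cfg["groups"] = [
        {
            "label": g.label, "n": g.n,
            "ap_mean": g.ap_mean, "ap_sd": g.ap_sd,
            "lat_mean": g.lat_mean, "lat_sd": g.lat_sd,
            "hu_mean": g.hu_mean, "hu_sd": g.hu_sd,
            "bmi_min": g.bmi_range[0], "bmi_max": g.bmi_range[1],
        }
        for g in spec.groups
    ]
    return cfg


def cohort_spec_from_config(cfg: dict) -> CohortSpec:
    """Build a cohort spec from a config dict.

    A minimal config is ``{"region": "chest", "seed": 7}`` — the region's
    default group structure is used, with any of the scalar fields or the
    full ``groups`` list overridable.  The seed is mandatory.
    """
    cfg = dict(cfg)
    region = cfg.get("region")
    if region not in ("chest", "abdomen"):
        raise ValueError(f"config region must be chest|abdomen, got {region!r}")
    if "seed" not in cfg:
        raise ValueError("config must carry an explicit seed")
    base = chest_cohort_spec() if region == "chest" else abdomen_cohort_spec()
    groups = base.groups
    if "groups" in cfg:
        groups = tuple(
            GroupSpec(
                label=g["label"], n=int(g["n"]),
                ap_mean=float(g["ap_mean"]), ap_sd=float(g["ap_sd"]),
                lat_mean=float(g["lat_mean"]), lat_sd=float(g["lat_sd"]),
                hu_mean=float(g["hu_mean"]), hu_sd=float(g["hu_sd"]),
                bmi_range=(float(g["bmi_min"]), float(g["bmi_max"])),
            )
            for g in cfg["groups"]
        )
        if len(groups) != 3:
            raise ValueError("config must define exactly three BMI groups")
    return CohortSpec(
        region=region,
        groups=groups,  # type: ignore[arg-type]
        ctdi_slope=float(cfg.get("ctdi_slope", base.ctdi_slope)),
        ctdi_intercept=float(cfg.get("ctdi_intercept", base.ctdi_intercept)),
        ctdi_noise_sd=float(cfg.get("ctdi_noise_sd", base.ctdi_noise_sd)),
        ap_lat_corr=float(cfg.get("ap_lat_corr", base.ap_lat_corr)),
        seed=int(cfg["seed"]),
    )
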