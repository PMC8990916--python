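"""Body segmentation and external size metrics from an axial CT slice.

The anteroposterior (AP) and lateral (LAT) external diameters of the body
section, measured in cm on the slice, summarize patient habitus.  Their
geometric mean is the *effective diameter*

    ED = sqrt(AP * LAT),

the diameter of the circle whose area equals that of the ellipse with axes
AP and LAT.  ED is the geometry-only size surrogate used by CTDI-to-SSDE
conversion; the attenuation-aware counterpart (WED) lives in
:mod:`ssdekit.wed`.

Axis convention: the first image axis is anteroposterior, the second is
left-right (lateral).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "CTImage",
    "BodyMask",
    "SizeMetrics",
    "SegmentationError",
    "segment_body",
    "measure_ap_lat",
    "effective_diameter",
    "DEFAULT_BODY_THRESHOLD_HU",
]

#: Default body segmentation threshold in HU.  Sits well above air (-1000)
#: and below any soft tissue, so the body contour (including low-density
#: skin margin and lung-bearing interior after hole filling) is kept.
DEFAULT_BODY_THRESHOLD_HU = -250.0

HU_AIR = -1000.0
HU_FLOOR = -1024.0


class SegmentationError(RuntimeError):
    """Raised when no body component can be found in a slice."""


@dataclass(frozen=True)
class CTImage:
    """A calibrated 2-D CT slice.

    Parameters
    ----------
    values
        2-D array of CT numbers in Hounsfield units (water = 0,
        air = -1000).
    pixel_spacing
        Physical size of a pixel in cm, ``(row_spacing, col_spacing)``;
        the row axis is anteroposterior, the column axis lateral.
    """

    values: np.ndarray
    pixel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("CT image must be a non-empty 2-D grid")
        if arr.min() < HU_FLOOR:
            raise ValueError(
                f"HU values below {HU_FLOOR} are not valid CT numbers "
                f"(min found: {arr.min():.1f})"
            )
        sp = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        if sp[0] <= 0 or sp[1] <= 0:
            raise ValueError(f"pixel spacing must be positive, got {sp}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "pixel_spacing", sp)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_cm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]


@dataclass(frozen=True)
class BodyMask:
    """Boolean body mask aligned to a :class:`CTImage`.

    ``table_excluded`` records that the patient-table slab (if any) was
    discarded by the largest-component rule; ``touches_border`` flags
    possible field-of-view truncation.
    """

    mask: np.ndarray
    table_excluded: bool = False
    touches_border: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "mask", m)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    def area_cm2(self, image: CTImage) -> float:
        if self.mask.shape != image.shape:
            raise ValueError("mask and image shapes differ")
        return self.pixel_count * image.pixel_area_cm2


@dataclass
class SizeMetrics:
    """Size and attenuation summary of one body section (all lengths cm)."""

    ap: float
    lat: float
    ed: float
    roi_area: float
    mean_hu: float
    wed: float | None = None

    def __post_init__(self) -> None:
        if self.ap <= 0 or self.lat <= 0 or self.ed <= 0:
            raise ValueError("AP, LAT and ED must be positive")
        if self.roi_area <= 0:
            raise ValueError("ROI area must be positive")
        lo, hi = sorted((self.ap, self.lat))
        # geometric mean lies between its arguments; tolerance covers
        # rasterized measurements where ED is recomputed from AP/LAT
        if not (lo * 0.999 <= self.ed <= hi * 1.001):
            raise ValueError(
                f"ED={self.ed:.3f} outside [min(AP,LAT), max(AP,LAT)] = "
                f"[{lo:.3f}, {hi:.3f}]"
            )


def segment_body(
    image: CTImage, threshold: float = DEFAULT_BODY_THRESHOLD_HU
) -> BodyMask:
    """Segment the body from a CT slice by thresholding.

    Pixels at or above ``threshold`` HU are foreground; the largest
    connected component is kept (this discards the thin patient-table
    slab) and interior holes are filled so that lungs and bowel gas count
    as body.

    Raises
    ------
    SegmentationError
        If no pixel reaches the threshold.
    """
    if not (HU_AIR < threshold):
        raise ValueError(
            f"threshold must be above air ({HU_AIR} HU), got {threshold}"
        )
    fg = image.values >= threshold
    labels, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationError(
            f"no component found at threshold {threshold} HU (all-air slice?)"
        )
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    body = labels == largest
    body = ndimage.binary_fill_holes(body)
    touches = bool(
        body[0, :].any() or body[-1, :].any()
        or body[:, 0].any() or body[:, -1].any()
    )
    if touches:
        warnings.warn(
            "body mask touches the image border; the field of view may "
            "truncate the section",
            stacklevel=2,
        )
    return BodyMask(mask=body, table_excluded=(n > 1), touches_border=touches)


def measure_ap_lat(mask: BodyMask, spacing: tuple[float, float]) -> tuple[float, float]:
    """Bounding-box AP and LAT extents of a body mask, in cm.

    AP is the extent along the first (row) axis, LAT along the second.
    """
    rows = np.flatnonzero(mask.mask.any(axis=1))
    cols = np.flatnonzero(mask.mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("cannot measure an empty mask")
    ap = (rows[-1] - rows[0] + 1) * float(spacing[0])
    lat = (cols[-1] - cols[0] + 1) * float(spacing[1])
    return ap, lat


def effective_diameter(ap: float, lat: float) -> float:
    """Effective diameter ED = sqrt(AP * LAT), in cm.

    Symmetric in its arguments and always between min(AP, LAT) and
    max(AP, LAT).
    """
    if ap <= 0 or lat <= 0:
        raise ValueError(f"AP and LAT must be positive, got ({ap}, {lat})")
    return math.sqrt(ap * lat)
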