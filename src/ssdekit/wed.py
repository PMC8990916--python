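"""Water-equivalent area and water-equivalent diameter (WED).

A pixel with CT number ``HU`` attenuates like ``HU/1000 + 1`` times the
same pixel filled with water.  Summing that weight over an ROI gives the
water-equivalent area

    A_w = sum_pixels (HU/1000 + 1) * pixel_area
        = (mean_HU/1000 + 1) * A,

and the water-equivalent diameter is the diameter of the water cylinder
with the same attenuation:

    WED = 2 * sqrt(A_w / pi).

For a chest section (air-bearing lungs, mean HU < 0) WED is smaller than
the geometric effective diameter; for an abdominal section (soft tissue
slightly denser than water, mean HU > 0) it is larger.
"""

from __future__ import annotations

import math

import numpy as np

from .body_metrics import BodyMask, CTImage

__all__ = [
    "water_equivalent_area_pixels",
    "wed_from_area",
    "wed_from_roi_stats",
    "fitted_ellipse_roi",
]


def water_equivalent_area_pixels(image: CTImage, mask: BodyMask) -> float:
    """Pixelwise water-equivalent area of the masked ROI, in cm².

    Equals ``(mean_HU/1000 + 1) * area`` exactly when mean and area are
    taken over the same mask.
    """
    if mask.mask.shape != image.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match image {image.shape}"
        )
    if mask.pixel_count == 0:
        raise ValueError("mask is empty")
    hu = image.values[mask.mask]
    return float((hu / 1000.0 + 1.0).sum() * image.pixel_area_cm2)


def fitted_ellipse_roi(mask: BodyMask) -> BodyMask:
    """Elliptical ROI fitted to a body mask (workstation-style ROI).

    The ellipse is centered on the mask centroid with semi-axes equal to
    half the bounding-box extents.  For elliptical bodies this coincides
    with the mask itself up to rasterization; it exists as an alternative
    ROI convention, the mask ROI being the parameter-free default.
    """
    if mask.pixel_count == 0:
        raise ValueError("cannot fit an ellipse to an empty mask")
    rows = np.flatnonzero(mask.mask.any(axis=1))
    cols = np.flatnonzero(mask.mask.any(axis=0))
    cy, cx = (rows[0] + rows[-1]) / 2.0, (cols[0] + cols[-1]) / 2.0
    a = (rows[-1] - rows[0] + 1) / 2.0
    b = (cols[-1] - cols[0] + 1) / 2.0
    yy, xx = np.indices(mask.mask.shape)
    ellipse = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    return BodyMask(
        mask=ellipse,
        table_excluded=mask.table_excluded,
        touches_border=mask.touches_border,
    )


def wed_from_area(a_w: float) -> float:
    """WED = 2*sqrt(A_w/pi): diameter of the water circle of area ``a_w``."""
    if a_w <= 0:
        raise ValueError(
            f"water-equivalent area must be positive, got {a_w:.4g} cm² "
            "(an ROI of pure air has no water equivalent)"
        )
    return 2.0 * math.sqrt(a_w / math.pi)


def wed_from_roi_stats(mean_hu: float, area: float) -> float:
    """WED from an ROI's mean CT number (HU) and area (cm²).

    This is the summary-statistics route used when only workstation ROI
    readouts are available; it agrees with the pixel route exactly on the
    same mask.
    """
    if area <= 0:
        raise ValueError(f"ROI area must be positive, got {area}")
    if mean_hu <= -1000.0:
        raise ValueError(
            f"mean HU {mean_hu} implies non-positive water-equivalent area"
        )
    return wed_from_area((mean_hu / 1000.0 + 1.0) * area)
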