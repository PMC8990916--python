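"""Elliptical CT phantom slices with closed-form ground truth.

A phantom is an axis-aligned ellipse of uniform CT number (the body) on
an air background, optionally carrying internal elliptical inclusions
(lungs, dense organs) and a thin high-density slab below the body that
mimics the patient table.  Because every region is an ellipse of constant
HU, the size metrics have exact closed forms, which makes the phantom an
analytic oracle for the image-based measurement pipeline:

    area  = pi * (AP/2) * (LAT/2)
    A_w   = sum over regions of (HU/1000 + 1) * region_area
    ED    = sqrt(AP * LAT)
    WED   = 2 * sqrt(A_w / pi)

Rendering samples each pixel at its center (no anti-aliasing), so pixel
counts converge to the analytic areas at O(spacing) and the oracle stays
exact up to discretization.  The table slab is deliberately excluded from
the ground truth: it exists only to exercise the segmentation's
largest-component rule, mirroring how the patient table is excluded from
a clinical ROI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .body_metrics import CTImage, SizeMetrics, effective_diameter
from .wed import wed_from_area

__all__ = ["Inclusion", "PhantomSpec", "render_phantom", "analytic_truth"]

HU_AIR = -1000.0
TABLE_HU = 300.0
TABLE_THICKNESS_CM = 0.4
TABLE_GAP_CM = 0.3


@dataclass(frozen=True)
class Inclusion:
    """Elliptical inclusion: center offset from body center (cm, AP/LAT
    axes), semi-axes (cm), and CT number (HU)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    hu: float

    def area_cm2(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]

    def _boundary(self, n: int = 360) -> np.ndarray:
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        return np.stack(
            [
                self.center[0] + self.semi_axes[0] * np.sin(t),
                self.center[1] + self.semi_axes[1] * np.cos(t),
            ],
            axis=1,
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one phantom slice.

    ``body_ap``/``body_lat`` are the full external diameters in cm along
    the anteroposterior and lateral axes; ``body_hu`` the uniform CT
    number of the body background (0 = water).  Inclusions must lie fully
    inside the body and be pairwise disjoint.
    """

    body_ap: float
    body_lat: float
    body_hu: float = 0.0
    outside_hu: float = HU_AIR
    inclusions: tuple[Inclusion, ...] = field(default_factory=tuple)
    table_present: bool = False

    def __post_init__(self) -> None:
        if self.body_ap <= 0 or self.body_lat <= 0:
            raise ValueError("body axes must be positive")
        object.__setattr__(self, "inclusions", tuple(self.inclusions))
        a, b = self.body_ap / 2.0, self.body_lat / 2.0
        for inc in self.inclusions:
            pts = inc._boundary()
            if np.any((pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 > 1.0):
                raise ValueError(
                    f"inclusion at {inc.center} with semi-axes "
                    f"{inc.semi_axes} is not contained in the body ellipse"
                )
        for i, p in enumerate(self.inclusions):
            for q in self.inclusions[i + 1 :]:
                if _ellipses_overlap(p, q):
                    raise ValueError(
                        f"inclusions at {p.center} and {q.center} overlap"
                    )

    def body_area_cm2(self) -> float:
        return math.pi * (self.body_ap / 2.0) * (self.body_lat / 2.0)


def _inside(inc: Inclusion, pts: np.ndarray) -> np.ndarray:
    dy = (pts[:, 0] - inc.center[0]) / inc.semi_axes[0]
    dx = (pts[:, 1] - inc.center[1]) / inc.semi_axes[1]
    return dy**2 + dx**2 < 1.0

def _ellipses_overlap(p: Inclusion, q: Inclusion) -> bool:
    # boundary-sampling test; exact enough for fixture geometry
    return bool(
        _inside(q, p._boundary()).any()
        or _inside(p, q._boundary()).any()
        or _inside(q, np.array([p.center]))[0]
        or _inside(p, np.array([q.center]))[0]
    )


def render_phantom(
    spec: PhantomSpec,
    pixel_spacing: float = 0.1,
    grid_size: tuple[int, int] | None = None,
) -> CTImage:
    """Rasterize a phantom spec onto a pixel grid, pixel-center sampling.

    ``pixel_spacing`` is the isotropic pixel size in cm.  When
    ``grid_size`` is omitted a grid with a 2-cm margin around the body
    (plus room for the table slab) is chosen.

    Raises
    ------
    ValueError
        If the body (plus a 1-cm margin) does not fit in the grid.
    """
    sp = float(pixel_spacing)
    if sp <= 0:
        raise ValueError("pixel spacing must be positive")
    extra_below = (TABLE_GAP_CM + TABLE_THICKNESS_CM) if spec.table_present else 0.0
    need_ap = spec.body_ap + 2.0 + 2.0 * extra_below
    need_lat = spec.body_lat + 2.0
    if grid_size is None:
        grid_size = (
            int(math.ceil((need_ap + 2.0) / sp)),
            int(math.ceil((need_lat + 2.0) / sp)),
        )
    rows, cols = grid_size
    if rows * sp < need_ap or cols * sp < need_lat:
        raise ValueError(
            f"grid {rows}x{cols} at {sp} cm/px covers "
            f"{rows * sp:.1f}x{cols * sp:.1f} cm but the phantom needs at "
            f"least {need_ap:.1f}x{need_lat:.1f} cm (body + 1 cm margin)"
        )

    # physical pixel-center coordinates, origin at grid center
    y = (np.arange(rows) - (rows - 1) / 2.0) * sp
    x = (np.arange(cols) - (cols - 1) / 2.0) * sp
    yy, xx = np.meshgrid(y, x, indexing="ij")

    img = np.full((rows, cols), spec.outside_hu, dtype=float)
    a, b = spec.body_ap / 2.0, spec.body_lat / 2.0
    body = (yy / a) ** 2 + (xx / b) ** 2 <= 1.0
    img[body] = spec.body_hu
    for inc in spec.inclusions:
        dy = (yy - inc.center[0]) / inc.semi_axes[0]
        dx = (xx - inc.center[1]) / inc.semi_axes[1]
        img[dy**2 + dx**2 <= 1.0] = inc.hu
    if spec.table_present:
        top = a + TABLE_GAP_CM
        slab = (yy >= top) & (yy <= top + TABLE_THICKNESS_CM) & (np.abs(xx) <= b)
        img[slab] = TABLE_HU
    return CTImage(values=img, pixel_spacing=(sp, sp))


def analytic_truth(spec: PhantomSpec) -> SizeMetrics:
    """Closed-form size metrics of a phantom (table slab excluded).

    The water-equivalent area is assembled region by region: the body
    contributes at its own HU, and each inclusion swaps body attenuation
    for its own over its area.
    """
    area = spec.body_area_cm2()
    w_body = spec.body_hu / 1000.0 + 1.0
    a_w = w_body * area
    hu_area = spec.body_hu * area
    for inc in spec.inclusions:
        ia = inc.area_cm2()
        a_w += (inc.hu / 1000.0 + 1.0 - w_body) * ia
        hu_area += (inc.hu - spec.body_hu) * ia
    return SizeMetrics(
        ap=spec.body_ap,
        lat=spec.body_lat,
        ed=effective_diameter(spec.body_ap, spec.body_lat),
        roi_area=area,
        mean_hu=hu_area / area,
        wed=wed_from_area(a_w),
    )
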