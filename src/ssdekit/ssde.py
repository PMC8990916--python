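"""Size conversion factors and size-specific dose estimates (SSDE).

CTDI_vol is referenced to a fixed acrylic phantom (32 cm for body
protocols, 16 cm for head) and therefore ignores patient size.  The
size-specific dose estimate rescales it by an exponential conversion
factor of the patient's diameter metric D (either ED or WED):

    f(D) = a * exp(-b * D),        SSDE = f(D) * CTDI_vol.

The default (a, b) pairs are the published exponential fits to the
AAPM TG-204 conversion-factor tables, shipped as an editable data table
keyed by phantom diameter so alternative fits can be swapped in.  For the
32-cm body phantom f crosses 1 at D = ln(a)/b ≈ 35.7 cm, so adult chest
and abdomen sections (ED typically 20-32 cm) always have SSDE > CTDI_vol.

Because f is convex in D, the mean of per-patient SSDE over a group is
not f(mean D) * mean CTDI_vol (a Jensen-type gap, small at clinical
dispersions); per-patient-first aggregation is the canonical order here.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from math import exp

from .body_metrics import SizeMetrics

__all__ = [
    "ConversionCoefficients",
    "SSDEResult",
    "conversion_factor",
    "ssde",
    "default_coefficients",
    "compute_ssde",
]

_COEFF_RESOURCE = "conversion_coefficients.tsv"


@dataclass(frozen=True)
class ConversionCoefficients:
    """Exponential conversion-factor fit for one CTDI reference phantom.

    ``f(D) = a * exp(-b * D)`` with D in cm; ``valid_range`` is the
    diameter interval the fit was derived over.
    """

    phantom_diameter: int
    a: float
    b: float
    valid_range: tuple[float, float] = (6.0, 55.0)

    def __post_init__(self) -> None:
        if self.a <= 1:
            raise ValueError(f"amplitude a must exceed 1, got {self.a}")
        if self.b <= 0:
            raise ValueError(f"decay rate b must be positive, got {self.b}")
        lo, hi = self.valid_range
        if not (lo < hi and lo >= 0 and hi <= 60):
            raise ValueError(f"implausible valid_range {self.valid_range}")


@dataclass(frozen=True)
class SSDEResult:
    """Per-patient dose bundle: CTDI_vol with its ED- and WED-based SSDE."""

    f_size_ed: float
    f_size_wed: float
    ssde_ed: float
    ssde_wed: float
    ctdi_vol: float
    phantom_diameter: int


def _load_coefficient_table() -> dict[int, ConversionCoefficients]:
    table: dict[int, ConversionCoefficients] = {}
    path = resources.files(__package__).joinpath("data", _COEFF_RESOURCE)
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            d = int(row["phantom_cm"])
            table[d] = ConversionCoefficients(
                phantom_diameter=d,
                a=float(row["a"]),
                b=float(row["b"]),
                valid_range=(float(row["d_min_cm"]), float(row["d_max_cm"])),
            )
    return table


def default_coefficients(phantom_diameter: int = 32) -> ConversionCoefficients:
    """Coefficients for the 32-cm body or 16-cm head reference phantom."""
    table = _load_coefficient_table()
    try:
        return table[int(phantom_diameter)]
    except (KeyError, ValueError):
        raise ValueError(
            f"unsupported reference phantom {phantom_diameter!r} cm; "
            f"available: {sorted(table)}"
        ) from None


def conversion_factor(d: float, coeffs: ConversionCoefficients) -> float:
    """Size conversion factor f = a*exp(-b*D) at diameter ``d`` (cm).

    Diameters outside the fit's valid range warn but are still computed,
    since clinical cohorts occasionally contain subjects near or beyond
    the 32-cm phantom diameter.
    """
    if d <= 0:
        raise ValueError(f"diameter must be positive, got {d}")
    lo, hi = coeffs.valid_range
    if not (lo <= d <= hi):
        warnings.warn(
            f"diameter {d:.1f} cm outside the fitted range "
            f"[{lo:.0f}, {hi:.0f}] cm for the "
            f"{coeffs.phantom_diameter}-cm phantom; extrapolating",
            stacklevel=2,
        )
    return coeffs.a * exp(-coeffs.b * d)


def ssde(f: float, ctdi_vol: float) -> float:
    """SSDE = f * CTDI_vol, in mGy."""
    if f <= 0:
        raise ValueError(f"conversion factor must be positive, got {f}")
    if ctdi_vol < 0:
        raise ValueError(f"CTDI_vol cannot be negative, got {ctdi_vol}")
    return f * ctdi_vol


def compute_ssde(
    size: SizeMetrics,
    ctdi_vol: float,
    coeffs: ConversionCoefficients | None = None,
) -> SSDEResult:
    """Full per-patient SSDE bundle from size metrics and CTDI_vol.

    Requires ``size.wed`` to be filled (by the WED engine or from ROI
    statistics).
    """
    if coeffs is None:
        coeffs = default_coefficients(32)
    if size.wed is None:
        raise ValueError("SizeMetrics.wed is unset; compute WED first")
    f_ed = conversion_factor(size.ed, coeffs)
    f_wed = conversion_factor(size.wed, coeffs)
    return SSDEResult(
        f_size_ed=f_ed,
        f_size_wed=f_wed,
        ssde_ed=ssde(f_ed, ctdi_vol),
        ssde_wed=ssde(f_wed, ctdi_vol),
        ctdi_vol=ctdi_vol,
        phantom_diameter=coeffs.phantom_diameter,
    )
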