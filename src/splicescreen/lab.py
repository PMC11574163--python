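"""Deterministic bench-side calculators.

Gel densitometry of splice variants (band intensity normalized to product
length), the two-band restriction-digest ratio, ellipsoid tumour volume,
and LDH-release percent specific lysis.  All four are pure functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GelBand",
    "molar_proportions",
    "digest_variant_ratio",
    "tumour_volume",
    "specific_lysis",
]


@dataclass(frozen=True)
class GelBand:
    label: str
    intensity: float  # densitometry units, >= 0
    product_length: float  # bp, > 0

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"band {self.label!r}: intensity must be >= 0")
        if self.product_length <= 0:
            raise ValueError(f"band {self.label!r}: product length must be > 0")


def molar_proportions(bands: list[GelBand]) -> dict:
    """Per-band molar fraction: (I_i / L_i) / sum_j (I_j / L_j).

    Dividing intensity by product length corrects for length-proportional
    staining, so fractions are proportional to molecule counts.
    """
    if not bands:
        raise ValueError("need at least one band")
    normalized = [b.intensity / b.product_length for b in bands]
    total = sum(normalized)
    if total <= 0:
        raise ValueError("all band intensities are zero")
    return {b.label: v / total for b, v in zip(bands, normalized)}


def digest_variant_ratio(
    intensity_uncut: float,
    intensity_cut_fragment: float,
    len_uncut: float = 309.0,
    len_cut_fragment: float = 150.0,
) -> tuple[float, float]:
    """Two-band proportion of the uncut (exon-26-included, exon-27-skipped)
    versus cut-fragment (exon-27-included) digestion products.

    Returns (uncut fraction, cut-fragment fraction), length-normalized.
    """
    props = molar_proportions(
        [
            GelBand("uncut", intensity_uncut, len_uncut),
            GelBand("cut", intensity_cut_fragment, len_cut_fragment),
        ]
    )
    return props["uncut"], props["cut"]


def tumour_volume(length: float, width: float) -> float:
    """Ellipsoid approximation V = (pi/6) * length * width^2 (mm^3)."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    return math.pi / 6.0 * length * width * width


def specific_lysis(
    sample: float, spontaneous: float, maximal: float
) -> tuple[float, bool]:
    """LDH-release cytotoxicity:
    (sample - spontaneous) / (maximal - spontaneous) * 100.

    Returns (percent, in_range).  Noisy inputs can land outside [0, 100];
    the value is returned as-is with ``in_range=False`` rather than clipped,
    so assay problems stay visible.
    """
    if maximal <= spontaneous:
        raise ValueError("maximal LDH activity must exceed spontaneous activity")
    pct = (sample - spontaneous) / (maximal - spontaneous) * 100.0
    return pct, 0.0 <= pct <= 100.0
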