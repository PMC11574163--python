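"""Bench-side calculators: gel proportions, digest ratio, volume, lysis."""

from splicescreen.lab import (
    GelBand,
    digest_variant_ratio,
    molar_proportions,
    specific_lysis,
    tumour_volume,
)

# Two RT-PCR bands of equal stain intensity: the shorter product carries
# twice as many molecules per unit intensity.
props = molar_proportions([GelBand("long", 100, 300), GelBand("short", 100, 150)])
print(f"molar fractions: long={props['long']:.3f}, short={props['short']:.3f}")

# Restriction digest separating the 309 bp (exon-27-skipped) and 150 bp
# (exon-27-included) products at equal intensities.
uncut, cut = digest_variant_ratio(100, 100)
print(f"digest proportions: skipped={uncut:.3f}, included={cut:.3f}")

# Ellipsoid tumour volume from caliper length x width.
print(f"tumour volume (L=6mm, W=3mm): {tumour_volume(6, 3):.3f} mm^3")

# LDH-release cytotoxicity relative to spontaneous/maximal controls.
pct, ok = specific_lysis(sample=60, spontaneous=20, maximal=100)
print(f"specific lysis: {pct:.1f}% (within [0,100]: {ok})")
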