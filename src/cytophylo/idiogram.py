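"""SVG idiogram rendering.

Draws a haploid idiogram: one glyph per chromosome pair, to relative-length
scale, pairs aligned on the centromere line with the short arm above and
the long arm below, the arm-ratio value printed beneath each pair, and
fluorochrome bands / rDNA sites drawn at their fractional arm positions.

Coordinate conventions: a marker's position along an arm is the fractional
distance of its centre from the centromere (0) towards the telomere (1);
its rendered centre lies at ``arm_origin + fraction * arm_extent`` where
``arm_origin`` is the centromere-side edge of the arm rectangle.  Markers
present on one homolog only are drawn on one chromatid; satellites are
drawn distal to a secondary-constriction gap on their annotated arm.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .karyotype import Karyotype
from .markers import CytoMarker

__all__ = ["IdiogramStyle", "render_idiogram"]

#: representative fractional position (of the whole chromosome, from the
#: centromere) used to draw a band whose exact distance is not annotated
_CLASS_FRACTION = {"CEN": 0.02, "PCEN": 0.10, "PROX": 0.28, "INT": 0.62, "TER": 0.92}


@dataclass
class IdiogramStyle:
    """Geometry and colors of the rendered idiogram."""

    scale: float = 18.0  # drawing units per RL percentage point
    chromatid_width: float = 9.0
    chromatid_gap: float = 2.0
    centromere_gap: float = 5.0
    pair_spacing: float = 34.0
    margin: float = 30.0
    satellite_gap: float = 3.0
    satellite_size: float = 6.0
    label_font_size: float = 9.0
    min_band_px: float = 2.0
    colors: dict = field(
        default_factory=lambda: {
            "CPD_band": "#d62728",
            "DAPI_band": "#1f77b4",
            "rDNA_45S": "#2ca02c",
            "chromosome": "#d9d9d9",
            "outline": "#555555",
        }
    )

    def __post_init__(self):
        for v in (self.scale, self.chromatid_width, self.pair_spacing):
            if v <= 0:
                raise ValueError("style dimensions must be positive")


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def render_idiogram(
    karyotype: Karyotype,
    markers: list[CytoMarker] | None = None,
    style: IdiogramStyle | None = None,
    path=None,
) -> str:
    """Render the karyotype (with attached markers) as an SVG document.

    Returns the SVG string; when ``path`` is given the document is also
    written there.  Output is deterministic for fixed inputs and style.
    """
    markers = markers or []
    style = style or IdiogramStyle()
    pair_ids = {p.pair_id for p in karyotype.pairs}
    for m in markers:
        if m.pair_id not in pair_ids:
            raise ValueError(f"marker references pair {m.pair_id} not in karyotype")

    rl_of = {p.pair_id: p.rl for p in karyotype.pairs}
    total_rl_len = {p.pair_id: p.rl * style.scale for p in karyotype.pairs}
    # arm extents in drawing units, derived from RL and CI
    extents = {}
    for p in karyotype.pairs:
        short_ext = total_rl_len[p.pair_id] * p.ci / 100.0
        extents[p.pair_id] = (short_ext, total_rl_len[p.pair_id] - short_ext)

    max_short = max(s for s, _ in extents.values())
    max_long = max(l for _, l in extents.values())
    cen_y = style.margin + max_short + style.satellite_gap + style.satellite_size
    height = cen_y + style.centromere_gap + max_long + style.margin + 14
    n = len(karyotype.pairs)
    width = 2 * style.margin + n * style.pair_spacing

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": _fmt(width),
            "height": _fmt(height),
        },
    )
    title = ET.SubElement(svg, "title")
    title.text = f"Idiogram: {karyotype.species_label or 'karyotype'}"

    by_pair: dict[int, list[CytoMarker]] = {}
    for m in markers:
        by_pair.setdefault(m.pair_id, []).append(m)

    for idx, p in enumerate(sorted(karyotype.pairs, key=lambda q: q.pair_id)):
        x0 = style.margin + idx * style.pair_spacing
        short_ext, long_ext = extents[p.pair_id]
        g = ET.SubElement(
            svg, "g", {"class": "pair", "id": f"pair-{p.pair_id}"}
        )
        chrom_w = 2 * style.chromatid_width + style.chromatid_gap

        def arm_rect(y, h):
            return {
                "x": _fmt(x0),
                "y": _fmt(y),
                "width": _fmt(chrom_w),
                "height": _fmt(h),
                "rx": _fmt(style.chromatid_width / 3),
                "fill": style.colors["chromosome"],
                "stroke": style.colors["outline"],
                "class": "arm",
            }

        short_top = cen_y - style.centromere_gap / 2 - short_ext
        long_top = cen_y + style.centromere_gap / 2
        ET.SubElement(g, "rect", arm_rect(short_top, short_ext))
        ET.SubElement(g, "rect", arm_rect(long_top, long_ext))

        if p.sat:
            # satellite drawn distal to a secondary-constriction gap
            sat_h = style.satellite_size
            if p.sat_arm == "short":
                sat_y = short_top - style.satellite_gap - sat_h
            else:
                sat_y = long_top + long_ext + style.satellite_gap
            attrs = arm_rect(sat_y, sat_h)
            attrs["class"] = "satellite"
            ET.SubElement(g, "rect", attrs)

        for m in sorted(
            by_pair.get(p.pair_id, []),
            key=lambda m: (m.marker_class, m.arm or "", m.position_class),
        ):
            arm = m.arm or "L"
            arm_ext = short_ext if arm == "S" else long_ext
            arm_um = p.mean_short if arm == "S" else p.mean_long
            if m.d is not None:
                frac = m.d / arm_um
            else:
                chrom_um = p.mean_short + p.mean_long
                frac = min(
                    _CLASS_FRACTION[m.position_class] * chrom_um / arm_um, 0.95
                )
            centre_off = frac * arm_ext
            centre_y = (
                cen_y - style.centromere_gap / 2 - centre_off
                if arm == "S"
                else cen_y + style.centromere_gap / 2 + centre_off
            )
            band_px = max(
                style.min_band_px,
                m.band_len / (arm_um / arm_ext) if m.band_len > 0 else style.min_band_px,
            )
            band_w = (
                style.chromatid_width
                if m.homologs_present == "one"
                else chrom_w
            )
            ET.SubElement(
                g,
                "rect",
                {
                    "x": _fmt(x0),
                    "y": _fmt(centre_y - band_px / 2),
                    "width": _fmt(band_w),
                    "height": _fmt(band_px),
                    "fill": style.colors[m.marker_class],
                    "class": f"marker {m.marker_class}",
                    "data-fraction": f"{frac:.4f}",
                },
            )

        label = ET.SubElement(
            g,
            "text",
            {
                "x": _fmt(x0 + chrom_w / 2),
                "y": _fmt(cen_y + style.centromere_gap / 2 + max_long + 12),
                "text-anchor": "middle",
                "font-size": _fmt(style.label_font_size),
                "class": "ar-label",
            },
        )
        label.text = f"{p.ar:.2f}"

    doc = ET.tostring(svg, encoding="unicode")
    doc = '<?xml version="1.0" encoding="UTF-8"?>\n' + doc
    if path is not None:
        with open(path, "w") as fh:
            fh.write(doc)
    return doc
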