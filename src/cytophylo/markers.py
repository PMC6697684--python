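"""Fluorochrome-band and 45S rDNA FISH site bookkeeping.

Markers are chromosome-attached annotations: GC-rich CPD bands and AT-rich
DAPI heterochromatin bands revealed by sequential fluorochrome staining,
and 45S rDNA sites mapped by FISH.  The module assigns each marker its
position code (e.g. ``1L-PROX (25.53%)``), computes the di statistic for
rDNA sites (percentage distance of the site centre from the centromere
along its arm), band amounts as a percentage of the karyotype length, and
flags heteromorphic (heterozygous) bands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict

import pandas as pd

from .karyotype import Karyotype

__all__ = [
    "MARKER_COLUMNS",
    "MARKER_CLASSES",
    "POSITION_CLASSES",
    "CytoMarker",
    "read_markers",
    "write_markers",
    "marker_code",
    "parse_marker_code",
    "rdna_di",
    "band_amount_percent",
    "heterozygosity_report",
    "position_class_from_fraction",
]

MARKER_CLASSES = ("CPD_band", "DAPI_band", "rDNA_45S")
POSITION_CLASSES = ("CEN", "PCEN", "PROX", "INT", "TER")

MARKER_COLUMNS = [
    "marker_class",
    "pair_id",
    "arm",
    "position_class",
    "band_len_um",
    "homologs_present",
    "d_um",
]

#: Fractional position of the site centre, measured from the centromere as
#: a fraction of the whole chromosome length, mapped to a position class.
#: Cutoffs are configurable via position_class_from_fraction.
POSITION_CUTOFFS = {"CEN": 0.05, "PCEN": 0.15, "PROX": 0.40, "INT": 0.85}


@dataclass
class CytoMarker:
    """One fluorochrome band or rDNA site on a chromosome pair."""

    marker_class: str
    pair_id: int
    arm: str | None  # "S", "L" or None when the arm was not resolved
    position_class: str
    band_len: float = 0.0  # per-homolog band length, µm
    homologs_present: str = "both"  # {"both", "one"}
    d: float | None = None  # rDNA site centre to centromere, µm
    band_len2: float | None = None  # second homolog's band, if heteromorphic
    co_localized_with_45S: bool = False
    di_sd: float | None = field(default=None, repr=False)  # over cells, if known

    def __post_init__(self):
        if self.marker_class not in MARKER_CLASSES:
            raise ValueError(f"unknown marker class {self.marker_class!r}")
        if self.position_class not in POSITION_CLASSES:
            raise ValueError(f"unknown position class {self.position_class!r}")
        if self.arm not in ("S", "L", None):
            raise ValueError(f"arm must be 'S', 'L' or None, got {self.arm!r}")
        if self.homologs_present not in ("both", "one"):
            raise ValueError("homologs_present must be 'both' or 'one'")


def rdna_di(d: float, a: float) -> float:
    """di = d * 100 / a: % distance of a site centre from the centromere.

    ``d`` is the distance from the centromere to the site centre and ``a``
    the length of the carrying arm, in any common unit.
    """
    if a <= 0:
        raise ValueError("arm length must be positive")
    if d < 0 or d > a:
        raise ValueError(f"site distance d={d} outside arm [0, {a}]")
    return d * 100.0 / a


def _arm_length(karyotype: Karyotype, pair_id: int, arm: str) -> float:
    for p in karyotype.pairs:
        if p.pair_id == pair_id:
            return p.mean_short if arm == "S" else p.mean_long
    raise ValueError(f"pair {pair_id} not in karyotype")


def marker_di(marker: CytoMarker, karyotype: Karyotype) -> float:
    """di of an rDNA marker against the arm length of its karyotype pair."""
    if marker.d is None:
        raise ValueError("marker has no centromere distance d")
    return rdna_di(marker.d, _arm_length(karyotype, marker.pair_id, marker.arm or "L"))


def marker_code(marker: CytoMarker, karyotype: Karyotype | None = None) -> str:
    """Position code, e.g. ``1L-PROX (25.53%)`` or ``15 PCEN (one homologue)``.

    The code is ``<pair><arm>-<position>``; when the arm was not resolved
    the separator degrades to a space.  rDNA sites append their di value
    (two decimals, computed against the karyotype when one is supplied);
    markers seen on a single homolog append ``(one homologue)``.
    """
    if karyotype is not None and all(
        p.pair_id != marker.pair_id for p in karyotype.pairs
    ):
        raise ValueError(f"pair {marker.pair_id} not in karyotype")
    if marker.arm:
        code = f"{marker.pair_id}{marker.arm}-{marker.position_class}"
    else:
        code = f"{marker.pair_id} {marker.position_class}"
    if marker.marker_class == "rDNA_45S" and marker.d is not None and karyotype is not None:
        code += f" ({marker_di(marker, karyotype):.2f}%)"
    if marker.homologs_present == "one":
        code += " (one homologue)"
    return code


_CODE_RE = re.compile(
    r"^(?P<pair>\d+)(?:(?P<arm>[SL])-| )(?P<pos>CEN|PCEN|PROX|INT|TER)"
    r"(?: \((?P<di>[\d.]+)%\))?"
    r"(?P<one> \(one homologue\))?$"
)


def parse_marker_code(code: str, marker_class: str = "CPD_band") -> CytoMarker:
    """Inverse of marker_code (di, when present, marks an rDNA site)."""
    m = _CODE_RE.match(code.strip())
    if m is None:
        raise ValueError(f"unparseable marker code {code!r}")
    is_rdna = m.group("di") is not None or marker_class == "rDNA_45S"
    return CytoMarker(
        marker_class="rDNA_45S" if is_rdna else marker_class,
        pair_id=int(m.group("pair")),
        arm=m.group("arm"),
        position_class=m.group("pos"),
        homologs_present="one" if m.group("one") else "both",
    )


def band_amount_percent(markers: list[CytoMarker], karyotype: Karyotype) -> dict[str, float]:
    """Band amount per marker class, as % of the (diploid) karyotype length.

    Band lengths are summed over both homologs — a marker present on both
    homologs contributes its length twice (or each homolog's own length
    for heteromorphic bands) — and divided by twice the haploid complement
    length TCL, so homomorphic bands give the same percentage as the
    haploid-over-haploid ratio.
    """
    if karyotype.tcl <= 0:
        raise ValueError("karyotype TCL must be positive")
    out = {c: 0.0 for c in MARKER_CLASSES}
    for m in markers:
        if m.homologs_present == "both":
            second = m.band_len2 if m.band_len2 is not None else m.band_len
            total = m.band_len + second
        else:
            total = m.band_len
        out[m.marker_class] += total
    return {c: 100.0 * v / (2.0 * karyotype.tcl) for c, v in out.items()}


def heterozygosity_report(
    markers: list[CytoMarker], size_ratio_threshold: float = 2.0
) -> list[dict]:
    """Flag heteromorphic markers.

    A marker is heterozygous when present on a single homolog, or when the
    per-homolog band sizes differ by more than ``size_ratio_threshold``.
    """
    report = []
    for m in markers:
        flagged = False
        reason = None
        if m.homologs_present == "one":
            flagged, reason = True, "one homologue"
        elif m.band_len2 is not None and m.band_len > 0 and m.band_len2 > 0:
            ratio = max(m.band_len, m.band_len2) / min(m.band_len, m.band_len2)
            if ratio > size_ratio_threshold:
                flagged, reason = True, f"size ratio {ratio:.2f}"
        report.append(
            {"marker": m, "code": marker_code(m), "heterozygous": flagged, "reason": reason}
        )
    return report


def position_class_from_fraction(
    fraction: float, cutoffs: dict[str, float] = POSITION_CUTOFFS
) -> str:
    """Map a fractional site position to a position class.

    ``fraction`` is the distance of the site centre from the centromere as
    a fraction of the whole chromosome length (0 = centromere, arm tip at
    arm_length/chromosome_length).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be within [0, 1]")
    for cls in ("CEN", "PCEN", "PROX", "INT"):
        if fraction <= cutoffs[cls]:
            return cls
    return "TER"


def read_markers(path) -> list[CytoMarker]:
    """Read a marker table (CSV dialect in MARKER_COLUMNS)."""
    df = pd.read_csv(path)
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    markers = []
    for _, r in df.iterrows():
        markers.append(
            CytoMarker(
                marker_class=r["marker_class"],
                pair_id=int(r["pair_id"]),
                arm=None if pd.isna(r["arm"]) else r["arm"],
                position_class=r["position_class"],
                band_len=0.0 if pd.isna(r["band_len_um"]) else float(r["band_len_um"]),
                homologs_present=r["homologs_present"],
                d=None if pd.isna(r["d_um"]) else float(r["d_um"]),
                band_len2=(
                    None
                    if "band_len2_um" not in df.columns or pd.isna(r.get("band_len2_um"))
                    else float(r["band_len2_um"])
                ),
                co_localized_with_45S=bool(r.get("co_localized_with_45S", False)),
            )
        )
    return markers


def write_markers(markers: list[CytoMarker], path) -> None:
    rows = []
    for m in markers:
        d = asdict(m)
        rows.append(
            {
                "marker_class": d["marker_class"],
                "pair_id": d["pair_id"],
                "arm": d["arm"],
                "position_class": d["position_class"],
                "band_len_um": d["band_len"],
                "homologs_present": d["homologs_present"],
                "d_um": d["d"],
                "band_len2_um": d["band_len2"],
                "co_localized_with_45S": d["co_localized_with_45S"],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
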