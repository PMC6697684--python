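"""Site-classification statistics for ITS1-5.8S-ITS2 alignments.

Given a multiple alignment of the nuclear ribosomal internal transcribed
spacer region, computes the descriptive statistics conventionally reported
for this marker: per-region sequence-length and GC-content ranges, indel
events, variable and parsimony-informative sites, and transition /
transversion counts.

Conventions (all deterministic and tree-free):

* Ambiguity codes and N are excluded from both variability calls and GC
  numerators/denominators.
* A column containing any gap is labelled ``gap_containing`` and excluded
  from the variable-site and substitution counts; labels are exclusive.
* Indels are counted as events, not gap columns: a maximal run of
  consecutive gap columns sharing an identical presence/absence pattern
  across sequences counts once.
* Substitution typing is per column over the observed states: each
  unordered pair of distinct observed bases contributes one event,
  A<->G and C<->T as transitions, the rest as transversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

__all__ = [
    "SiteClassification",
    "read_alignment",
    "write_alignment",
    "gc_content",
    "classify_sites",
    "count_indels",
    "count_substitution_types",
    "region_table",
]

_BASES = frozenset("ACGT")
_GAP = "-"
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass
class SiteClassification:
    """Per-column labels and substitution events of an alignment.

    labels[i] is one of ``conserved``, ``variable_singleton``,
    ``variable_informative`` or ``gap_containing``; events[i] is the
    (transitions, transversions) pair contributed by column i.
    """

    labels: list[str]
    events: list[tuple[int, int]] = field(repr=False)

    @property
    def n_variable(self) -> int:
        return self.n_singleton + self.n_informative

    @property
    def n_singleton(self) -> int:
        return self.labels.count("variable_singleton")

    @property
    def n_informative(self) -> int:
        return self.labels.count("variable_informative")

    @property
    def n_gap_containing(self) -> int:
        return self.labels.count("gap_containing")

    @property
    def transitions(self) -> int:
        return sum(ts for ts, _ in self.events)

    @property
    def transversions(self) -> int:
        return sum(tv for _, tv in self.events)

    @property
    def ratio_string(self) -> str:
        return f"{self.transitions}:{self.transversions}"


def read_alignment(path, fmt: str = "fasta") -> MultipleSeqAlignment:
    return AlignIO.read(path, fmt)


def write_alignment(alignment: MultipleSeqAlignment, path, fmt: str = "fasta") -> None:
    AlignIO.write(alignment, path, fmt)


def _rows(alignment) -> list[str]:
    rows = [str(rec.seq).upper() for rec in alignment]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("ragged alignment: sequences differ in aligned length")
    return rows


def gc_content(sequence, region: tuple[int, int] | None = None) -> float:
    """GC content in percent: 100*(G+C)/(A+C+G+T).

    Gaps, N and ambiguity codes are excluded from the denominator.
    ``region`` restricts the computation to a half-open slice of the
    (possibly gapped) sequence.
    """
    s = str(sequence).upper()
    if region is not None:
        s = s[region[0] : region[1]]
    counts = {b: s.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("no unambiguous bases in sequence/region")
    return 100.0 * (counts["G"] + counts["C"]) / denom


def _column_events(bases: set[str]) -> tuple[int, int]:
    ts = tv = 0
    ordered = sorted(bases)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if frozenset((a, b)) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    return ts, tv


def classify_sites(
    alignment, region: tuple[int, int] | None = None
) -> SiteClassification:
    """Classify every column of (a region of) the alignment.

    A gap-free column is variable when at least two distinct unambiguous
    bases occur, and parsimony-informative when at least two distinct
    bases each occur in at least two sequences.
    """
    rows = _rows(alignment)
    if len(rows) < 2:
        raise ValueError("site classification needs at least 2 sequences")
    start, stop = region if region is not None else (0, len(rows[0]))
    labels = []
    events = []
    for col in range(start, stop):
        chars = [r[col] for r in rows]
        if _GAP in chars:
            labels.append("gap_containing")
            events.append((0, 0))
            continue
        counts: dict[str, int] = {}
        for c in chars:
            if c in _BASES:
                counts[c] = counts.get(c, 0) + 1
        if len(counts) < 2:
            labels.append("conserved")
            events.append((0, 0))
            continue
        n_ge2 = sum(1 for v in counts.values() if v >= 2)
        labels.append(
            "variable_informative" if n_ge2 >= 2 else "variable_singleton"
        )
        events.append(_column_events(set(counts)))
    return SiteClassification(labels=labels, events=events)


def count_indels(alignment, region: tuple[int, int] | None = None) -> int:
    """Number of distinct gap events in (a region of) the alignment.

    A maximal run of consecutive gap-containing columns with an identical
    gap presence/absence pattern across sequences counts as one event.
    """
    rows = _rows(alignment)
    start, stop = region if region is not None else (0, len(rows[0]))
    n = 0
    prev_pattern: frozenset[int] | None = None
    for col in range(start, stop):
        pattern = frozenset(i for i, r in enumerate(rows) if r[col] == _GAP)
        if pattern and pattern != prev_pattern:
            n += 1
        prev_pattern = pattern or None
    return n


def count_substitution_types(alignment) -> tuple[int, int, str]:
    """Total (transitions, transversions, "ts:tv") over variable columns."""
    sc = classify_sites(alignment)
    return sc.transitions, sc.transversions, sc.ratio_string


def _ungapped_length(row: str, start: int, stop: int) -> int:
    return sum(1 for c in row[start:stop] if c != _GAP)


def region_table(
    alignment, regions: dict[str, tuple[int, int]] | None = None
) -> pd.DataFrame:
    """Per-region summary table (plus a ``complete`` row).

    ``regions`` maps region names (e.g. ITS1, 5.8S, ITS2) to half-open
    column intervals on the alignment; intervals must lie within the
    alignment.  For each region the table reports the ungapped
    sequence-length range, GC-content range, indel events, variable and
    parsimony-informative sites, transitions, transversions and the ts:tv
    ratio string.
    """
    rows = _rows(alignment)
    ncol = len(rows[0])
    regions = dict(regions or {})
    for name, (a, b) in regions.items():
        if not (0 <= a < b <= ncol):
            raise ValueError(f"region {name!r} interval ({a}, {b}) outside alignment")
    regions["complete"] = (0, ncol)

    out = []
    for name, (a, b) in regions.items():
        lengths = [_ungapped_length(r, a, b) for r in rows]
        gcs = [gc_content(r, (a, b)) for r in rows]
        sc = classify_sites(alignment, (a, b))
        lo, hi = min(lengths), max(lengths)
        out.append(
            {
                "region": name,
                "length_range": str(lo) if lo == hi else f"{lo}-{hi}",
                "gc_min": min(gcs),
                "gc_max": max(gcs),
                "n_indels": count_indels(alignment, (a, b)),
                "n_variable": sc.n_variable,
                "n_informative": sc.n_informative,
                "transitions": sc.transitions,
                "transversions": sc.transversions,
                "ratio": sc.ratio_string,
            }
        )
    return pd.DataFrame(out)
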