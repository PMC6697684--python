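"""Synthetic measurement tables, marker sets and ITS alignments.

Every downstream stage of the pipeline is testable without external data:
this module generates (a) per-cell chromosome arm-length measurement
tables with a known ground truth, emulating a grass karyotype measured on
five metaphase plates (19 homolog pairs, mean chromosome length around
4 µm, centromeric-index profile around 44, one satellite pair, per-cell
condensation scaling, multiplicative measurement noise); (b) marker
annotation sets; and (c) gapped ITS1-5.8S-ITS2-like alignments whose
per-column site classes, indel events and substitution-type counts are
controlled exactly and returned in a ground-truth ledger.

Measurement noise is multiplicative Gaussian per arm, independent across
arms and cells; chromosome condensation is a single per-cell scalar
applied to all arms.  Alignment targets that cannot be realized exactly
fail loudly with the violated inequality rather than being truncated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .karyotype import MEASUREMENT_COLUMNS
from .markers import CytoMarker

__all__ = [
    "KaryotypeSpec",
    "AlignmentSpec",
    "default_karyotype_spec",
    "simulate_measurements",
    "simulate_alignment",
    "miscanthus_fixture",
    "FixtureBundle",
]

_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


# --------------------------------------------------------------------------
# karyotype measurements
# --------------------------------------------------------------------------

@dataclass
class KaryotypeSpec:
    """Ground-truth karyotype and measurement-noise model.

    ``true_short`` / ``true_long`` are per-pair arm lengths in µm, ordered
    by decreasing total length.  ``sat_pairs`` maps satellited pair ids to
    the carrying arm ("short"/"long"); the satellite segment is measured
    separately from the arms.  Each measured arm is
    true_length x cell_scale x (1 + Normal(0, noise_cv)).
    """

    true_short: np.ndarray
    true_long: np.ndarray
    sat_pairs: dict[int, str] = field(default_factory=dict)
    sat_len: float = 0.45
    n_cells: int = 5
    condensation_scales: np.ndarray | None = None
    noise_cv: float = 0.03
    seed: int = 0

    def __post_init__(self):
        self.true_short = np.asarray(self.true_short, dtype=float)
        self.true_long = np.asarray(self.true_long, dtype=float)
        if self.n_pairs < 1:
            raise ValueError("need at least one pair")
        if self.true_short.shape != self.true_long.shape:
            raise ValueError("short/long arm arrays differ in length")
        if (self.true_short <= 0).any() or (self.true_long <= 0).any():
            raise ValueError("true arm lengths must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.condensation_scales is None:
            self.condensation_scales = np.ones(self.n_cells)
        self.condensation_scales = np.asarray(self.condensation_scales, dtype=float)
        if len(self.condensation_scales) != self.n_cells:
            raise ValueError("one condensation scale per cell required")
        if (self.condensation_scales <= 0).any():
            raise ValueError("condensation scales must be positive")
        for pid, arm in self.sat_pairs.items():
            if not 1 <= pid <= self.n_pairs:
                raise ValueError(f"satellite pair {pid} out of range")
            if arm not in ("short", "long"):
                raise ValueError("satellite arm must be 'short' or 'long'")

    @property
    def n_pairs(self) -> int:
        return len(self.true_short)

    @property
    def true_totals(self) -> np.ndarray:
        return self.true_short + self.true_long


#: Default per-pair centromeric-index profile (%): 17 metacentric pairs
#: spread over 40.5-50 plus two submetacentric pairs (CI 31 and 29, i.e.
#: arm ratios ~2.2 and ~2.4) at size ranks 9 and 15.  Together with the
#: relative-length profile below this yields a 2n=38, 34m(2SAT)+4sm
#: complement with mean CI ~ 44, longest/shortest ratio ~ 2.33 and
#: Stebbins category 2B.
_DEFAULT_CI = np.array(
    [47.0, 49.0, 44.5, 50.0, 46.0, 44.0, 48.0, 45.5, 31.0,
     49.5, 45.0, 47.5, 46.5, 48.5, 29.0, 44.8, 47.8, 45.8, 46.8]
)
_SM_RANKS = (9, 15)  # 1-based size ranks of the submetacentric pairs


def default_karyotype_spec(
    tcl: float = 74.0,
    length_ratio: float = 2.33,
    noise_cv: float = 0.03,
    n_cells: int = 5,
    seed: int = 0,
) -> KaryotypeSpec:
    """The packaged 19-pair grass-like karyotype (see module docstring)."""
    n = 19
    raw = np.linspace(length_ratio, 1.0, n)
    totals = tcl * raw / raw.sum()
    short = totals * _DEFAULT_CI / 100.0
    long = totals - short
    return KaryotypeSpec(
        true_short=short,
        true_long=long,
        sat_pairs={1: "long"},
        sat_len=0.45,
        n_cells=n_cells,
        condensation_scales=np.linspace(0.94, 1.06, n_cells) if noise_cv > 0 else None,
        noise_cv=noise_cv,
        seed=seed,
    )


def _noisy(value: float, scale: float, cv: float, rng: np.random.Generator) -> float:
    if cv == 0:
        return value * scale
    for _ in range(100):
        x = value * scale * (1.0 + rng.normal(0.0, cv))
        if x > 0:
            return x
    raise RuntimeError("could not sample a positive length in 100 tries")


def simulate_measurements(spec: KaryotypeSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a per-cell measurement table plus its ground-truth ledger.

    Returns ``(measurements, ledger)``: n_cells x 2 n_pairs rows in the
    standard CSV dialect, and the true per-pair RL/AR/CI/total values the
    downstream pipeline should recover at zero noise.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for c in range(spec.n_cells):
        scale = float(spec.condensation_scales[c])
        for pid in range(1, spec.n_pairs + 1):
            ts, tl = spec.true_short[pid - 1], spec.true_long[pid - 1]
            for hom in (1, 2):
                sat_arm = spec.sat_pairs.get(pid, "none")
                sat = (
                    _noisy(spec.sat_len, scale, spec.noise_cv, rng)
                    if sat_arm != "none"
                    else 0.0
                )
                rows.append(
                    {
                        "cell_id": f"cell{c + 1}",
                        "pair_id": pid,
                        "homolog": hom,
                        "short_arm_um": _noisy(ts, scale, spec.noise_cv, rng),
                        "long_arm_um": _noisy(tl, scale, spec.noise_cv, rng),
                        "satellite_um": sat,
                        "satellite_arm": sat_arm,
                    }
                )
    totals = spec.true_totals
    ledger = {
        "tcl": float(totals.sum()),
        "pairs": [
            {
                "pair_id": pid,
                "true_short": float(spec.true_short[pid - 1]),
                "true_long": float(spec.true_long[pid - 1]),
                "true_total": float(totals[pid - 1]),
                "rl": float(100.0 * totals[pid - 1] / totals.sum()),
                "ar": float(spec.true_long[pid - 1] / spec.true_short[pid - 1]),
                "ci": float(100.0 * spec.true_short[pid - 1] / totals[pid - 1]),
                "sat": pid in spec.sat_pairs,
            }
            for pid in range(1, spec.n_pairs + 1)
        ],
    }
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS), ledger


# --------------------------------------------------------------------------
# alignments
# --------------------------------------------------------------------------

@dataclass
class AlignmentSpec:
    """Targets for a gapped alignment with exactly known site statistics.

    ``group_labels`` maps taxon name -> group name (input order of the
    dict is the taxon order).  Parsimony-informative columns give a
    derived base to every member of one group (groups cycle); singleton
    columns give a derived base to one taxon (taxa cycle in input order).
    Every variable column carries exactly two observed states, so the
    transition/transversion targets must sum to ``n_variable``.
    """

    length: int
    group_labels: dict[str, str]
    n_variable: int = 0
    n_informative: int = 0
    n_indel_events: int = 0
    ts_tv_targets: tuple[int, int] = (0, 0)
    gc_target: float = 0.5
    max_indel_len: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if not (0 <= self.n_informative <= self.n_variable <= self.length):
            raise ValueError(
                "targets must satisfy 0 <= n_informative <= n_variable <= length; "
                f"got {self.n_informative}, {self.n_variable}, {self.length}"
            )
        ts, tv = self.ts_tv_targets
        if ts < 0 or tv < 0 or self.n_indel_events < 0:
            raise ValueError("counts must be non-negative")
        if ts + tv != self.n_variable:
            raise ValueError(
                "ts_tv_targets must sum to n_variable (every variable column "
                f"carries exactly two observed states): {ts}+{tv} != {self.n_variable}"
            )
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be in (0, 1)")
        if self.n_informative > 0 and not self._informative_groups():
            raise ValueError(
                "n_informative > 0 requires a group with >= 2 members and "
                ">= 2 taxa outside it"
            )
        # room for variable columns plus gap events with 1-column spacers
        need = self.n_variable + self.n_indel_events * (self.max_indel_len + 1)
        if need > self.length:
            raise ValueError(
                f"targets need up to {need} columns but length is {self.length}"
            )

    @property
    def taxa(self) -> list[str]:
        return list(self.group_labels)

    @property
    def n_taxa(self) -> int:
        return len(self.group_labels)

    def _informative_groups(self) -> list[str]:
        sizes: dict[str, int] = {}
        for g in self.group_labels.values():
            sizes[g] = sizes.get(g, 0) + 1
        return [
            g
            for g, s in sorted(sizes.items())
            if s >= 2 and self.n_taxa - s >= 2
        ]


def _place_gap_events(
    spec: AlignmentSpec, variable_cols: set[int], rng: np.random.Generator
) -> list[tuple[int, int, list[int]]]:
    """Choose (start, length, taxon indices) for each gap event.

    Events avoid variable columns, never overlap, and keep at least one
    gap-free column between events so each is a distinct maximal run.
    """
    events = []
    blocked = set(variable_cols)
    pool: list[int] = []
    taxa_idx = list(range(spec.n_taxa))
    for _ in range(spec.n_indel_events):
        k = int(rng.integers(1, min(3, spec.n_taxa - 1) + 1))
        if len(pool) < k:
            pool = taxa_idx.copy()
            rng.shuffle(pool)
        members = [pool.pop() for _ in range(k)]
        glen = int(rng.integers(1, spec.max_indel_len + 1))
        for _ in range(1000):
            start = int(rng.integers(0, spec.length - glen + 1))
            span = set(range(start - 1, start + glen + 1))  # + flanking spacer
            if span.isdisjoint(blocked):
                blocked |= span
                events.append((start, glen, sorted(members)))
                break
        else:
            raise RuntimeError("could not place gap events; alignment too crowded")
    return events


def simulate_alignment(spec: AlignmentSpec) -> tuple[MultipleSeqAlignment, dict]:
    """Generate a gapped alignment whose realized statistics equal the
    spec's targets exactly; returns ``(alignment, ledger)``.

    The ledger records the per-column class of every column, the derived
    and ancestral base of each variable column, each gap event's columns
    and taxa, the substitution-type totals, and the realized per-sequence
    GC contents.
    """
    rng = np.random.default_rng(spec.seed)
    taxa = spec.taxa
    # exact base composition realizing gc_target (up to rounding), shuffled
    n_gc = round(spec.gc_target * spec.length)
    n_g = n_gc // 2
    n_a = (spec.length - n_gc) // 2
    root = np.array(
        ["G"] * n_g + ["C"] * (n_gc - n_g)
        + ["A"] * n_a + ["T"] * (spec.length - n_gc - n_a)
    )
    rng.shuffle(root)

    var_cols = sorted(
        int(c) for c in rng.choice(spec.length, size=spec.n_variable, replace=False)
    )
    order = list(var_cols)
    rng.shuffle(order)
    informative_cols = sorted(order[: spec.n_informative])
    singleton_cols = sorted(order[spec.n_informative :])
    ts_cols = set(
        int(c) for c in rng.choice(var_cols, size=spec.ts_tv_targets[0], replace=False)
    ) if spec.n_variable else set()

    groups = spec._informative_groups()
    members_of = {
        g: [i for i, t in enumerate(taxa) if spec.group_labels[t] == g]
        for g in set(spec.group_labels.values())
    }

    matrix = np.tile(root, (spec.n_taxa, 1))
    column_info = []
    for k, col in enumerate(informative_cols):
        g = groups[k % len(groups)]
        carriers = members_of[g]
        anc = root[col]
        der = _TS_PARTNER[anc] if col in ts_cols else str(rng.choice(_TV_PARTNERS[anc]))
        matrix[carriers, col] = der
        column_info.append(
            {
                "col": col,
                "class": "variable_informative",
                "ancestral": str(anc),
                "derived": der,
                "carriers": [taxa[i] for i in carriers],
                "event": "transition" if col in ts_cols else "transversion",
            }
        )
    for k, col in enumerate(singleton_cols):
        carrier = k % spec.n_taxa
        anc = root[col]
        der = _TS_PARTNER[anc] if col in ts_cols else str(rng.choice(_TV_PARTNERS[anc]))
        matrix[carrier, col] = der
        column_info.append(
            {
                "col": col,
                "class": "variable_singleton",
                "ancestral": str(anc),
                "derived": der,
                "carriers": [taxa[carrier]],
                "event": "transition" if col in ts_cols else "transversion",
            }
        )

    gap_events = _place_gap_events(spec, set(var_cols), rng)
    for start, glen, members in gap_events:
        for i in members:
            matrix[i, start : start + glen] = "-"

    records = [
        SeqRecord(Seq("".join(matrix[i])), id=t, description="")
        for i, t in enumerate(taxa)
    ]
    alignment = MultipleSeqAlignment(records)

    labels = ["conserved"] * spec.length
    for info in column_info:
        labels[info["col"]] = info["class"]
    for start, glen, _ in gap_events:
        for col in range(start, start + glen):
            labels[col] = "gap_containing"

    gc = {}
    for rec in records:
        s = str(rec.seq)
        acgt = sum(s.count(b) for b in "ACGT")
        gc[rec.id] = 100.0 * (s.count("G") + s.count("C")) / acgt

    ledger = {
        "taxa": taxa,
        "group_labels": dict(spec.group_labels),
        "length": spec.length,
        "labels": labels,
        "columns": sorted(column_info, key=lambda d: d["col"]),
        "n_variable": spec.n_variable,
        "n_informative": spec.n_informative,
        "n_singleton": spec.n_variable - spec.n_informative,
        "transitions": spec.ts_tv_targets[0],
        "transversions": spec.ts_tv_targets[1],
        "ratio": f"{spec.ts_tv_targets[0]}:{spec.ts_tv_targets[1]}",
        "n_indel_events": len(gap_events),
        "gap_events": [
            {"start": s, "length": l, "taxa": [taxa[i] for i in m]}
            for s, l, m in gap_events
        ],
        "gc_percent": gc,
    }
    return alignment, ledger


def concatenate_alignments(
    parts: list[MultipleSeqAlignment],
) -> MultipleSeqAlignment:
    """Column-wise concatenation of alignments over the same taxa order."""
    ids = [rec.id for rec in parts[0]]
    for p in parts[1:]:
        if [rec.id for rec in p] != ids:
            raise ValueError("alignments list different taxa")
    records = []
    for i, t in enumerate(ids):
        seq = "".join(str(p[i].seq) for p in parts)
        records.append(SeqRecord(Seq(seq), id=t, description=""))
    return MultipleSeqAlignment(records)


# --------------------------------------------------------------------------
# packaged deterministic fixture
# --------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """Deterministic packaged dataset used by the test suite and docs."""

    measurements: pd.DataFrame
    karyotype_ledger: dict
    markers: list[CytoMarker]
    alignment: MultipleSeqAlignment
    alignment_ledger: dict
    regions: dict[str, tuple[int, int]]
    outgroup: str

    def write(self, out_dir) -> None:
        """Serialize the bundle (CSV / FASTA / JSON) into a directory."""
        import pathlib

        from .its import write_alignment
        from .karyotype import write_measurements
        from .markers import write_markers

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_measurements(self.measurements, out / "measurements.csv")
        write_markers(self.markers, out / "markers.csv")
        write_alignment(self.alignment, out / "alignment.fasta")
        with open(out / "ledgers.json", "w") as fh:
            json.dump(
                {
                    "karyotype": self.karyotype_ledger,
                    "alignment": self.alignment_ledger,
                    "regions": self.regions,
                    "outgroup": self.outgroup,
                },
                fh,
                indent=2,
            )


_FIXTURE_SEED = 1729

#: Taxon sampling of the fixture: four ingroup species x six accessions
#: falling into two groups, plus one outgroup taxon listed first.
_FIXTURE_SPECIES = {
    "Msin": "groupI",   # M. sinensis-like
    "Mflo": "groupI",   # M. floridulus-like
    "Msac": "groupII",  # M. sacchariflorus-like
    "Mlut": "groupII",  # M. lutarioriparius-like
}
_FIXTURE_OUTGROUP = "Icyl01"


def _fixture_group_labels() -> dict[str, str]:
    labels = {_FIXTURE_OUTGROUP: "outgroup"}
    for sp, grp in _FIXTURE_SPECIES.items():
        for a in range(1, 7):
            labels[f"{sp}{a:02d}"] = grp
    return labels


def miscanthus_fixture(noise_cv: float = 0.03, seed: int = _FIXTURE_SEED) -> FixtureBundle:
    """The packaged fixture: measurements + markers + ITS-like alignment.

    The karyotype side is the default 19-pair spec measured in 5 cells;
    the marker set mirrors a typical fluorochrome/rDNA annotation (one
    45S rDNA pair proximally on the long arm of pair 1, co-localized CPD
    band, a handful of DAPI bands including a heteromorphic one); the
    alignment is a 661-column ITS1(260) + 5.8S(157) + ITS2(244)
    concatenation over 24 ingroup accessions in two groups plus an
    outgroup, with region-wise site statistics controlled exactly.
    """
    kspec = default_karyotype_spec(noise_cv=noise_cv, seed=seed)
    measurements, kledger = simulate_measurements(kspec)

    tcl = kledger["tcl"]
    pair1 = kledger["pairs"][0]
    arm1_long = pair1["true_long"]
    markers = [
        CytoMarker(
            "rDNA_45S", 1, "L", "PROX",
            band_len=0.0093 * tcl, d=0.2553 * arm1_long,
            co_localized_with_45S=True,
        ),
        CytoMarker(
            "CPD_band", 1, "L", "PROX",
            band_len=0.0093 * tcl, d=0.2553 * arm1_long,
            co_localized_with_45S=True,
        ),
        CytoMarker("DAPI_band", 10, "S", "CEN", band_len=0.40),
        CytoMarker("DAPI_band", 12, "L", "PCEN", band_len=0.40),
        CytoMarker("DAPI_band", 19, "S", "CEN", band_len=0.45),
        CytoMarker(
            "DAPI_band", 19, "L", "PROX", band_len=0.45, homologs_present="one"
        ),
    ]

    groups = _fixture_group_labels()
    its1 = AlignmentSpec(
        length=260, group_labels=groups, n_variable=5, n_informative=3,
        n_indel_events=2, ts_tv_targets=(2, 3), gc_target=0.675,
        seed=seed + 1,
    )
    r58s = AlignmentSpec(
        length=157, group_labels=groups, n_variable=1, n_informative=0,
        n_indel_events=0, ts_tv_targets=(0, 1), gc_target=0.56,
        seed=seed + 2,
    )
    its2 = AlignmentSpec(
        length=244, group_labels=groups, n_variable=7, n_informative=5,
        n_indel_events=1, ts_tv_targets=(1, 6), gc_target=0.61,
        seed=seed + 3,
    )
    parts, ledgers = [], []
    for s in (its1, r58s, its2):
        aln, led = simulate_alignment(s)
        parts.append(aln)
        ledgers.append(led)
    alignment = concatenate_alignments(parts)

    offsets = [0, 260, 417, 661]
    regions = {
        "ITS1": (offsets[0], offsets[1]),
        "5.8S": (offsets[1], offsets[2]),
        "ITS2": (offsets[2], offsets[3]),
    }
    combined = {
        "taxa": ledgers[0]["taxa"],
        "group_labels": groups,
        "length": sum(l["length"] for l in ledgers),
        "regions": {
            name: led for name, led in zip(("ITS1", "5.8S", "ITS2"), ledgers)
        },
        "n_variable": sum(l["n_variable"] for l in ledgers),
        "n_informative": sum(l["n_informative"] for l in ledgers),
        "transitions": sum(l["transitions"] for l in ledgers),
        "transversions": sum(l["transversions"] for l in ledgers),
        "n_indel_events": sum(l["n_indel_events"] for l in ledgers),
        "labels": sum((l["labels"] for l in ledgers), []),
    }
    combined["ratio"] = f"{combined['transitions']}:{combined['transversions']}"

    return FixtureBundle(
        measurements=measurements,
        karyotype_ledger=kledger,
        markers=markers,
        alignment=alignment,
        alignment_ledger=combined,
        regions=regions,
        outgroup=_FIXTURE_OUTGROUP,
    )
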