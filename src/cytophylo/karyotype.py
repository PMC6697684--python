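"""Homolog-pair aggregation and chromosome-level karyotype descriptors.

A karyotype is built from per-cell arm-length measurements of every
chromosome in a diploid complement.  Measurements are aggregated over
metaphase cells and homologs into homolog-pair means, from which the
classical descriptors are computed: relative length (RL, % of the haploid
complement), arm ratio (AR = long/short), centromeric index
(CI = 100·short/total), the Levan centromere-position class, the karyotype
formula string and the total haploid complement length (TCL).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "MEASUREMENT_COLUMNS",
    "KaryotypePair",
    "Karyotype",
    "read_measurements",
    "write_measurements",
    "normalize_orientation",
    "aggregate_pairs",
    "arm_ratio",
    "centromeric_index",
    "classify_levan",
    "karyotype_formula",
    "length_ratio",
]

#: Canonical column order of the measurement-table CSV dialect.
MEASUREMENT_COLUMNS = [
    "cell_id",
    "pair_id",
    "homolog",
    "short_arm_um",
    "long_arm_um",
    "satellite_um",
    "satellite_arm",
]

#: Levan (1964) arm-ratio intervals; boundary values belong to the more
#: symmetric (left) class.  AR exactly 1.0 (Levan's median point "M") is
#: folded into "m".
LEVAN_BOUNDS = {"m": 1.7, "sm": 3.0, "st": 7.0}
LEVAN_ORDER = ("m", "sm", "st", "t")


@dataclass
class KaryotypePair:
    """Aggregated homolog pair: arm means and derived descriptors."""

    pair_id: int
    mean_short: float
    mean_long: float
    rl: float  # relative length, % of haploid complement
    ar: float  # arm ratio, long/short (>= 1)
    ci: float  # centromeric index, 100*short/total
    levan_type: str
    sat: bool = False
    sat_arm: str = "none"  # {"short", "long", "none"}
    sat_len: float = 0.0
    source_pair_id: int | None = None  # id before length-rank renumbering

    @property
    def total_len(self) -> float:
        return self.mean_short + self.mean_long


@dataclass
class Karyotype:
    """Ordered diploid karyotype: pairs ranked by decreasing length."""

    species_label: str
    pairs: list[KaryotypePair]
    tcl: float  # total haploid complement length, µm
    tcl_sd: float  # SD of the per-cell haploid lengths used for TCL
    #: per-chromosome (pair, homolog) arm means of the "mean cell";
    #: columns pair_id, homolog, mean_short, mean_long
    chromosomes: pd.DataFrame = field(repr=False, default=None)

    @property
    def two_n(self) -> int:
        return 2 * len(self.pairs)

    @property
    def formula(self) -> str:
        return karyotype_formula(self)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            d = asdict(p)
            d["total_len"] = p.total_len
            rows.append(d)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "species_label": self.species_label,
            "two_n": self.two_n,
            "tcl": self.tcl,
            "tcl_sd": self.tcl_sd,
            "formula": self.formula,
            "pairs": [dict(asdict(p), total_len=p.total_len) for p in self.pairs],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement table (CSV, the dialect in MEASUREMENT_COLUMNS)."""
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    df["satellite_arm"] = df["satellite_arm"].fillna("none")
    return df


def write_measurements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=MEASUREMENT_COLUMNS)


def normalize_orientation(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy in which long_arm >= short_arm for every chromosome.

    Rows whose measured "short" arm exceeds the "long" arm have the arms
    swapped; a satellite annotation attached to a swapped arm follows it.
    """
    out = df.copy()
    flip = out["short_arm_um"] > out["long_arm_um"]
    if flip.any():
        s = out.loc[flip, "short_arm_um"].copy()
        out.loc[flip, "short_arm_um"] = out.loc[flip, "long_arm_um"]
        out.loc[flip, "long_arm_um"] = s
        swap = {"short": "long", "long": "short"}
        out.loc[flip, "satellite_arm"] = out.loc[flip, "satellite_arm"].map(
            lambda a: swap.get(a, a)
        )
    return out


def arm_ratio(short: float, long: float) -> float:
    """Arm ratio AR = long/short (orientation-normalized, so AR >= 1)."""
    if short <= 0:
        raise ValueError(f"short arm must be positive, got {short}")
    return long / short


def centromeric_index(short: float, long: float) -> float:
    """Centromeric index CI = 100 * short / (short + long), in percent."""
    if short <= 0 or long <= 0:
        raise ValueError("arm lengths must be positive")
    return 100.0 * short / (short + long)


def classify_levan(ar: float) -> str:
    """Classify centromere position from the arm ratio.

    m (metacentric) for AR in [1, 1.7], sm (submetacentric) for (1.7, 3],
    st (subtelocentric) for (3, 7], t (telocentric) above 7.  Boundary
    values belong to the more symmetric class.
    """
    if ar < 1.0:
        raise ValueError(
            f"arm ratio {ar} < 1: arms not orientation-normalized upstream"
        )
    for typ in ("m", "sm", "st"):
        if ar <= LEVAN_BOUNDS[typ]:
            return typ
    return "t"


def _validate_measurements(df: pd.DataFrame) -> None:
    if df.empty:
        raise ValueError("empty measurement table")
    bad = df[(df["short_arm_um"] <= 0) | (df["long_arm_um"] <= 0)]
    if not bad.empty:
        rows = bad[["cell_id", "pair_id", "homolog"]].values.tolist()
        raise ValueError(f"non-positive arm length in rows (cell, pair, homolog): {rows}")
    # every pair must have both homologs in every cell
    missing = []
    counts = df.groupby(["cell_id", "pair_id"])["homolog"].apply(set)
    for (cell, pair), homs in counts.items():
        if homs != {1, 2}:
            missing.append((cell, pair))
    if missing:
        raise ValueError(f"missing homolog for (cell, pair): {sorted(missing)}")


def aggregate_pairs(
    measurements: pd.DataFrame,
    n_cells_for_tcl: int = 5,
    species_label: str = "",
) -> Karyotype:
    """Aggregate per-cell measurements into an ordered Karyotype.

    Pair arm means are taken over all cells and both homologs.  TCL is the
    mean haploid complement length over the ``n_cells_for_tcl`` most
    condensed cells, operationalized as the cells with the smallest summed
    chromosome length (higher condensation = shorter chromosomes).  Pairs
    are re-ordered by decreasing mean total length (ties: lower AR, then
    original pair id) and renumbered 1..n.

    Satellite segments are excluded from arm lengths (they enter the table
    as their own column) and are carried through as annotations.
    """
    df = measurements.copy()
    df["satellite_um"] = df.get("satellite_um", 0.0)
    df["satellite_um"] = df["satellite_um"].fillna(0.0)
    df["satellite_arm"] = df.get("satellite_arm", "none")
    df["satellite_arm"] = df["satellite_arm"].fillna("none")
    _validate_measurements(df)
    df = normalize_orientation(df)

    # per-chromosome (pair, homolog) means over cells -> the "mean cell"
    chrom = (
        df.groupby(["pair_id", "homolog"])[["short_arm_um", "long_arm_um"]]
        .mean()
        .rename(columns={"short_arm_um": "mean_short", "long_arm_um": "mean_long"})
        .reset_index()
    )

    pairs = []
    total_sum = 0.0
    for pid, grp in df.groupby("pair_id"):
        ms = grp["short_arm_um"].mean()
        ml = grp["long_arm_um"].mean()
        sat_rows = grp[grp["satellite_um"] > 0]
        sat = not sat_rows.empty
        sat_arm = "none"
        sat_len = 0.0
        if sat:
            sat_arm = sat_rows["satellite_arm"].mode().iloc[0]
            sat_len = float(sat_rows["satellite_um"].mean())
        ar = arm_ratio(ms, ml)
        pairs.append(
            KaryotypePair(
                pair_id=int(pid),
                mean_short=ms,
                mean_long=ml,
                rl=np.nan,
                ar=ar,
                ci=centromeric_index(ms, ml),
                levan_type=classify_levan(ar),
                sat=sat,
                sat_arm=sat_arm,
                sat_len=sat_len,
                source_pair_id=int(pid),
            )
        )
        total_sum += ms + ml

    for p in pairs:
        p.rl = 100.0 * p.total_len / total_sum

    # decreasing length; ties: lower AR first, then original pair id
    pairs.sort(key=lambda p: (-p.total_len, p.ar, p.source_pair_id))
    renumber = {}
    for i, p in enumerate(pairs, start=1):
        renumber[p.source_pair_id] = i
        p.pair_id = i
    chrom["pair_id"] = chrom["pair_id"].map(renumber)
    chrom = chrom.sort_values(["pair_id", "homolog"]).reset_index(drop=True)

    # TCL over the most condensed (shortest-complement) cells
    per_cell = df.groupby("cell_id").apply(
        lambda g: (g["short_arm_um"] + g["long_arm_um"]).sum() / 2.0,
        include_groups=False,
    )
    n_sel = min(int(n_cells_for_tcl), len(per_cell))
    if n_sel < 1:
        raise ValueError("n_cells_for_tcl must be >= 1")
    selected = per_cell.sort_values().iloc[:n_sel]
    tcl = float(selected.mean())
    tcl_sd = float(selected.std(ddof=1)) if n_sel > 1 else 0.0

    return Karyotype(
        species_label=species_label,
        pairs=pairs,
        tcl=tcl,
        tcl_sd=tcl_sd,
        chromosomes=chrom,
    )


def karyotype_formula(karyotype: Karyotype) -> str:
    """Karyotype formula string, e.g. ``2n=2x=38=34m(2SAT)+4sm``.

    Chromosome counts (two per pair) are listed per Levan type in the
    order m, sm, st, t; a ``(2kSAT)`` tag follows the count of any type
    containing k satellite pairs.
    """
    counts = {t: 0 for t in LEVAN_ORDER}
    sats = {t: 0 for t in LEVAN_ORDER}
    for p in karyotype.pairs:
        counts[p.levan_type] += 2
        if p.sat:
            sats[p.levan_type] += 2
    parts = []
    for t in LEVAN_ORDER:
        if counts[t] == 0:
            continue
        part = f"{counts[t]}{t}"
        if sats[t]:
            part += f"({sats[t]}SAT)"
        parts.append(part)
    return f"2n=2x={karyotype.two_n}=" + "+".join(parts)


def length_ratio(karyotype: Karyotype) -> float:
    """Longest / shortest pair mean length (scale-invariant)."""
    if len(karyotype.pairs) < 2:
        raise ValueError("length ratio needs at least two pairs")
    totals = [p.total_len for p in karyotype.pairs]
    return max(totals) / min(totals)
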