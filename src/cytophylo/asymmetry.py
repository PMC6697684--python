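"""Complement-level karyotype asymmetry statistics.

Implements the classical indices used to place a karyotype on the
symmetric-to-asymmetric spectrum:

* Romero-Zarco intrachromosomal index  A1 = 1 - mean(short/long) over pairs
* Romero-Zarco interchromosomal index  A2 = s / mean of pair lengths (CV)
* Arano's As K% = 100 * (sum of long arms) / (total complement length)
* Paszko's AI = (CV of pair lengths x CV of pair centromeric indices) / 100
* Stebbins two-way category (length ratio letter x arm-ratio-proportion digit)

Sample (n-1) standard deviations are used throughout, the small-n
karyotype convention.  CI mean/SD are reported over the 2n individual
chromosomes of the mean cell, matching the "CI ± SD" presentation style.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .karyotype import Karyotype, centromeric_index, length_ratio

__all__ = [
    "KaryotypeIndices",
    "a1_intra",
    "a2_inter",
    "as_k_percent",
    "paszko_ai",
    "stebbins_category",
    "karyotype_indices",
]


@dataclass
class KaryotypeIndices:
    """One species' row of complement-level statistics."""

    tcl: float
    tcl_sd: float
    ci_mean: float
    ci_sd: float
    a1: float
    a2: float
    as_k: float
    ai: float
    cv_cl: float
    cv_ci: float
    stebbins: str
    rrl_min: float
    rrl_max: float

    def to_dict(self) -> dict:
        return asdict(self)


def a1_intra(karyotype: Karyotype) -> float:
    """Intrachromosomal asymmetry A1 = 1 - (sum b_i/B_i)/n over pair means."""
    ratios = [p.mean_short / p.mean_long for p in karyotype.pairs]
    return 1.0 - float(np.mean(ratios))


def a2_inter(karyotype: Karyotype) -> float:
    """Interchromosomal asymmetry A2: CV (as a ratio) of pair total lengths."""
    if len(karyotype.pairs) < 2:
        raise ValueError("A2 needs at least two pairs")
    totals = np.array([p.total_len for p in karyotype.pairs])
    return float(totals.std(ddof=1) / totals.mean())


def as_k_percent(karyotype: Karyotype) -> float:
    """As K% = 100 * sum of long arms / total complement length."""
    long_sum = sum(p.mean_long for p in karyotype.pairs)
    total = sum(p.total_len for p in karyotype.pairs)
    return 100.0 * long_sum / total


def _cv_percent(values: np.ndarray) -> float:
    return 100.0 * float(values.std(ddof=1) / values.mean())


def paszko_ai(karyotype: Karyotype) -> float:
    """Paszko's AI = (CV of pair lengths * CV of pair CIs) / 100."""
    if len(karyotype.pairs) < 2:
        raise ValueError("AI needs at least two pairs")
    totals = np.array([p.total_len for p in karyotype.pairs])
    cis = np.array([p.ci for p in karyotype.pairs])
    return _cv_percent(totals) * _cv_percent(cis) / 100.0


def stebbins_category(karyotype: Karyotype) -> str:
    """Stebbins two-way category, e.g. ``2B``.

    Letter from the longest/shortest pair-length ratio (A < 2, B in [2, 4],
    C > 4); digit from the proportion p of chromosomes with AR > 2
    (1: p = 0; 2: 0 < p <= 0.5; 3: 0.5 < p < 1; 4: p = 1).  The proportion
    is taken over the 2n individual chromosomes of the mean cell.
    """
    ratio = length_ratio(karyotype)
    letter = "A" if ratio < 2.0 else ("B" if ratio <= 4.0 else "C")
    chrom = karyotype.chromosomes
    ars = chrom["mean_long"] / chrom["mean_short"]
    p = float((ars > 2.0).mean())
    if p == 0.0:
        digit = "1"
    elif p <= 0.5:
        digit = "2"
    elif p < 1.0:
        digit = "3"
    else:
        digit = "4"
    return digit + letter


def karyotype_indices(karyotype: Karyotype) -> KaryotypeIndices:
    """Compute the full complement-level statistics row for one karyotype."""
    chrom = karyotype.chromosomes
    chrom_cis = np.array(
        [
            centromeric_index(s, l)
            for s, l in zip(chrom["mean_short"], chrom["mean_long"])
        ]
    )
    totals = np.array([p.total_len for p in karyotype.pairs])
    rls = np.array([p.rl for p in karyotype.pairs])
    cis = np.array([p.ci for p in karyotype.pairs])
    return KaryotypeIndices(
        tcl=karyotype.tcl,
        tcl_sd=karyotype.tcl_sd,
        ci_mean=float(chrom_cis.mean()),
        ci_sd=float(chrom_cis.std(ddof=1)) if len(chrom_cis) > 1 else 0.0,
        a1=a1_intra(karyotype),
        a2=a2_inter(karyotype),
        as_k=as_k_percent(karyotype),
        ai=paszko_ai(karyotype),
        cv_cl=_cv_percent(totals),
        cv_ci=_cv_percent(cis),
        stebbins=stebbins_category(karyotype),
        rrl_min=float(rls.min()),
        rrl_max=float(rls.max()),
    )
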