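# Methods

## Scope and model

`cytophylo` implements the quantitative half of a molecular-cytogenetic
species characterization: (1) karyotype analysis from per-cell chromosome
arm-length measurements, (2) bookkeeping and statistics for fluorochrome
bands and 45S rDNA FISH sites, with idiogram rendering, and (3) descriptive
statistics and distance-based phylogenetics for ITS1-5.8S-ITS2 alignments.
Wet-lab steps (slide preparation, staining, probe labelling, hybridization,
PCR) and image processing are outside the package: the inputs are the
*measurements* such work produces — arm lengths in µm, marker annotations,
aligned sequences.

## Karyotype analysis

A measurement table holds one row per chromosome per metaphase cell
(`cell_id, pair_id, homolog, short_arm_um, long_arm_um, satellite_um,
satellite_arm`). Orientation is normalized first (the longer measured arm
is the long arm, so AR ≥ 1 by construction; a satellite annotation follows
a flipped arm). Pair statistics are arithmetic means over all cells and
both homologs. Derived descriptors:

* relative length RL = 100·(pair total)/(haploid complement total), so
  Σ RL = 100 exactly;
* arm ratio AR = long/short; centromeric index CI = 100·short/total;
* Levan centromere classes from AR: m ∈ [1, 1.7], sm ∈ (1.7, 3],
  st ∈ (3, 7], t > 7, with boundary values assigned to the more symmetric
  class and Levan's AR = 1 median point folded into m;
* karyotype formula: chromosome counts (2 per pair) per class in the order
  m, sm, st, t, with a `(2kSAT)` tag on the class containing k satellite
  pairs, e.g. `2n=2x=38=34m(2SAT)+4sm`;
* TCL (total haploid complement length): the mean haploid length over the
  n (default 5) most condensed cells. "Most condensed" is operationalized
  as the cells with the smallest summed chromosome length, since stronger
  condensation shortens chromosomes; the selection rule is a package
  choice, as is reporting TCL ± SD over the selected cells.

Satellite segments are *excluded* from arm lengths for RL/AR/CI and carried
as annotations. Whether published karyotype tables include them is rarely
stated; excluding them treats the secondary constriction and satellite as a
marker, which matches how the sites are listed in marker tables, and keeps
the descriptors insensitive to satellite measurement error.

Pairs are renumbered by decreasing mean total length, ties broken by lower
AR and then by input pair id, making the numbering deterministic.

## Asymmetry indices

All complement-level indices use sample (n−1) standard deviations — the
small-n convention — so exact-match tests are well defined:

* A1 (intrachromosomal) = 1 − (Σ bᵢ/Bᵢ)/n over homolog-pair means
  (b short, B long arm);
* A2 (interchromosomal) = s/x̄ of pair total lengths;
* As K% = 100·Σ long arms / Σ total — the long-arm share of the complement;
* AI = (CV of pair lengths × CV of pair CIs)/100, CVs in percent;
* Stebbins category: letter from the longest/shortest pair ratio (A < 2,
  B ∈ [2, 4], C > 4 — boundary ratios fall in B) and digit from the
  proportion p of chromosomes with AR strictly greater than 2 (1: p = 0;
  2: 0 < p ≤ 0.5; 3: 0.5 < p < 1; 4: p = 1). Both boundary conventions
  (closed lower categories, strict exceedance of the 2:1 ratio) are
  deterministic package choices.

CI mean ± SD is reported over the 2n individual chromosomes of the "mean
cell" (per-chromosome means over cells), matching the CI ± SD presentation
style of karyotype tables; because the complement mean CI is a mean of
ratios while As K% is a ratio of sums, CI_mean + As K% ≈ 100 only to about
one unit, which the tests check as an interval, not an identity.

## Markers

Marker codes follow the `<pair><arm>-<position>` convention
(`1L-PROX (25.53%)`, `19S-PCEN`, `15 PCEN (one homologue)`): position
classes CEN/PCEN/PROX/INT/TER are declared by the annotator; an optional
helper maps the fractional distance of a site centre from the centromere
(as a fraction of the whole chromosome) to a class with configurable
cutoffs 0.05/0.15/0.40/0.85. For rDNA sites the di statistic is
d × 100/a (d = distance of the site centre from the centromere, a = length
of the carrying arm), dimensionless in [0, 100].

Band amounts are expressed as a percentage of the karyotype length. Since
TCL is haploid while heteromorphic bands differ between homologs, the
package sums band lengths over both homologs (each homolog's own length
when two are annotated; a single length for a one-homolog band) and divides
by 2·TCL. A homomorphic band therefore gives the same percentage as the
haploid/haploid ratio. Heterozygosity is flagged for one-homolog markers
and for per-homolog size ratios above a configurable threshold (default 2).

## ITS site statistics

Conventions (all tree-free and deterministic, in the style of standard
sequence-analysis software): ambiguity codes and N are ignored both for
variability and in GC numerator/denominator; a column containing any gap
is labelled `gap_containing` and excluded from the variable/informative
counts (labels are exclusive); a column is variable when ≥ 2 distinct
unambiguous bases occur and parsimony-informative when ≥ 2 bases each occur
in ≥ 2 sequences. Indels are counted as events: a maximal run of gap
columns with an identical presence/absence pattern counts once.
Substitution typing is per column over the observed states — one event per
unordered pair of distinct observed bases, A↔G and C↔T as transitions —
rather than along a tree; with the generator's two-state columns the two
definitions coincide. Region tables (ITS1/5.8S/ITS2/complete) report
ungapped length ranges, GC ranges and the per-region counts; regions are
half-open column intervals on the alignment.

## Phylogenetics

Distances: p-distance and Kimura two-parameter
(d = −½ln(1−2P−Q) − ¼ln(1−2Q)), with complete or pairwise gap deletion.
The default is K2P with pairwise deletion, the historical default of
distance-matrix phylogeny software; saturated pairs (non-positive log
argument) raise by default or can be flagged infinite. Neighbour joining
follows the Saitou–Nei Q-criterion; ties in Q are broken by the
lexicographically smallest cluster-label pair, negative branch-length
estimates are clamped to zero and flagged, and the final three clusters
are resolved by the three-point formulas, so additive matrices are
recovered exactly (topology and branch lengths). Trees are unrooted
(trifurcating seed node) until rooted on an outgroup's pendant edge
midpoint. Because bootstrap supports belong to bipartitions rather than
nodes, rerooting re-maps internal labels by bipartition.

Bootstrap: alignment columns are resampled with replacement; replicate r
draws from a generator seeded `seed + r`, so the stream is deterministic
and order-independent. Supports are mapped onto the full-data NJ tree (not
a consensus), as percentages of replicates containing each bipartition.
Maximum-likelihood and maximum-parsimony inference are deliberately not
implemented; externally produced Newick trees can be imported
(`read_newick`) for support comparison and monophyly queries.

## Synthetic data

The generator defines the study conditions the tests run under.

*Karyotype*: 19 homolog pairs, total haploid length 74 µm (mean chromosome
≈ 3.9 µm), relative lengths on a linear profile with longest/shortest
ratio 2.33, a per-pair CI profile with 17 metacentric pairs (CI 44–50) and
two submetacentric pairs (CI 31 and 29) at size ranks 9 and 15, and a
satellite (0.45 µm) on the long arm of the largest pair — a complement
whose formula is 2n = 2x = 38 = 34m(2SAT)+4sm, mean CI ≈ 45, A1 ≈ 0.17,
As K% ≈ 55, AI ≈ 3, Stebbins 2B, i.e. the parameter ranges published for
karyotypes of this structure. Five cells are measured; condensation is a
per-cell scalar (0.94–1.06) and measurement noise is multiplicative
Gaussian per arm (CV 3% by default), independent across arms and cells.
This emulates the *statistical* structure of real measurement tables, not
their failure modes: no mis-paired homologs, no missing chromosomes, no
correlated within-cell distortions — so passing tests demonstrate correct
arithmetic and bookkeeping, not robustness to karyotyping errors.

*Alignment*: targets (variable sites, informative sites, indel events,
transition/transversion counts, GC) are realized *exactly* and returned in
a ledger. Every variable column carries exactly two observed states, hence
the constraint ts + tv = n_variable, enforced loudly (published tables
whose transition+transversion totals undershoot their variable-site counts
were produced by pairwise-averaging software and are a different
statistic). Informative columns give a derived base to all members of one
group (groups with ≥ 2 members cycle); singleton columns cycle over taxa
in input order, so an outgroup listed first accumulates private
substitutions. Gap events (1–3 columns, 1–3 taxa) avoid variable columns
and keep a gap-free spacer between events so each is one countable event.
The packaged fixture concatenates three region-wise simulations —
ITS1 260 + 5.8S 157 + ITS2 244 columns with per-region targets
(5/1/7 variable, 3/0/5 informative, 2/0/1 indels, ts:tv 2:3 / 0:1 / 1:6,
GC 67.5/56/61%) — over 24 ingroup accessions (4 "species" × 6, in two
groups) plus an outgroup. There is no homoplasy and no rate variation;
bootstrap supports on such clean data are upper bounds on what real ITS
data would give.

## Numerical choices and degenerate inputs

Zero-noise, unit-scale generation reproduces ledger values through the
pipeline to ≤ 1e-9 (absolute); exactness is limited only by floating-point
summation in the means. Single-pair karyotypes raise for A2/AI/length
ratio (undefined). NJ requires ≥ 3 taxa; distance computation errors on
pairs with zero comparable sites. Sampled arm lengths ≤ 0 are resampled
with a bounded retry (100) before erroring. The idiogram renderer enforces
a minimum band height (2 px) so thin bands stay visible; geometry tests
use the arm rectangles, not the minimum-size bands.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
19 pairs × 5 cells for the karyotype half; 25 taxa × 661 columns for the
alignment; 100 random additive 4–6-taxon matrices for NJ recovery; 1,000
bootstrap replicates for the support analysis; 50 random alignment specs
for the counter/ledger agreement check.

## Known limitations

* Homolog pairing and measurement are assumed done upstream; no image
  analysis.
* GISH signal comparison is qualitative in the source domain and has no
  quantitative procedure here.
* The substitution-typing and indel-counting conventions are one
  deterministic choice among several in circulation; counts from other
  software may differ on the same alignment.
* ML/MP tree inference is not implemented; only imported trees can be
  compared.
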