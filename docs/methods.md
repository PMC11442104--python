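# Methods

This note records the models, conventions and defaults behind `armscaps`,
the choices made where the design was genuinely open, and the limits of
what the synthetic-data tests demonstrate.

## Pileup model

Allele counts are taken per reference position from coordinate-sorted
alignments, excluding unmapped, secondary, supplementary, QC-fail and
duplicate reads, reads below mapping quality 20 and bases below base
quality 13 (both configurable; duplicates are excluded because standard
resequencing preprocessing marks PCR duplicates). Only aligned A/C/G/T
bases are counted: insertions, deletions and reference skips are ignored —
the pipeline targets SNPs only — and positions whose reference base is N
are never emitted. All user-facing coordinates are 1-based inclusive.
Plain SAM inputs (used by the hermetic test fixtures) are converted to
sorted, indexed BAM on the fly.

The SNP-index of allele *b* at a position is count(b)/depth. It is
deliberately undefined (an error, never silently 0) at depth 0: absence of
coverage is absence of evidence.

## Genotype calls from binomial intervals

At a site with variant dosage *d* and ploidy *k*, the variant read count
at depth *n* is modelled as X ~ Binomial(n, d/k) — reads sample the
chromosomal copies independently and uniformly, with no reference bias,
mapping bias or overdispersion. The central confidence interval of X/n
uses the convention: lower endpoint q/n with q the smallest integer whose
CDF reaches α/2, upper endpoint r/n with r the smallest integer whose CDF
reaches 1 − α/2. The convention is stated because it makes every interval
bit-reproducible; the companion Monte-Carlo construction (≥ 10,000 seeded
replicates, same quantile rule applied to the empirical CDF) exists only
as an independent cross-check of the exact one. Where the exact CDF ties a
quantile target within simulation noise (a knife-edge cell), empirical and
exact quantiles can legitimately differ by one 1/n grid step; the
cross-check treats exactly those cells as equal-within-one-step and
demands identity everywhere else.

Derived quantities:

* **Minimal depth separating heterozygous from homozygous** — the smallest
  n whose interval excludes both 0 and 1. For diploids at 95% this is 6
  (at depth 5 the interval is [0, 1]).
* **Dosage discernibility** — for ploidy ≥ 3, the smallest n at which the
  closed intervals of dosages 1..k−1 are pairwise disjoint (strictest
  reading of "discernible"; disjointness of closed intervals is stated
  explicitly because an open-interval reading changes the answer by a few
  units). For autotetraploids at 95% this is 58.

Selection filters built on these intervals:

* **Homozygous default** — cultivar A non-polymorphic (every non-reference
  index ≤ tol_A, default 0), cultivar B with exactly one non-reference
  allele at index within [1, 1]. Multi-allelic cultivar-B sites are
  rejected outright: a marker needs a single discriminating allele, and
  picking the major allele would silently genotype the wrong thing.
* **HeteroSelect** — candidates come from the open index range (0, 1);
  a site is kept iff its index lies in the interval for the requested
  dosage at the site's own depth, and is relabelled simplex/duplex/triplex
  (ploidy 4) or heterozygous_diploid (ploidy 2). Only cultivar B's index
  is interval-tested; cultivar A is still bounded by tol_A.
* **ProgenySNP** — a site survives iff the progeny bulk's index of the
  cultivar-B allele lies in the dosage-1/ploidy-2 interval at the bulk's
  depth (a random F2 bulk carries both parental alleles in equal
  expectation at every truly segregating site, as an F1 would), and the
  bulk's depth is within the accepted range. Sites absent from the bulk
  are dropped.

Depth bounds everywhere default to min 6 (the diploid separability
threshold) and max 3× the region's mean depth — a cheap guard against
collapsed repeats; both configurable.

## Primer design

Melting temperatures are nearest-neighbor (SantaLucia 1998 unified
parameters) at fixed conditions: 50 mM monovalent salt (entropy-side salt
correction 0.368·(N−1)·ln[Na⁺]) and 50 nM total oligo. The calculator is
implemented in-package (scalar and vectorized over all windows of a
region, sharing one parameter table) and is cross-checked in the tests
against Biopython's independent implementation to ±0.5 °C.

Hard constraints (defaults): length 18–28 (optimum 22), Tm 57–63 °C
(optimum 60), GC 30–70%, no homopolymer run longer than 4, footprint
coverage within depth bounds in both cultivars. Among valid candidates the
penalty |Tm − Tm_opt| + 0.5·|len − len_opt| selects the winner,
tie-broken by smaller start coordinate then lexicographic sequence, so
design is deterministic and rerunning on identical inputs is
bit-identical.

Allele-specific primers fix the 3′ end on the SNP and substitute the third
base from the 3′ end using A→C, C→A, G→T, T→G. The table is a design
choice (any non-complementary substitution works in principle); this one
is deterministic, never reproduces the original base, never complements
the template at that position, and prefers destabilizing
purine↔pyrimidine swaps. The substitution is defined on the primer's own
strand, for reverse primers too. Footprints may not contain any *other*
polymorphism and must have in-range depth.

Common primers must match the reference exactly over their footprint, with
no position where either cultivar shows a non-reference allele above a
masking threshold. That threshold (`max_nonref_freq`, default 0.10) is
deliberately separate from the selection tolerance tol_A = 0: at 30×, a
single miscalled read gives an index of ~0.033, and a strict zero would
mark essentially every covered position polymorphic, while any real allele
of the lowest dosage class (simplex, expected index 0.25) still exceeds
0.10 comfortably.

## Marker assembly

Distance conventions, fixed because prose rules like "within 100–700 bp"
are ambiguous: specific-primer pairing for tri-ARMS uses the distance
between 3′ ends (the SNP positions), window [100, 300] bp; the common
primer's whole footprint must lie 100–700 bp beyond the 3′ end of the
nearer specific primer. Product sizes are inclusive spans between the two
primers' 5′ ends. The reported tri-ARMS `spacing` is the distance between
the specific primers' 5′ ends, which equals the band-size difference
exactly (the 3′-end distance is reported separately as `snp_spacing`; the
two differ when the primers have unequal lengths).

Tetra-ARMS markers search both flanking windows, evaluate all
(left, right) common-primer pairs (reduced to the best candidate per
distinct footprint edge, which is lossless because products depend only on
those edges) and keep the minimum-penalty pair whose inner bands differ by
at least `min_band_separation` (default 50 bp — a comfortable agarose
resolution margin; any such default is a lab-specific choice). One marker
per SNP (tetra) or per specific-primer pair (tri), by summed penalty,
tie-broken by leftmost common primer. A genome-wide thinning helper keeps
the best marker per interval (default 1 Mb).

Tri-ARMS markers built on heterozygous-labelled sites carry a
`trans_risk` flag: short reads cannot phase the two cultivar-specific
alleles, and a trans configuration makes the marker unable to separate
homozygotes from heterozygotes. Sites labelled homozygous are trivially
cis.

The in-silico PCR oracle declares a product when both primers' 3′-terminal
bases match the template perfectly, each primer has at most one internal
mismatch (room for the deliberate ARMS substitution), the primers face
each other and the span is ≤ 2,000 bp; more than one amplifiable locus is
an error (non-specific primers). This is a deliberately strict annealing
model — no thermodynamic partial-binding — because its job is to verify
coordinate arithmetic and allele logic, not to predict PCR efficiency.

## CAPS design

Recognition motifs are IUPAC strings matched on the top strand;
non-palindromic motifs are additionally matched as their reverse
complement with the cut offset mirrored (the shipped AluI and EcoRI are
palindromic, so the choice is immaterial for them, but the rule is stated
because extended tables need it). An enzyme discriminates a SNP when, over
windows of motif length overlapping the SNP, one allele has at least one
match and the other none. Digestion counts *all* motif occurrences in the
product — invariant sites included — and the two allele patterns must be
distinguishable: at least one fragment in one pattern differs by
≥ `min_band_separation` from every fragment of the other. Distinguishable
patterns (rather than requiring a unique cut site) were chosen because an
invariant second site merely adds a shared band and does not confuse the
genotype call. Product size defaults to 200–1,000 bp. Primer pairs are
ranked by summed penalty; to bound runtime, at most 500 pairs per enzyme
are digested before the site is declared unusable (patterns rarely change
between adjacent candidate pairs).

## Synthetic data

The generator emulates two resequenced cultivars (plus an optional progeny
bulk) at desk scale: a seeded random reference at specified GC content,
perfectly aligned error-bearing reads (full-match CIGARs, uniform
qualities, uniform substitution errors at 0.1% by default) at ~30× mean
coverage with 100 bp reads, and SNPs whose alt-allele counts are
binomially distributed with probability dosage/ploidy per covered read —
the exact sampling model the interval machinery assumes. Standard study
conditions for the end-to-end checks: 100 kb genome, 40 SNPs (18 pairs
spaced 120–280 bp apart for tri-ARMS geometry plus 4 SNPs planted inside
AluI sites so CAPS discrimination is represented), 30× depth. The
dosage-recovery checks use 2,000 sites per dosage class at 100× — depth
100 was chosen as comfortably above the tetraploid discernibility
threshold of 58. The density-trend check uses a 400 kb genome in two
200 kb halves at 50 vs 500 SNPs/Mb with uniformly random placement, so
close pairs arise (or fail to) naturally from the density itself.

What passing these tests does *not* show about real data: reads here have
no mapping ambiguity, no indels, no coverage waves, no reference bias and
no paralogy, so the selection filters' error rates on real alignments will
be worse than the near-ideal rates measured on fixtures; the binomial
model itself ignores overdispersion (a beta-binomial would be the next
step and is explicitly out of scope).

## Known limitations

* No secondary-structure or primer-dimer thermodynamics beyond run-length
  and spacing constraints; no probe or dCAPS design.
* No subgenome-specificity screening: in allopolyploids, primers must be
  checked against homoeologous regions externally.
* Cis/trans phasing of tri-ARMS allele pairs is flagged, not resolved;
  resolving it needs long reads.
* Genotype calls are threshold rules on exact binomial intervals, not
  likelihood-based joint calls.
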