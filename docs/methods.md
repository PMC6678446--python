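# Methods

## The analysis

A sense–antisense (SAS) pair is a `+`-strand gene and a `-`-strand gene on
the same chromosome whose annotated spans intersect by at least 1 bp.
"Sense" is positional (the `+`-strand member), not functional: with
strand-phased quantification the two labels are symmetric roles, and the
classification reflects that — swapping all strands maps the embedded
forms A↔B and the partial forms C↔D (swapping strands flips which physical
end of a gene is its 5′ end), while reverse-complementing the locus maps
A↔B and leaves C and D fixed. Both symmetries are property-tested.

Genes are treated as single spans (the annotation's gene rows), 1-based
inclusive; exon structure and transcript isoforms are not modeled. No
minimum-overlap or reciprocal-overlap filter is applied, since 1-bp
overlaps are biologically reported and counted. Pairs — not merged loci —
are the unit of counting; a gene overlapping k opposite-strand genes
contributes k pairs. The count of distinct genes involved is reported
alongside for transparency. Identical spans tie-break to form A; the
choice is arbitrary but deterministic and documented.

Detection uses a per-chromosome interval tree over the `-`-strand genes
queried with each `+`-strand gene (O((n+k) log n) versus the quadratic
all-pairs scan, which is retained in the test suite as the oracle).
Same-strand overlaps are counted in a diagnostic log but never paired.

## Landscape summaries

* Length stats use the standard median (midpoint of the two central order
  statistics at even n). Forms with no pairs are flagged absent, not zero.
* Chromosome normalization is **pairs per Mb**; the per-gene normalization
  is pairs per annotated gene × 100. Both are emitted because chromosome
  length and gene density rank chromosomes differently.
* The biotype-pair label is unordered (strand assignment ignored), with
  mRNA listed first when present, otherwise case-insensitive alphabetical.
  Foreign biotype vocabularies are normalized onto eight labels
  (mRNA, lncRNA, miRNA, tRNA, snRNA, miscRNA, other); unknown biotypes map
  to `other` with a warning rather than an error so arbitrary annotations
  still run.
* Percentages are stored at full precision; rounding happens only at
  presentation.

## Expression filtering and correlation

**Filter.** "Expressed" means FPKM strictly above a threshold (default 0;
no threshold is canonical, so it is configurable). The support filter
counts the sense gene over the sense strand-samples plus the antisense
gene over the antisense strand-samples and retains a pair when the sum
reaches `min_samples` (default 26 of 32). The joint 26-of-32 reading — as
opposed to 13-of-16 per gene — follows the design in which the 32
strand-samples form a single family; both counts are reported and the rule
is configurable.

**Alignment.** Correlation pairs values by biological sample (same
specimen, sense library vs antisense library). When the sample metadata
carries a `biosample` column it is used directly; otherwise sense and
antisense sample ids are sorted within each gestational stage and paired
positionally. This convention is deterministic; it assumes consistent
within-stage naming.

**Statistic.** Spearman ρ is the Pearson correlation of mid-ranks
(average ranks on ties); p-values use the two-sided t-approximation
t = ρ·√((n−2)/(1−ρ²)) on n−2 df, adequate at n = 16 and matching
mainstream packages. |ρ| = 1 maps p to the smallest positive double so BH
input stays in (0, 1]. Constant vectors leave ρ undefined; such pairs are
flagged and excluded from the BH family, which runs over exactly the
tested set. Significance is declared on BH-adjusted p < α (default 0.05)
only.

**Skew.** The antisense/sense skew is the median of the per-(pair ×
biological sample) FPKM ratio over cells where both values are positive;
zeros are excluded because the ratio is undefined there, and a NaN
sentinel is returned when no doubly-expressed cell exists. The density
export gives the same cells as log10(FPKM+1) column pairs; the heatmap
matrix is pairs × (stage-ordered biological samples × sense/antisense) on
the same scale.

## Synthetic cohort generator

The generator emulates the stranded placental time-course design the
pipeline targets: 16 biological samples over four gestational stages (45
days, 4/6/10 months), each split into a sense and an antisense library
(32 strand-samples).

* **Annotation.** Default 600 genes on five 2-Mb chromosomes with 150
  planted pairs. Forms are drawn from a mix of 0.06/0.19/0.05/0.70
  (A/B/C/D), echoing the head-to-head-dominated landscape observed in
  mammalian genomes (~70% D, ~25% embedded, ~5% C). The antisense gene's
  coordinates are constructed to realize the drawn form *exactly*;
  embedded lengths and partial-overlap lengths are drawn as a uniform
  fraction (0.05–0.95) of the relevant gene. Gene lengths are log-normal
  (median 2 kb, σ_log 1.0 — compact relative to real mammalian genes so
  that desk-scale chromosomes hold hundreds of non-colliding pairs).
  Filler genes are placed overlapping nothing, so the detected pair set
  equals the planted set and detection recovery must be 100%. Biotype
  frequencies default to ~70% mRNA, 22% lncRNA, 2% miRNA and small
  remainder classes, mirroring a mammalian annotation's composition.
* **Expression.** Per pair, 16 latent bivariate-normal draws with Pearson
  parameter r = 2·sin(πρ_s/6) (the Gaussian-copula identity) are pushed
  through the monotone log-normal FPKM map (median ≈ 4.5 FPKM, σ_log 1),
  so the latent Spearman correlation equals ρ_s exactly in expectation.
  Per-pair targets default to a clipped normal centered at 0.29 with sd
  0.21, echoing the positive co-expression reported for SAS pairs in
  placenta; `planted_rho` pins explicit targets instead. A gene's values
  on the opposite strand's libraries are zero, as strand-phased
  quantification sees no signal there. Dropout zeroes own-strand cells
  independently with probability 0.1 by default (0.3 in the filter
  calibration), applied *after* the correlation structure — it models
  detection failure, not biological zeros.
* **Stage effects.** A per-stage shift shared by both members of a pair is
  available (`stage_shift_sd`) but defaults to 0: a shared shift is common
  signal across samples, so it *raises* the realized rank correlation
  above the planted value and de-calibrates the null. Enabling it makes
  the data more realistic (developmental trends are a genuine source of
  SAS co-expression) at the cost of the planted-ρ interpretation.
* Everything is deterministic given the seed: same seed, byte-identical
  GFF3/TSV outputs.

**What passing tests do and do not show.** Planted forms are recovered
exactly because construction and classification share no code but do share
the same geometric definitions; this validates the classifier's logic, not
annotation quality on real genomes (fragmented or merged gene models will
shift the form mix, and artificially short 3′ annotations deflate
tail-to-tail counts). Planted ρ is recovered without bias on fully
observed data; with dropout, tied zeros attenuate the realized ρ below the
latent target (visible in the worked example: realized mean ≈ 0.17 against
a planted mean of 0.29 at 10% dropout), exactly as library-depth dropout
attenuates rank correlations in real data. The generator does not simulate
reads, alignment, or strand-phasing errors; upstream biases are out of its
scope.

## Numerical and interface choices

* Coordinates are 1-based inclusive internally (GFF3); the BED6 writer is
  the single place converting to 0-based half-open (start−1, end).
* Expression round-trips are bit-identical: the reader parses floats with
  round-trip precision.
* BH adjustment delegates to the standard step-up implementation in
  statsmodels behind the `bh_adjust` surface and is verified elementwise
  against an independently coded step-up recursion; Spearman delegates to
  scipy and is verified against a hand-written mid-rank-then-Pearson
  oracle at 1e−12.
* Degenerate inputs: empty pair lists yield empty-summary sentinels rather
  than exceptions; genes missing from the expression matrix drop their
  pairs with a logged reason; unstranded annotation features are returned
  in a rejected list, never silently dropped.
* Problem sizes in the test suite (cohorts of 40–1000 genes, 200-replicate
  correlation recoveries, 400-pair calibration cohorts) are chosen so each
  statistical check has enough resolution for its exact binomial 99% band
  while a full run stays fast on a laptop.

## Known limitations

* Gene-span overlap only; a pair whose gene spans overlap but whose exons
  do not is still counted.
* The t-approximation p-value is approximate at small n with many ties;
  heavy dropout pushes p slightly conservative. A permutation alternative
  can be added behind the same `spearman` surface if exactness at n < 10
  matters.
* The skew statistic conditions on both strands being detected, which
  biases it toward 1 when dropout is strong.
* Chromosome enrichment is reported descriptively (counts and
  normalizations), with no significance test attached.
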