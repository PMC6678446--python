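# saspairs

Detection, classification and expression correlation of **sense–antisense
(SAS) overlapping gene pairs** — opposite-strand gene pairs sharing at least
1 bp of the same locus (cis-natural antisense transcript loci).

Overlapping transcription is widespread in mammalian genomes, and each
antisense RNA can in principle base-pair with its complementary sense RNA
and regulate it. Given a gene-level annotation and per-strand expression
matrices from stranded RNA-seq (for example, a placental time course across
gestation), this package answers three questions:

1. **Where are the SAS loci?** Every (+, −) gene pair on the same
   chromosome with intersecting spans is detected (interval-indexed, no
   minimum-overlap filter — 1-bp overlaps are genuine pairs) and classified
   into one of four forms. With sense span S = [s1, e1] on `+` and
   antisense span T = [s2, e2] on `-`:

   | form | definition | rule |
   |------|-----------|------|
   | A | antisense embedded in sense | T ⊆ S |
   | B | sense embedded in antisense | S ⊆ T |
   | C | tail-to-tail (3′ regions overlap) | partial, s2 > s1 |
   | D | head-to-head (5′ regions overlap) | partial, s1 > s2 |

   Identical spans tie-break deterministically to A. By construction,
   form-A pairs overlap 100% of the antisense gene and form-B pairs 100%
   of the sense gene.

2. **What does the landscape look like?** Overlap-length distribution
   (median/min/max, count of 1-bp pairs), per-form overlap/gene-length
   ratio tables, per-chromosome counts normalized both to chromosome
   length (pairs/Mb) and to the annotated gene count, and the
   biotype-pair × form contingency table.

3. **Do the pairs co-express?** For pairs expressed in ≥ 26 of the 32
   strand-samples (16 biological samples × sense/antisense, configurable),
   per-pair Spearman rank correlation ρ across biological samples, with
   two-sided p from the t-approximation and Benjamini–Hochberg FDR control
   (significant at adjusted p < 0.05); plus the antisense/sense expression
   skew (median of the per-cell FPKM ratio) and log10(FPKM+1) density and
   heatmap matrix exports.

A synthetic-cohort generator plants all four overlap forms in controlled
proportions and plants Spearman correlations through a Gaussian copula
(latent Pearson r = 2·sin(πρ_s/6)), so the entire pipeline is testable
offline against known ground truth.

## Worked example

Run the whole pipeline on a default synthetic cohort (600 genes, 150
planted pairs on five 2-Mb chromosomes, 16 biological samples across four
gestational stages):

```bash
saspairs run --synthetic --seed 42 --out-dir demo
```

prints (abridged):

```
annotated genes (stranded): 600
overlapping pairs: 150
  form A: 9 (6.0%)
  form B: 38 (25.3%)
  form C: 4 (2.7%)
  form D: 99 (66.0%)
overlap length (bp): median 755, min 17, max 11178
pairs with 1-bp overlap: 0
expression filter (>= 26 expressed strand-samples): 144 of 150 pairs retained
pairs tested for correlation: 144
Spearman rho: mean 0.1722 +/- 0.2976, median 0.1935
significant (BH-adjusted p < 0.05): 2 positive, 0 negative
antisense/sense expression skew (median): 0.9441
```

All 150 planted pairs are recovered and the form mix tracks the configured
proportions (0.06/0.19/0.05/0.70 for A/B/C/D). The filter drops the 6
pairs whose dropout left fewer than 26 expressed strand-samples; the mean
ρ sits below the planted latent mean of 0.29 because dropout zeros
attenuate rank correlations (see `docs/methods.md`). `demo/` contains the
pair table (TSV + BED6), ratio/chromosome/biotype tables, correlation and
filter tables, density and heatmap matrices, and the report.

The same stages are available on real inputs:

```bash
saspairs detect    --gff annotation.gff3 --chrom-lengths chroms.tsv --out-dir out
saspairs correlate --gff annotation.gff3 --expression fpkm.tsv \
                   --metadata samples.tsv --out-dir out
```

or from Python via `saspairs.run_pipeline(PipelineConfig(...))`.

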