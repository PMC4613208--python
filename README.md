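# sweepx

Selection-signature scanning of a single chromosome from phased SNP-chip
genotypes, for population geneticists working with small livestock (or
other) panels: a within-population haplotype scan (iHS), a
between-population differentiation scan (per-SNP F_ST), empirical
outlier calling, candidate-region construction, and gene annotation —
plus a synthetic-panel generator with ground truth so every stage can be
validated end to end.

## The statistics

**iHS.** For a core SNP, the extended haplotype homozygosity at a
flanking SNP is the probability that two random haplotypes carrying the
same core allele are identical over the intervening interval.
Integrating EHH over physical distance on both sides gives iHH,
separately for ancestral- and derived-allele carriers, and

```
iHS = [ ln(iHH_A / iHH_D) − E ln(iHH_A / iHH_D) ] / SD ln(iHH_A / iHH_D)
```

with the mean and SD taken within derived-allele frequency bins.  A
recent hard sweep leaves the derived allele on an unusually long shared
haplotype, inflating iHH_D and pushing iHS strongly negative.  The
companion value P_iHS = −log10 of the two-sided Gaussian tail
probability of iHS.

**F_ST.** With p_i the allele frequency in population i, pooled
frequency p (size-weighted), H_T = 1 − (p² + q²) and
H_S = Σ 2 p_i (1 − p_i) n_i / N:

```
F_ST = (H_T − H_S) / H_T
```

**Outliers and regions.** iHS outliers are |iHS| > 2.  F_ST outliers
use the boxplot rule: with quartiles F_L, F_U and Q = F_U − F_L, values
above UL = F_U + 1.5 Q (or below LL = F_L − 1.5 Q) are outliers; only
the upper tail seeds regions.  Each outlier SNP becomes a ±200 kb
window; overlapping windows merge; per-method regions combine into
candidates (union by default, or a Benjamini–Hochberg FDR rule: region
q < 0.1 in both methods or q < 0.05 in one).  Candidates are annotated
with any gene overlapping the region after a ±100 kb extension.

See `docs/methods.md` for assumptions, parameter defaults, and the
simulator's design.

## Worked example

Simulate a three-population panel (40/25/12 samples, 400 SNPs over
135 Mb) with a known sweep and differentiated loci, then run the whole
pipeline:

```
$ sweepx simulate --seed 7 --out demo --n-snps 400 --samples 40,25,12
panel written to demo (77 samples x 400 SNPs)

$ sweepx run --config demo/config.txt
INFO QC: 0 samples and 27 SNPs removed; 77 x 373 panel remains
  method  label n_outlier_snps  n_regions  avg_length_mb  total_length_mb
     ihs     GM             16         15           0.40             6.04
     ihs      D             16         15           0.40             6.04
     ihs      S             12         11           0.42             4.62
     fst GM-D-S             20         18           0.42             7.48
     fst   GM-D             20         17           0.45             7.64
     fst   GM-S             41         36           0.42            15.24
     fst    D-S             34         31           0.43            13.19
combined     GM           <NA>         31           0.41            12.72
combined      D           <NA>         32           0.42            13.34
combined      S           <NA>         27           0.44            11.79
run directory: demo/run
```

Reading the table: each `ihs` row is one population's scan (16 outlier
SNPs merged into 15 regions of ~0.40 Mb in GM); each `fst` row is the
joint or a pairwise scan; `combined` rows are the merged per-population
candidates.  The run directory also contains the per-SNP score tracks
(`ihs_GM.tsv`, `fst_GM-D-S.tsv`, ...), QC report, PCA coordinates,
region BED/TSV, pairwise overlap lengths (`overlaps.tsv`), and a
provenance file; `demo/truth.json` records the simulated sweep
(here: focal SNP `snp00330` at 115.9 Mb in GM, derived frequency 0.8)
and the differentiated loci, so you can check directly that the focal
SNP falls inside a reported candidate region.

Every stage is also callable on its own (`sweepx qc | ihs | fst |
regions | annotate`) and as plain library functions
(`sweepx.ehh.ihs_scan`, `sweepx.fst.fst_scan`, ...), accepting phased
VCF (with optional `AA` ancestral tags) or PLINK PED/MAP text, a
sample→population table, and GFF3/BED gene models.

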