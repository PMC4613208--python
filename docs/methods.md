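# Methods

`sweepx` scans a single chromosome of phased SNP-chip genotypes for
signatures of recent positive selection, combining a within-population
haplotype statistic (iHS) with a between-population differentiation
statistic (F_ST), and reduces the per-SNP scores to merged candidate
regions annotated with genes.  It was designed around the geometry of a
medium-density ovine chip panel on the X chromosome — three ewe
populations of roughly 90/50/12 animals, ~1,200 SNPs over ~135 Mb
(~110 kb spacing) — but every geometric parameter is configurable.

## Quality control

Samples are removed for call rate < 0.90 or duplication (pairwise
identity-by-state ≥ 0.99 over co-called SNPs; the later-listed sample of
a pair is dropped, a deterministic tie-break).  SNPs are removed, in
this order of reasons, for call rate < 0.90, pooled minor-allele
frequency < 0.05, or Hardy–Weinberg disequilibrium with exact-test
p < 1e-6.  All removals use strict inequality, so a sample called at
exactly 90% survives.

The HWE test is the full-enumeration exact test: conditional on the
observed allele counts, every compatible heterozygote count is
enumerated and the probabilities no larger than the observed
configuration's are summed.  HWE is tested **within each population**
and the minimum p across populations is compared to the threshold.
Pooled testing would flag genuinely differentiated SNPs (the Wahlund
effect) — precisely the SNPs the F_ST scan needs — whereas
per-population testing targets genotyping artifacts only.  A pooled
mode is available by passing no population map.

PCA is a diagnostic: genotype columns are centered and scaled by
√(2p(1−p)) and samples projected onto the leading singular directions.
No automatic exclusion is derived from it; panel selection from PCA is
a judgment call left to the analyst.

Residual missing genotypes can be filled with the within-population
modal genotype (ties to the smaller code).  This is a deliberately
simple rule — the pipeline expects its input to be phased and imputed
upstream, and refuses unphased panels for the haplotype statistics.

## iHS

For a core SNP, EHH at a flanking SNP is the probability that two
randomly drawn haplotypes carrying the same core allele are identical
at every SNP between core and flank (both inclusive):
EHH = Σ_g C(k_g, 2) / C(n_c, 2) over groups g of identical carrier
haplotypes.  EHH is integrated by the trapezoid rule over physical
distance separately to the left and right, and separately for carriers
of the ancestral (iHH_A) and derived (iHH_D) allele.  The
unstandardized score is ln(iHH_A / iHH_D); a sweep on the derived
allele inflates iHH_D and drives the score strongly negative.

Numerical choices:

* **Distance is physical (bp).**  Chip panels carry no genetic map;
  a per-bp scaling would cancel in the log-ratio anyway (the score is
  invariant to position translation and to uniform rescaling).
* **Integration cutoff 0.05** — each side stops at the first point
  whose EHH drops below 0.05 (that point excluded).  **Gap truncation
  at 500 kb** — an inter-SNP gap larger than 500 kb truncates the
  integral at the last SNP before the gap and flags the SNP
  (`truncated_by_gap`) instead of dropping it.  Both are the common
  practice for sparse chip data and both are configurable.
* **Eligibility** — cores need a resolved ancestral allele and derived
  frequency in [0.05, 0.95]; others are reported as NA with a flag.
  Ancestral alleles come from an `AA` INFO tag or a user table; the
  default fallback assigns the major allele (with a warning), since
  chip annotations resolve ancestral state for only part of the
  markers; a strict `skip` mode leaves them out instead.
* **Standardization in derived-frequency bins of width 0.05** spanning
  [0.05, 0.95]: within each bin, iHS = (raw − mean)/sd (sample sd,
  n−1).  The log-ratio has a well-known dependence on derived
  frequency; binning removes it.  `bin_width = 1.0` collapses to a
  single global bin for the literal unconditional-moments reading.
  Bins with fewer than two finite scores or zero spread produce NA
  with a warning.
* **P_iHS = −log10(2(1 − Φ(|iHS|)))**, the two-sided Gaussian tail of
  the standardized score, reflecting the approximate standard normality
  of the binned z-scores.

## F_ST

Per SNP, with p_i the alt-allele frequency in population i and n_i the
population sizes: pooled p = Σ n_i p_i / Σ n_i (an unweighted pooling
switch exists), H_T = 1 − (p² + q²), H_S = Σ 2 p_i (1−p_i) n_i / N, and
F_ST = (H_T − H_S)/H_T.  Monomorphic SNPs (H_T = 0) are NA; tiny
negative rounding artifacts are clamped to 0.  This is the plain
H_T/H_S estimator **without** small-sample or
population-count correction (no Nei or Weir–Cockerham terms).  A
consequence worth knowing: across k populations each drifted
independently with variance F·p·q, the plain estimator's expectation is
F·(k−1)/k, not F — about F/2 for a pairwise scan.  The scans are
outlier scans, so this global scale factor does not affect which SNPs
stand out, but absolute values should not be read as Weir–Cockerham θ.

The standard study design is one joint scan over all populations plus
every pairwise scan; the pipeline runs all of them.

## Outliers, regions, candidates

* iHS outliers: |iHS| strictly greater than 2 (the usual empirical
  autosomal cutoff carried to the X).
* F_ST outliers: the boxplot rule.  Quartiles F_L, F_U by linear
  interpolation at ranks 0.25(n−1) and 0.75(n−1) on the sorted values
  (other quantile definitions can be passed through), interquartile
  range Q = F_U − F_L, fences UL = F_U + 1.5Q and LL = F_L − 1.5Q;
  outliers are strictly outside the fences.  Only upper-tail outliers
  seed candidate regions — diversifying selection raises F_ST; values
  below LL are reported but not promoted.
* Each outlier SNP spawns a ±200 kb window clamped to the chromosome;
  overlapping or book-ended windows merge, keeping the member with the
  largest |statistic| as the peak.  The 200 kb half-width reproduces
  the ~0.4 Mb single-SNP regions typical of ~110 kb marker spacing and
  is configurable.
* Candidate combination has two modes.  The default `threshold` mode
  takes the merged union of the |iHS| regions and the upper-tail F_ST
  regions.  The `fdr` mode computes Benjamini–Hochberg q-values — from
  two-sided Gaussian p for iHS and from empirical upper-tail rank p,
  p = (1 + #{F_ST_j ≥ F_ST_i})/(1 + n), for F_ST — and keeps a region
  when its minimum member q is below 0.1 in both tracks or below 0.05
  in at least one.  The region-level q is the minimum over member SNPs,
  the natural choice when the rule is stated per region.
* Summaries report per (method, label) the outlier count, region count,
  mean and total length in Mb (two decimals); overlap between two
  merged region sets is the total pairwise intersection length.

## Annotation

Candidate regions are extended by exactly 100 kb (configurable) up- and
downstream at annotation time, then any gene whose interval overlaps
the extended region by ≥ 1 bp is reported — partial overlap counts,
since sweep windows routinely clip gene boundaries.  Gene models come
from a user-supplied GFF3 (gene-type features) or BED file; strand is
carried through but ignored.  Enrichment analysis and ortholog mapping
are out of scope (they require external databases).

## Synthetic panels

The generator provides ground truth for every stage:

* **Background**: per SNP an ancestral derived-allele frequency
  p ~ U(0.05, 0.95); each population draws its own frequency from the
  Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) at background F = 0.05.
  Haplotypes are mosaics of 20 per-population founder haplotypes with
  Poisson crossovers at 1e-7 per bp (mean segment ~10 Mb), giving LD —
  and hence EHH — that decays with distance at chip density.
* **Differentiated loci** (default five at F = 0.5) are displaced
  deterministically: p_i = p + c_i·√(F·p(1−p)) with contrasts c_i of
  mean 0 and variance 1 under the population-size weights, permuted
  across populations per locus.  A plain Balding–Nichols draw at F=0.5
  realizes wildly variable differentiation (a "differentiated" locus
  can land with F_ST ≈ 0.04), which would make the truth record false;
  the deterministic displacement guarantees each truth locus realizes
  its nominal differentiation under the estimator's own weighting.
* **Sweep** (default: to derived frequency 0.8 over a 1 Mb span in the
  largest population, at a random interior core starting below the
  target): the final derived-carrier set is exactly one donor haplotype
  plus randomly chosen recipients of its window copy; haplotypes
  outside that set revert to the ancestral core allele (flanks
  untouched).  This matches hard-sweep genealogy — every derived copy
  descends from the haplotype the mutation arose on — pins the achieved
  frequency exactly, and makes EHH = 1 among carriers across the span.
* **Degradation**: genotype collapse plus uniform missingness, for
  exercising QC.

What the generator does **not** emulate: demographic history,
recombination hotspots, ascertainment bias of chip SNP selection,
genotyping error beyond missingness, and linked background selection.
Passing recovery tests therefore show the statistics detect the
*idealized* signals they are defined for at realistic panel geometry,
not that real data of this size always yields them.

Default problem sizes used in the test-suite recovery studies: 20
replicates of the full default panel (148 samples × 1,200 SNPs) for
sweep and differentiated-locus recovery; 600–800 SNP single-population
panels for distributional checks; a 50-sample, 300–400 SNP panel for
end-to-end pipeline and determinism checks.

## Determinism

All randomness flows from `numpy.random.default_rng` seeded from the
run seed; the sweep uses a sub-stream spawned from the seed so the
neutral background is identical with and without injection.  Identical
seed and configuration reproduce the run directory byte for byte.

## Known limitations

* Only biallelic SNPs; multiallelic records are rejected loudly.
* Only diploid, fully phased input for iHS (e.g. an all-female panel on
  the X; no hemizygote handling).
* One chromosome per run.
* The F_ST scale is the uncorrected H_T/H_S estimator (see above).
* The boxplot and |iHS| > 2 rules are empirical-outlier conventions,
  not calibrated significance tests; the FDR mode is provided but its
  empirical p-values inherit the genome-wide-neutrality assumption of
  rank p-values.
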