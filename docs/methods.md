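# Methods

## Scope and design

The package implements a population CNV analysis whose input is four
heterogeneous CNV call sets (two array-intensity callers, two
sequencing-depth callers) over one cohort, plus SNP genotypes, annotation
tracks and a reference CNVR catalogue. Every computational step lives in
`src/cnvpop/`; the numbered scripts under `analysis/` are thin drivers that
run one stage each on the built-in synthetic cohort and narrate what they
find. Because the study design this emulates deposited no raw data, the
synthetic cohort is the primary test bed: it is first-class, tested code,
and every downstream stage is scored against its planted truth.

## Coordinates and classes

Intervals are 0-based half-open internally (BED convention); all
tab-separated I/O prints 1-based inclusive coordinates and the conversion
happens only at the I/O boundary, where it is tested as an exact bijection.
Copy-number state is categorical — 0, 1, 3, 4+ — with classes above 4
collapsed into 4+; direction (deletion for {0,1}, duplication for {3,4+})
is derived, never stored. Chromosome names are normalized by stripping any
`chr` prefix at ingest.

## Consensus integration

* **Size filter**: calls must span ≥ `min_units` (default 5) consecutive
  probes/windows. With the default unit sizes (array 1000 bp, sequencing
  500 bp) this imposes an effective size floor of ~2.5 kb: smaller events
  cannot survive in any call set, which is a property of the design, not a
  defect, and the recovery analyses account for it explicitly.
* **Outlier rule**: a sample is dropped when its raw call count exceeds
  median + k·(1.4826·MAD), k = 3. If MAD is 0 the scale falls back to
  IQR/1.349; if both are 0 no sample is dropped. On well-separated count
  distributions this recovers exactly the planted outliers; on homogeneous
  cohorts it occasionally flags heavy-but-legitimate carriers — a known
  property of any robust cutoff, visible in the stage report.
* **Matching** requires ≥ 1 bp overlap and the same direction, not the same
  class: a heterozygous and a homozygous deletion at one locus are the same
  event seen with platform-dependent genotype accuracy. A reciprocal-overlap
  fraction is available but off by default. Within a sample, matching is
  restricted to pairs from different algorithms and closed transitively
  (connected components); a component survives if it contains ≥ 2 distinct
  algorithms.
* **Rescue** compares each surviving singleton against all post-QC raw
  calls of other samples (the permissive reading of "a second occurrence");
  rescued calls keep their own breakpoints, since the curation rules are
  within-genome rules.
* **Curation**: in mixed-platform groups only sequencing members donate
  breakpoints; multiple donor calls intersect (max start, min end). The
  consensus class follows the breakpoint donor; for intersections the
  narrowest member donates, ties broken toward the extreme class (0 over 1,
  4+ over 3). If transitively chained donors share no common segment the
  narrowest single member is used and the call is flagged (`fallback`);
  such calls are the only ones whose endpoints may not both appear among
  the raw endpoints.

## CNVR merging and accounting

Within a subpopulation, final CNVs are merged per class by single-linkage
≥ 1 bp overlap; the region interval is the cluster hull (min start–max end),
because a population "region" is the locus extent across carriers, and
same-class regions are pairwise disjoint and idempotent under re-merging.
For the combined tally, same-direction regions (e.g. overlapping CN0 and
CN1) first collapse into direction-level loci; a deletion locus overlapping
a duplication locus is a *polymorphic* pair, and

    combined = deletion_loci + duplication_loci − polymorphic_pairs,

i.e. each polymorphic site counts once. Frequency labels read the printed
bin edges literally: < 1% strict, 1–10% inclusive, > 10% strict, and
"common" means carrier fraction > 20%.

## Annotation

The genic/nongenic partition uses gene-span overlap; per-gene impact uses
exon *containment* ("affected" exons are those fully inside the CNV
breakpoints; merely overlapped exons are reported separately). Deletions
containing ≥ 1 exon are exonic; duplications are full-gene (span contains
the gene), internal (both endpoints strictly inside), or partial (exactly
one endpoint inside — excluded from the disease-gene report, as partial
duplications have ambiguous functional reading). Exon indices follow
transcription order, so minus-strand genes count from the right. Novelty
means no same-direction overlap with any high-resolution record of the
reference catalogue (an optional reciprocal-overlap fraction tightens
this). Strand is otherwise ignored: CNVs are strand-agnostic.

## Statistics

* **Density curves**: Gaussian KDE with Silverman's rule-of-thumb bandwidth
  0.9·min(sd, IQR/1.34)·n^(−1/5) on a grid spanning the data ± 3 bandwidths,
  with a bandwidth floor of 10⁻⁶ × range (10⁻⁶ for constant input) so a
  degenerate sample yields one narrow spike that still integrates to 1.
  The KDE is implemented directly rather than through a library wrapper
  because the floor and the exact rule-of-thumb factor are part of the
  contract; it is tested against the closed-form normal density (sup-norm
  < 0.02 at n = 10⁴) and the unit-integral invariant.
* **ANOVA–Tukey**: `scipy.stats.f_oneway` + `scipy.stats.tukey_hsd`
  (studentized-range adjusted p). Validated against a 10⁴-permutation
  maximum-studentized-statistic oracle in the tests. All-zero within-group
  variance makes the p-values NaN, reported as such.
* **PCA** is an SVD of the column-centred sample × CNVR carrier (0/1)
  matrix — incidence, not dosage, since the question is CNV *sharing* —
  with signs fixed by the largest loading per component. An all-zero
  carrier matrix is an error; identical rows give identical (zero-variance)
  coordinates.
* **Cytoband burden**: per band, two-sided Fisher's exact test on
  [[a, A−a], [b, B−b]] where A and B are the two cohorts' CNVR totals —
  the only 2×2 construction consistent with "enrichment of CNVRs from a
  specific cytoband". Matched to exhaustive hypergeometric enumeration to
  10⁻¹² on margins ≤ 40. The default alpha 6.7 × 10⁻⁶ is a configurable
  constant taken from the source convention, not derived here.

## Deletion tagging

CNV genotypes are binary carrier vectors (any deletion-direction overlap),
per the "converted to binary format" convention; deleted-allele dosage
coding (CN0 → 2, CN1 → 1) is available behind a flag but the pipeline uses
binary.
Deletion loci are the subpopulation-merged deletion regions lifted to the
full cohort (n = all post-QC samples). The ± 500 kb window is closed at
both boundaries; SNPs inside the deletion are included. r² is squared
Pearson correlation over pairwise-complete samples; monomorphic vectors
make r² undefined, and undefined SNPs never compete for best tag rather
than scoring 0. Best tag maximizes r², then minimizes distance to the
nearer breakpoint, then position — fully deterministic. The top summary
threshold (1.0) counts complete LD (r² ≥ 1 − 10⁻¹²), since "r² > 1" is
unsatisfiable; lower thresholds are strict.

## The synthetic cohort

The generator emulates the statistical structure the analysis must
resolve, with study-scale defaults:

* **Cohort**: 57/20/20 samples in subpopulations Q1/Q2/Q3.
* **Loci**: 150 deletion and 120 duplication loci laid out round-robin
  over 22 linear chromosomes of 100 Mb, ≥ 1.1 Mb apart so the ± 500 kb SNP
  windows of neighbouring loci stay disjoint; 12 duplication loci are
  planted on top of deletion loci to create polymorphic sites. No sequence
  is simulated — the analysis never touches one.
* **Allele frequencies**: shared loci draw a Beta(0.8, 4) base frequency
  (rare-skewed with a common tail); 30% of loci are private to one
  subpopulation with frequency U(0.2, 0.6), which is what lets PCA separate
  the groups. Genotypes are Hardy–Weinberg within subpopulation with an
  inbreeding coefficient F (defaults 0.08/0.05/0 for Q1/Q2/Q3) inflating
  homozygosity — the consanguinity mechanism behind the homozygous-deletion
  excess in Q1/Q2 — and a duplication-frequency scale (1.25 in Q3) planting
  the reciprocal amplification excess in Q3. Hom deletion → CN0, het → CN1;
  hom duplication → CN4+, het → CN3.
* **Sizes**: log-normal (σ = 0.7 on the log scale) with class medians
  4187/8604/20101/10669 bp for CN0/CN1/CN3/CN4+. Locus sizes use the
  heterozygous-class medians (most carriers are het); the homozygous-class
  medians shape false-positive calls of those classes.
* **Platform model**: per-algorithm detection sensitivity (array 0.55–0.75,
  sequencing 0.85–0.88), Gaussian breakpoint jitter with array sd 800 bp ≫
  sequencing 50 bp, unit counts proportional to span (1000 bp probes /
  500 bp windows), Poisson false positives per sample (15–30 per
  algorithm), a vendor sequencing caller that never emits CN0 (it relabels
  to CN1) and over-emits duplications 3:1, and 3 designated outlier samples
  with 40× the false-positive rate. These rates are free parameters chosen
  once to reproduce the qualitative platform asymmetry (array: fewer,
  larger, coarser calls; sequencing: more, smaller calls with a duplication
  excess); no quantitative per-caller error rates exist to calibrate
  against.
* **SNPs**: 25 per deletion-locus window, background frequencies
  U(0.05, 0.5) independent of the deletion. For each common deletion
  (≥ 4 truth carriers), with probability 0.6 one window SNP carries the
  carrier-indicator genotype (dosage 1 for carriers, 0 otherwise) so its
  r² with the binary CNV coding is exactly 1 by construction. The array
  panel is a 35% random subset of SNPs, but includes a planted tag with
  only probability 0.2 — the mechanism behind the array panel's poor
  tagging performance.

**What the simulation does not emulate** — and hence what passing tests do
not show about real data: LD between background SNPs (each is drawn
independently, so there are no partial tags from haplotype structure),
recombination and haplotypes, locus-length variation between carriers at
one locus, platform-specific systematic artifacts (GC waves, segmental
duplications, reference errors), and genuine cytoband-level clustering of
CNVs (no burden enrichment is planted, so the Fisher screen is a null
check). The pipeline's recovery results bound what the method can do under
its own assumptions; they are not an accuracy claim for any real platform.

## Problem sizes and numerical choices

The default in-package runs use 97 samples and 270 loci (seconds per
stage). The frequency-recovery analysis uses 1000 samples and 200 loci in
a noise-free configuration, restricted to loci above the ~2.5 kb size
floor, where planted carrier probabilities must be recovered within 3
binomial standard deviations for ≥ 95% of (locus, subpopulation) pairs;
its burden contrast plants equal F in Q1 and Q2 (no private loci, no
duplication scaling) so the inbreeding effect is the single difference the
ANOVA is asked to find. At the 97-sample study scale the CN0 contrast is
underpowered and reported as such — only the duplication excess in Q3
reaches p < 0.01 there.

Determinism: one `numpy` generator seeded from the config drives the
truth draw, the platform emission and the SNP simulation (fixed offsets
separate the three streams); iteration orders are sorted everywhere, and
two runs with the same config are byte-identical, which the suite asserts
on the serialized outputs.

## Known limitations

* The inter-individual rescue step indexes raw calls per chromosome with an
  interval tree; on cohorts far larger than simulated here it becomes the
  bottleneck.
* Carrier status for tagging is binary; multi-allelic dosage LD is out of
  scope.
* Cross-subpopulation CNVR unification is provided only as the
  direction-locus view used for tagging; the primary objects are
  subpopulation-level regions.
* The annotation bundle shipped with the simulator is synthetic; real
  analyses should load real GFF3/BED/cytoband tracks through `cnvpop.io`.
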