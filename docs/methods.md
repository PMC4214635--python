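# Methods

## Scope and data model

The package analyses proband–father–mother exome trios after upstream
alignment and genotype calling; its inputs are multi-sample VCFs (GT/DP/AD
per member), a tab-delimited annotation table keyed by
`(chrom, pos, ref, alt)` carrying gene symbol, predictor scores (SIFT,
PolyPhen-2, PROVEAN) and population allele frequencies, transcript models
(GFF3 + FASTA), gene panels, and per-trio callable-base totals.
Coordinates are 1-based and fully closed throughout, as in VCF.
Multi-allelic records are decomposed into biallelic sites on read, with
per-allele alt depths and the reference AD taken unchanged; indels are
assumed left-normalised upstream. When DP is absent but AD present, depth
is reconstituted as the AD sum.

## De novo filter cascade

Three conjunctive predicates, order-independent by construction:

| rule | default | rationale |
|---|---|---|
| proband depth | ≥ 10 | below this a het call is unreliable |
| proband alt reads | ≥ 4 and ≥ 20% of reads | standard exome support rule |
| panel / in-house frequency | < 0.5% each | a true DNM is essentially private |
| parent depth | ≥ 10 | an uncovered parent cannot exclude inheritance |
| parent alt reads | ≤ 1 and VAF ≤ 3% | one stray read in a deep parent is noise |

Parental absence is deliberately not a literal zero-alt-read rule: at
depth ~135× a single mismatching read is expected from sequencing error
alone, and a strict-zero rule would discard true DNMs roughly in
proportion to parental depth. `FilterConfig.strict_parental_zero()`
restores the literal rule. The ≥ 10× requirement is applied to all three
members for de novo assertions, although support filtering of the proband
alone would suffice for calling.

Proband VAF below 25% raises `mosaic_flag` but never excludes: a germline
heterozygote is binomially centred at 50%, so a markedly lower fraction is
evidence of post-zygotic origin, not of a false call. The 20–25% band is
thereby retained-but-flagged; the cascade takes no position on it.

## Consequence classification

Splice windows are positional: the two intronic bases flanking every
internal exon boundary are canonical (the near-invariant GT/AG
dinucleotides); the consensus window extends to acceptor −3 and donor
+3..+6, strand-aware. The acceptor-side consensus window is taken as {−3}
beyond the canonical pair and the donor side as {+3..+6} — the natural
reading of "up to −3 and +6". Priority: canonical splice, consensus
splice, coding indel (frameshift iff |Δlength| mod 3 ≠ 0), coding SNV by
codon translation (standard genetic code, table 1, hard-coded), else
noncoding. A coding base that also lies near an exon boundary is
classified by its coding effect — splice classes apply only to intronic
positions — except that a synonymous change within the three exonic bases
flanking an internal boundary is tagged `splice_region_synonymous`, which
an external splice-prediction flag in the annotation table can promote to
damaging. Stop-loss and start-loss fold into missense; the taxonomy
carries no separate class for them.

LoF **SNVs** are nonsense + canonical splice only: frameshifts are LoF but
not single-nucleotide events, and consensus-splice variants are excluded
from coding-SNV totals, so neither enters the SNV burden comparisons.

Damaging prediction: truncating classes are damaging by definition;
missense requires every *available* predictor to call damaging (SIFT ≤
0.05, PolyPhen-2 ≥ 0.45, PROVEAN ≤ −2.5 — the predictors' published
conventions); in-frame indels are judged by PROVEAN alone; unscored
missense is conservatively not damaging. Consensus-splice variants are
treated as damaging by position.

## Burden statistics

The exact binomial test is implemented directly rather than delegated,
because the rate test needs n ≈ 2.5×10⁹ trials: the point probability is
evaluated with the saddle-point (Stirling/deviance) decomposition used by
robust pmf implementations — a log-gamma difference loses ~6 significant
digits at that scale — and tails are summed from the anchor with a
multiplicative recurrence, always on the numerically smaller side, so cost
scales with the distribution's width, not with n. The two-sided p follows
the minimum-likelihood construction (sum of all outcome probabilities not
exceeding that of the observed count, with a 1+1e-7 relative fuzz); the
opposite-tail boundary is located by bisection on the unimodal pmf flank.
Agreement is verified against full-support enumeration (n ≤ 200, relative
error ≤ 1e-12) and against scipy's independent implementation at n = 10⁶
(≤ 1e-9).

Tests performed by `DNMBurdenModel.fit()`:

- **Rate test**: k = coding de novo SNVs within the callable denominator,
  n = callable CCDS bases, p₀ = null per-base per-generation rate
  (default 1.65×10⁻⁸; empirical control-study rates 1.28×10⁻⁸ and
  1.51×10⁻⁸ as alternatives). One-sided (greater) is the default
  alternative — the scientific hypothesis is an excess — with the
  two-sided minimum-likelihood value reported alongside; every report
  states which was used.
- **LoF excess**: k = case LoF SNVs among n = case coding SNVs, p₀ = the
  control cohort's LoF proportion. Because a published control table can
  be read with two denominators (LoF over coding SNVs, or over all DNMs),
  both constructions are computed and printed whenever they differ. A
  zero-LoF control uses the continuity proportion 0.5/(n+1), logged.
- **Diagnostic yield**: distinct trios carrying ≥ 1 predicted-damaging DNM
  in a known-disease-gene panel, over all trios; multiple hits in one trio
  count once.

A summary's `ccds_snvs` field holds the coding-SNV count restricted to the
callable denominator when that differs from the class-count total (the
packaged study cohort: 64 of 66 coding SNVs fell within the ≥ 10× CCDS
denominator; averages derived from each are reported separately).

Control cohorts ship as a packaged, versioned TSV of per-class counts. The
published control tables print frameshifts as a single row; the packaged
split into insertion/deletion is nominal and affects no statistic. No
multiple-testing machinery is applied: nominal p-values are reported, as
is conventional for these few pre-specified comparisons.

## Inherited recessive/X-linked screen

Candidate genotypes in recessive/X-linked disease panels, all Mendelianly
consistent by construction: hemizygous (male proband alt on X outside
pseudo-autosomal intervals, mother het, father ref), homozygous (both
parents het), and compound het (two proband hets in one gene, one per
parent). Trans/cis is resolved from parental genotypes only — no
read-backed phasing — and pairs where either variant is untyped in a
parent, or both hets trace to the same parent, are excluded and logged;
this is conservative and will miss true trans pairs with a double-carrier
parent. Variants must pass the rarity filter and be predicted damaging;
when no transcript models are supplied the screen judges deleteriousness
from predictor scores alone, as annotation-driven pipelines do. The
packaged recessive/X-linked panel is a small synthetic stand-in (see its
file header); real analyses should supply a curated clinical panel.

## Synthetic cohort generator

The generator emulates post-calling trio exome data on a toy genome
(~1 Mb, two contigs including an X, 13 multi-exon genes of 3–5 exons,
alternating strands), with a single seed governing all randomness and
per-trio substreams derived deterministically from it, so equal configs
give byte-identical output files.

- **Depth**: negative binomial per site and member, mean 135,
  overdispersion 4 — matching a high-coverage capture regime (median
  ~135×, ≥ 95% of targets at ≥ 10×); `depth_overdispersion=None` gives
  uniform coverage.
- **Inherited variants**: a cohort-level set of segregating coding SNVs
  with allele frequencies from a rare/common mixture (35% common at
  0.5–20%, the rest at 0.01–0.4%), parents drawn from Hardy–Weinberg and
  children by Mendelian transmission. Sites accumulate until the expected
  alt-carrying count per proband reaches `n_inherited_per_trio`.
- **DNMs**: per-trio counts Poisson(μ × callable bases); the toy default
  μ = 1.2×10⁻⁴ yields a few DNMs per trio over the ~18 kb toy exome in
  seconds, and study-scale rates (1.28–2.6×10⁻⁸ over ~6×10⁷ callable
  bases per proband) are ordinary config values. Classes are drawn from a
  mixture (55% missense, 18% synonymous, 6% nonsense, 3% canonical
  splice, 2% consensus splice, 12% frameshift, 4% in-frame — weighted
  toward the spectrum seen in affected cohorts) and placed by a planting
  routine whose postcondition is that the classifier assigns exactly the
  intended class. A configurable fraction (default 8%) is planted as
  mosaic at VAF 0.08–0.22; allele fractions are realised by binomial read
  sampling, so germline hets centre on 50%.
- **Artifacts**: three families the cascade must reject — parental alt
  reads at a proband het site, weak proband support (< 4 alt reads or
  < 20% VAF), and common variants (AF ≥ 0.5%) presenting as Mendelian
  violations. Parents at non-carrier sites show alt reads at a per-read
  error rate of 10⁻³.

The callable denominator per proband is `callable_fraction ×
ccds_length` and DNMs are planted only within it, so the planted rate and
the estimation denominator refer to the same base set. (The study-scale
callable total, ~6×10⁷ bases per proband, exceeds a haploid CCDS; whether
such totals are diploid-counted is not derivable from count tables alone,
so callable bases per proband is an explicit parameter, never inferred.)

What the generator does *not* emulate: read-level errors (no FASTQ/BAM),
mapping artifacts, indel realignment ambiguity, CNVs, relatedness or
contamination. Passing recovery tests therefore validates the filter
logic, not robustness to alignment pathology.

Rate-recovery experiments plant `mosaic_fraction=0`: a VAF-thresholded
caller censors sub-20%-VAF events by design, so planted mosaics would bias
any germline-rate estimator low — the same censoring affects real
cohorts, where the per-base rate is a germline rate.

## Numerical and degenerate-case choices

- Tail sums stop when increments fall below 1e-18 of the running total on
  the decaying side of the mode.
- p₀ ∈ {0, 1} degenerates to a point mass; handled explicitly.
- `dnm_rate` with a zero denominator raises; a summary without callable
  bases skips rate tests rather than guessing a denominator.
- Extraction output is sorted by (trio, chrom, pos, ref, alt); report JSON
  is key-sorted — both for byte-stable reruns.
- Unannotated DNM sites are retained with `gene="unknown"` and flagged
  rather than dropped: absence of annotation is not evidence of absence.
- A proband VAF at exactly the 20% support threshold is retained (rule is
  ≥), and at exactly the 25% mosaic threshold is not flagged (rule is <).

## Problem sizes used in validation

Simulation-backed checks run on the toy genome: type-I calibration of the
rate test uses 2,500 null draws at study-scale callable bases (p-values
cached per distinct count); rate recovery uses 500 simulated trios
(~450 extracted events, Clopper–Pearson 95% check); recovery/monotonicity
properties use cohorts of 10–40 trios. The whole suite runs in well under
a minute.

## Known limitations

- No genotype-likelihood-based trio calling: the proband genotype field is
  trusted, and borderline parental evidence is handled by read-count
  thresholds, not by a probabilistic model.
- Single worst-consequence per variant across supplied transcripts; no
  HGVS nomenclature, no NMD prediction.
- The compound-het phasing rule discards double-carrier-parent pairs.
- Panel membership is exact-symbol matching; no alias resolution.
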