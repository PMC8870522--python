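# Methods

## Problem and scope

`varcascade` implements a somatic variant discovery workflow for tumor
whole-exome data in cohorts where only some patients have a matched blood
(germline) sample, as used in low-burden lymphoma sequencing studies.  It
consumes the outputs of two variant callers per tumor — a GATK
HaplotypeCaller-style primary caller ("A") and a FreeBayes-style secondary
caller ("B") — plus a per-variant annotation table and per-target coverage
profiles, and produces filtered somatic variant lists, major/minor clonal
labels, copy-number segments and cohort summary tables.  Read alignment,
variant calling itself and consequence prediction are upstream of this
package and are consumed, not computed.

## Harmonization

Call sets are unioned by normalized variant key (chromosome, 1-based
position, ref, alt after shared suffix-then-prefix trimming).  When both
callers report a key, the record keeps caller A's read counts and quality
metrics and is marked provenance `both`; A-side precedence is stable under
re-merging.  Trimming is reference-free; full left-alignment would need
the reference genome, which is not an input of the pipeline — for the
direct output of the two callers, suffix/prefix trimming is what makes
equivalent representations collide.

Multi-base substitutions of equal allele length (MNPs, typical of the
secondary caller) are decomposed into one SNV per mismatching aligned
base.  Components inherit the parent's read counts and quality metrics —
the evidence is the same reads, so counts are never divided — and re-enter
the filter cascade individually.  A component whose SNV was also called
directly folds into that record (promoted to `both`).  Composite records
that change length *and* substitute bases cannot be resolved without
inspecting alignments, so they are quarantined to a separate table for
human review rather than guessed at.

## The exclusion cascade

Every variant is evaluated against every applicable predicate; reasons
accumulate with no short-circuiting, so per-reason tallies audit the full
cascade.  A variant is retained iff its reason set is empty.  Exclusion
criteria, with defaults:

| criterion | rule | default |
|---|---|---|
| site quality | QUAL < `qual_min` | 20 |
| strand bias | FS > `fs_max` | 60 |
| mapping quality | MQ < `mq_min` | 40 |
| MQ rank sum | MQRankSum < `mqrs_min` | −12.5 |
| quality/depth | QD < `qd_min` | 2 |
| quality/depth per AF | QD ÷ VAF < `qd_af_min` | 8.0 |
| read position | ReadPosRankSum < `rprs_min` | −20 |
| consequence | synonymous | — |
| 1000 Genomes | AF > `pop_1000g_max` (strict) | 0.02 |
| ExAC / gnomAD | AF ≥ `pop_maf_max` (inclusive) | 0.001 |
| depth | total reads < `depth_min` | 20 |
| alt support | alt reads < `alt_min` | 4 |
| blood (matched) | alt reads in normal > `blood_alt_max` | 3 |
| deleteriousness | CADD Phred < `cadd_min` (15 is kept) | 15 |
| rescue (unmatched) | gene not in matched somatic set and not cancer-flagged | — |

Boundary semantics follow the inequality direction and strictness of each
printed rule exactly; where a rule is strict the boundary value passes.

Two deliberate interpretations:

* **QD per allele frequency.**  The "QD/AF < 8.0" criterion is read as the
  literal ratio qd ÷ vaf compared against 8.0.  The alternative reading (a
  second QD threshold stratified by AF) is not well defined without more
  information, so the rule is exposed as `qd_af_rule` (`"ratio"` default,
  `"off"` to disable) rather than hard-coded.
* **Missing metrics never exclude.**  A variant cannot fail a test that
  was not computed; secondary-caller calls legitimately lack GATK-style
  rank-sum annotations, and excluding on absence would silently drop them.
  Every such pass is logged.

In matched mode the blood rule applies and the rescue rule does not; in
unmatched mode the reverse.  Because predicates are independent and reasons
accumulate, the retained set is invariant under evaluation order — a
property the test suite checks over 50 random predicate permutations — and
tightening any single threshold can only shrink the retained set.

The orchestrator always processes matched cases before unmatched ones,
because the rescue rule needs the somatic gene set of the fully filtered
matched cohort.

## Clonality

Within one sample, the retained variant with the highest VAF defines a
reference; variants with VAF ≥ 50% of the reference are *major clonal*
(present in the majority of tumor cells), the rest *minor clonal*.  If the
top variant rests on fewer than 25 reads, its VAF is too noisy to anchor
the cutoff and the reference becomes the mean of the two highest VAFs.
Degenerate cases are resolved the only self-consistent way: a
single-variant sample is its own reference (and major, even below 25
reads, since no second VAF exists); ties at the top VAF are broken by
genomic order, and the depth fallback looks at that specific variant's
depth.  Every non-empty sample has at least one major variant, since
VAF₁ ≥ mean(VAF₁, VAF₂)/2 under both reference rules.  "Total read
count" in the fallback is read as the variant's site depth — the only
per-variant reading.

## Copy-number calling

Per-target mean depths of a tumor/normal pair become
log2(tumor/normal) ratios, median-centered to remove library-size
differences.  Targets with normal depth < 10 reads are masked; a ratio
against near-zero reference coverage is noise.  A centered running median
(window 5 targets) absorbs single-target outliers; maximal runs of targets
whose smoothed ratio exceeds +0.3 (gain) or falls below −0.3 (loss), with
same-direction runs separated by fewer than 5 quiet targets merged, become
segments if they span at least 10 targets.

The gap-merge width of 5 matches the smoothing window: a noise dip
shorter than the window can momentarily pull the running median across the
threshold inside a true event, and such dips should not split a segment.
With the default thresholds this segmenter recovers injected single-copy
gains and losses spanning ≥ 10 targets with ≥ 90% reciprocal overlap in
≥ 95% of seeds, and calls nothing on diploid-only profiles at 100×.
Thresholds are deliberately conservative for single-copy events
(|log2(3/2)| ≈ 0.59, |log2(1/2)| = 1 versus a 0.3 bar); all parameters
are exposed.  GC-content correction is not applied — an extension point
for real capture data, where GC waves would first need removing.

Cohort CNA statistics (median and range of events per case) are computed
over cases carrying at least one event; zero-event cases are reported
separately.  Whole-chromosome aggregation into trisomy nominations is out
of scope.

## Coverage QC

Mean and median target coverage are length-weighted over targets, along
with the fraction of target bases above 50×.  Samples with mean target
coverage below 20× are flagged excluded and skipped by the pipeline:
coverage that thin cannot support the cascade's read-support thresholds.

## Cohort summarization

Per-case summaries tally retained variants, consequence classes,
major/minor counts, mutated genes and CNA counts.  Cohort burden over a
subset (matched / unmatched / all) reports the summed variant count, the
size of the union of gene sets (shared genes counted once), the per-case
median and range, and consequence percentages computed as count ÷ subset
total × 100 rounded to the nearest integer with ties rounding up.
Recurrence is counted at case level: a gene is recurrent iff mutated in
more than one case, however many variants hit it within a case.

## The synthetic cohort generator

The generator emulates the statistical structure the cascade assumes, with
defaults shaped like a small salivary-gland lymphoma exome cohort: 12
matched and 5 unmatched cases; per-case somatic burden drawn from a
low/high mixture (Poisson mean 7 versus 40, high-burden probability 0.18,
matching a mostly-quiet cohort with a high-burden minority); 30 germline
and 10 artifact events per case; mean depth 130×; major-clone VAF 0.35
with subclonal VAFs uniform on [0.05, 0.15]; 10% of somatic events emitted
as two-base MNPs in caller B with the constituent SNVs in caller A; 10%
reported by caller B only (with rank-sum metrics absent, as a
FreeBayes-style caller would leave them).

Read counts are binomial draws of alt reads given Poisson depth and the
assigned VAF — the simplest error model that exercises boundary behaviour.
Germline events appear in tumor and matched blood with blood alt reads
forced above 3, so the blood rule must remove them; 70% carry common
population frequencies (removable by the population filters even without
blood), 30% are rare "personal" variants that only the unmatched rescue
rule can catch.  Artifacts violate one or two quality criteria by
construction.  Somatic, germline and artifact events draw genes from
disjoint pools so cohort-level gene logic (recurrence, rescue) has known
truth; the first 25 somatic-pool genes carry the tumor-suppressor/oncogene
flag.

Every emitted primitive variant has one truth row whose
`expected_surviving` flag is precomputed by a brute-force restatement of
the retention rules written directly from their printed form and kept
separate from the cascade implementation, so the two can be compared as
implementation versus oracle; the acceptance suite requires 100% agreement
over a 20-case mixed cohort (~200 records per case).  For unmatched cases
the rescue truth depends on the matched cohort's surviving gene set, so
`simulate_cohort` generates matched cases first and threads that set
through.

Determinism: per-case generator substreams are derived from the master
seed and a CRC32 of the case id, so identical (config, seed) yield
byte-identical files regardless of generation order.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: read-level errors and mapping ambiguity (quality
metrics are drawn, not recomputed from reads), tumor purity and copy-number
distortion of VAFs, GC-dependent coverage waves, FFPE artifact spectra,
and indel representation ambiguity beyond suffix/prefix trimming.  The
tests demonstrate that the cascade's logic is exact and order-invariant,
not that the thresholds are optimal for any particular assay.

## Problem sizes

Default test and acceptance runs use cohorts of up to 20 cases with ~200
records per case, 1600–2000 capture targets, and 20-seed repetitions for
stochastic recovery properties — sizes chosen so the full suite exercises
every cohort-level code path while completing in seconds on one CPU.

## Known limitations

* Composite MNP+indel records are quarantined, not resolved; the matching
  manual step (visual alignment review) has no deterministic equivalent.
* One consequence per variant is consumed as given; transcript arbitration
  is out of scope.
* The CNA caller reports segment-level gains/losses only: no allele-specific
  copy number, no B-allele-frequency integration, no purity correction.
* Population-frequency and CADD annotations are trusted inputs; no live
  database queries are made.
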