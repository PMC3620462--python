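# Methods

## Scope and data model

`crossvar` consumes single-sample SNV call sets (VCF), per-base depth and
mean-mapping-quality tracks (bedGraph-like TSV), a reference FASTA, a
repeat annotation (BED) and a SNP-array genotype table (4-column TSV). It
does not touch reads or alignments: alignment and variant calling are
upstream of the package, and pileup base counts are an input (here,
produced by the simulator). Only biallelic single-nucleotide records are
represented; multiallelic VCF records are split and non-SNV alleles
dropped. VCF and chip positions are 1-based, BED/track intervals 0-based
half-open, and conversion happens only at format boundaries; internal site
keys are `(contig, 1-based position)`. Contig names must match across
inputs exactly — there is no `chr`-prefix aliasing, and unknown contigs
abort the run with the offending inputs listed.

## Concordance classification

Sites called in both platforms are concordant only when alt allele *and*
zygosity agree; any disagreement (zygosity or alt) is discordant, with alt
disagreement additionally flagged on the record, since a three-relation
scheme (concordant / discordant / specific) has nowhere else to put it.
The four categories partition the site union, and swapping the platforms
swaps the two specific categories while preserving the other counts — both
properties are tested against a brute-force per-site dictionary comparison.
Heterozygosity rates and repeat-overlap fractions are computed per
category; for the repeat test a 1-based position *p* occupies 0-based
offset *p*−1.

## Chip comparison

A call's implied unordered genotype is {alt,alt} (HOM) or {ref,alt} (HET)
and is chip-concordant iff it equals the chip's allele pair. Sites absent
from the chip are excluded from all rate denominators. A chip hom-ref
genotype at a sequenced SNV site counts as chip-discordant (the call
asserts a variant the chip denies) and is flagged distinctly. In the
classification table the discordant category appears once per platform,
because the two platforms' genotypes — hence chip statuses — differ there
by construction; HOM/HET sub-rows are stratified by the reported platform's
sequencing zygosity, and their printed percentage is the share of the
(category × chip-status) group total, not a within-stratum rate. Median
depths use the mean-of-middle-two convention, which is why half-integer
medians occur.

## High-confidence heterozygotes

`is_confident_het` requires pileup total > `min_depth` (default 20) and
second-most-frequent-base fraction > `min_second_fraction` (default 0.30),
both strictly: a total of exactly 20 or a second fraction of exactly 30%
fails. When bases tie for second place, any base other than the single most
frequent may serve, so the maximum qualifying fraction is used — the most
permissive reading of "second most frequent base". The depth entering the
criterion is the pileup total, not the caller's DP annotation (the two can
differ when a caller filters reads; the pileup is what the criterion
inspects). The filter is invariant under permutation of base labels, and
adding reads of the second base never flips a passing site to failing while
the depth condition holds.

## Callability

Per-base classification follows fixed precedence: depth 0 → no-coverage;
0 < depth < 4 → low-coverage; depth ≥ 4 and MQ < 10 → poor-MQ; else
callable. Thresholds are inclusive ("minimum equal to 4/10" read
literally) and configurable. Coverage is evaluated before MQ, so a 2-read
base with MQ 0 is low-coverage. Tracks are run-length encoded; runs tile
each contig exactly and adjacent runs differ, with a round-trip identity
tested up to 10⁶ bases.

Merging approximates re-analysis of a pooled alignment at the track level:
per-base depths add, and the merged MQ is the depth-weighted mean of the
platform mean-MQs (zero-depth platforms contribute nothing). Weighted-mean
is the default because a pooled alignment's mean MQ *is* the read-weighted
mean; max/min variants would bound rather than estimate it. Under this
construction any base callable in one platform stays callable after
merging whenever the other platform's reads do not drag the weighted MQ
below threshold; on the simulated two-level MQ data the merged callable
set is a strict superset of each platform's, which is asserted, not
assumed. Headline "callability" means the CALLABLE state only; a secondary
figure including poor-MQ bases is reported alongside, since the two
conventions coexist in practice.

The callability gain is the merged callable percentage minus the mean of
the two platform percentages, reported at 2 dp. Its final rounding breaks
ties toward zero so a gain is never overstated — gains of exactly *x*.xx5
occur routinely because the inputs are themselves 2-dp percentages — while
the base-count equivalent (gain × genome length / 100) uses the unrounded
value. All other percentages round half away from zero at 2 dp, applied
once at render time over exact integer/decimal arithmetic; empty
denominators render "NA", never "0.00%".

The merged-vs-platform accuracy comparison builds, for each dataset, the
chip-concordant/discordant counts of its calls inside its own callable
regions, and tests each platform against the merged dataset with a Pearson
χ² (1 df, no continuity correction by default — counts in this design are
large; a Yates flag exists) and the cross-product odds ratio, left
undefined (no Haldane correction) when a zero cell occurs. Because no
merged alignment exists at the calls level, the merged call set is defined
as: concordant and specific calls as-is, discordant sites resolved in
favour of the deeper platform's call.

## Synthetic data generator

The generator emulates the study conditions the analyses expect, not read-
level sequencing. Defaults (all configurable in `SimConfig`):

| parameter | default | rationale |
|---|---|---|
| genome_length / n_contigs | 200 kb / 2 | desk-scale yet large enough for 5,000 sites at < 1 site / 10 bp |
| repeat_fraction | 0.30 | realistic repeat load; supplies enough repeat sites for specific-call placement |
| n_variant_sites | 5,000 | the size at which parameter recovery is assessed |
| het_fraction | 0.60 | typical heterozygous share of a human SNV set |
| mean depth p1 / p2 | 20× / 35× | echo the two platforms' median depths |
| dropout p1 / p2 | 0.5% AT-biased / 0.2% uniform | coverage holes; AT bias emulates sequencing-by-synthesis coverage bias |
| het→hom error | 0.2·exp(−d/5) | decays with depth d; functional form is a simulator choice (only the qualitative depth dependence is established) |
| min_call_depth | 4 | sites below it are uncalled |
| platform_specific_rate | 0.15 | per platform, suppressed from the other call set |
| repeat_enrichment | 0.70 | share of designated specific sites placed in repeats |
| chip_site_fraction / chip error | 0.50 / 0.10 | array coverage of variant sites; chip-side het→hom rate |
| low_mq_repeat_fraction | 0.05 | whole repeat intervals marked MQ 5 |

Design choices worth recording:

* **Exact-count designation.** Proportions that downstream stages must
  recover (het fraction, chip flips, repeat placement of specific sites)
  are realised by designating exactly `round(p·n)` of a shuffled list
  rather than by independent coin flips. Marginals are unchanged
  (a conditioned binomial), and recovery error then reflects only the
  downstream error processes, not designation noise.
* **AT-rich repeats with controlled motif composition.** Repeat blocks are
  tandem copies of 2–6-mers built with exactly ~70% A/T letters, so every
  block — not just the average — is AT-rich. This matters twice: AT-biased
  dropout (windows sampled ∝ (AT fraction + 0.01)⁴) concentrates in
  repeats, and poor-MQ repeat intervals are reliably AT-enriched, giving
  the non-callable composition its expected AT excess without relying on
  lucky motif draws.
* **Suppression, not simulation, of platform-specific calls.** Specificity
  operates on truth sites (disjoint designated sets per platform,
  suppressed from the other platform's calls) because the pipeline
  consumes calls, not reads. Dropout adds a second, smaller source of
  specific sites; the designated sets dominate, keeping the realised
  repeat enrichment near 0.70.
* **One RNG stream per output role**, seeded from `(seed, crc32(role))`,
  so adding an output file never perturbs the others; a fixed seed yields
  a byte-identical bundle.
* **Pileups are a simulator output** (even ref/alt split for het calls,
  all-alt for hom, 1% uniform miscalls): generating them from alignments
  is out of scope, but the het-confidence stage needs them.

What the generator does **not** emulate — linkage structure, indels/SVs,
base-quality distributions, strand bias, GC-dependent depth waves,
reference errors, real repeat families — bounds what passing tests show:
they validate the analysis logic and its invariants under the stated error
model, not platform behaviour on real genomes. Genome-scale counts from
real studies (millions of SNVs, genome-wide callability) require the
original alignments and are explicitly not reproduced; published count
pairs are instead used as *inputs* to verify the rate arithmetic.

## Problem sizes

Defaults keep every stage desk-scale: the full pipeline on the default
bundle runs in a few seconds, the complete test suite in well under a
minute, and `scripts/acceptance.py` in under ten seconds, with the
1,000-pair classification oracle sweep and the 10⁶-base RLE round-trip the
largest single items.

## Known limitations

* Merged-data behaviour is a track-level approximation; a true pooled
  re-call could rescue or lose calls in ways the merged call-set heuristic
  cannot.
* Chip genotypes are modelled per-site with a single error mode (het→hom);
  probe-level effects, missingness patterns and hom→het errors are absent.
* Diploid autosomal logic only; hemizygous chromosomes, gVCF blocks and
  phasing are out of scope.
* The MQ model is two-valued (60 / 5); real MQ distributions are
  continuous and alignment-dependent.
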