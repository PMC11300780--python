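# Methods

## Scope and model

The package implements a deterministic prioritization cascade for
tumor/normal cohorts. It consumes caller outputs — it never aligns reads or
calls variants itself — and everything downstream of the VCFs is pure
computation: the same inputs always produce byte-identical retained sets,
traces and reports. Variant identity throughout is the normalized
(chrom, pos, ref, alt) tuple; genotype and quality fields never influence
consensus or filtering, only caller *presence* does. Chromosome names are
compared verbatim (no silent `chr` harmonization).

### Normalization

Shared suffix is trimmed first, then shared prefix with the position
advanced, keeping one anchor base for indels. When a reference-context
callable is supplied, indels are additionally left-aligned to their 5'-most
equivalent position (vt-style: trim matching terminal bases, extend left
with the reference base whenever an allele empties). Both modes are
idempotent. Without a reference, an indel inside a repeat stays where the
caller put it; cross-caller matching then assumes callers normalize
consistently, which is why supplying a reference is preferred when caller
provenance is mixed.

### Filter semantics worth knowing

- Boundary semantics follow the rule wording exactly: normal VAF ≥ 5%
  removes (inclusive); "> 20 ref reads" and "> 1% population frequency" are
  strict, so 20 reads and exactly 1% are retained; "tumor VAF < 2 × normal
  VAF" is strict, so exactly 2× is retained.
- A zero-depth normal defines normal VAF = 0, so the ratio rule reduces to
  `tumor VAF < 0` and can never fire; no pseudo-counts are invented.
- The panel of normals is cohort-wide by default ("any normal control"),
  with `normal_scope: matched` restricting subtraction to the matched pair.
- Blacklist propagation is two-pass: read-support verdicts are computed for
  every sample first, then any key failing rules 2–4 anywhere is removed
  everywhere (original stage where it failed, `BLACKLIST` elsewhere). The
  population-frequency rule is key-intrinsic and fires identically in every
  sample, so it is not propagated.
- Variants absent from the recount table are removed with a dedicated
  `MISSING_COUNTS` trace rather than silently kept: the recount step is
  assumed to cover every candidate.
- In the predictor vote, verdictless predictors are excluded from the
  denominator by default (`vote_denominator: all` keeps all six); ties
  ("at least half") count toward removal; the SPIDEX |z| ≥ 2 bound is
  inclusive in both the silent-rescue and vote-override contexts. Nonsense
  and splice-site variants are subject to the vote like any substitution
  (a config flag can exempt truncating classes; off by default).
- Every removal emits one trace record, and per-sample, per-stage counts
  satisfy `|input| = |retained| + |traces|` — the audit trail reconstructs
  the cascade exactly.

### Copy number and two-hit calls

Gene copy state is the base-length-weighted mean of overlapping SEG
segment log2 ratios (`gene_summary: min` switches to the most-deleted
segment, the GISTIC-like convention). Thresholds: amplification ≥ +0.8,
loss ≤ −0.6 (the array-analysis settings this pipeline mirrors) and deep
deletion ≤ −1.3, a package decision: −1.3 log2 corresponds to fewer than
one copy in a diploid background, separating homozygous from single-copy
loss; it is configurable because the boundary is not externally fixed. A
gene with no overlapping segment is called NEUTRAL with a warning rather
than failing the run. Fraction of genome altered uses |log2| ≥ 0.2 over
segmented bases (the cBioPortal convention), configurable.

Mutation zygosity is inferred from tumor VAF: ≥ 0.7 is treated as
homozygous — high enough to exclude balanced heterozygotes while tolerating
purity and contamination — and two distinct functional variants in one gene
default to homozygous-equivalent (compound biallelic assumption; phasing is
unavailable, so this is explicitly an assumption with an off-switch). The
two-hit truth table: deep deletion, homozygous mutation, or het mutation
plus loss (LOSS or DEEP_DEL) ⇒ TWO_HIT; mutation-only or loss-only ⇒
ONE_HIT; otherwise WT. Mechanisms accumulate, so a deep deletion over a
homozygous mutation records both.

### Statistics

- Gene-set enrichment uses the upper-tail hypergeometric probability
  P(X ≥ k) computed through scipy's stable log-gamma machinery; the test
  suite checks it against exact big-integer pmf enumeration for all
  population sizes ≤ 60. Nominal p ≤ 0.05 with no multiple-testing
  correction is the default (the cross-sample recurrence requirement is the
  de-facto replication filter); BH-FDR is available. The gene universe
  defaults to the expressed-gene set.
- The one-tailed Mann–Whitney comparison is exact by enumeration of all
  rank assignments with mid-rank ties up to a pooled size of 20, and a
  tie-corrected normal approximation with continuity correction beyond.
  A fully degenerate comparison reports p = 1 with a warning.
- TMB divides the somatic mutation count by a configurable callable
  territory, default 38 Mb (a typical exome callable size), making the
  statistic well-defined and reproducible.
- Validation rate counts a variant as validated when ≥ 5% of its
  orthogonal capture reads support the alternate allele; only variants with
  a capture entry enter a sample's denominator, and samples with nothing
  assessed are excluded from the cohort median (midpoint convention for
  even counts).

## The synthetic cohort generator

`synthetic_data.generate_cohort` emulates the targeted study design on a
6-chromosome, 300 Mb genome carrying 1,998 genes. Defaults:

- **15 tumor/normal pairs**, depths Poisson(100) in both tissues.
- **Somatic load** negative-binomial, mean 200/tumor with ~60% in
  coding/splice territory, giving ≈ 120 coding variants per tumor; VAFs are
  Beta(2, 5) rescaled above a 0.15 detection floor (a caller cannot emit a
  call with no supporting reads, so planted VAFs represent detectable
  clonal fractions). Read counts are binomial at the drawn depth.
- **Germline**: a population pool of 800 shared het sites (VAF 0.5 in both
  tissues), 400 drawn per sample — scaled far below a real exome's germline
  load but large enough to exercise the panel and normal-VAF filters; 10%
  of pool sites carry PopFreqMax > 1%. A small fraction (2%) of somatic
  variants also carry high population frequencies so the POPFREQ stage has
  real work.
- **Caller error**: per-caller Bernoulli detection with sensitivities
  0.95/0.90/0.85 and 20 intergenic false positives per caller per sample.
  Detection is independent of the drawn read counts: the callers saw the
  actual reads, while the recount table is a separate draw — this is what
  makes the perfect-sensitivity limit exactly recoverable.
- **Annotations** are generated consistently with the planted truth:
  predictors return the planted verdict with probability 0.9 (10% missing;
  indels all-missing, as predictors typically score substitutions only);
  spliceogenic variants get |z| drawn in [2, 4], everything else stays
  below 2. The SNV spectrum is C>T-heavy and C>A-poor, a never-smoker-like
  mix.
- **Engineered structure**: eight designated candidate genes each
  functionally mutated in three samples and given external-cohort counts
  ≥ 3 (all other genes < 3, so the candidate list is exactly the engineered
  set); a 6q-like 20 Mb single-copy deletion; a focal homozygous deletion
  over the designated tumor suppressor G1800; and a two-hit plan covering
  every mechanism (deep deletion ×2, homozygous mutation at VAF 0.9 ×2,
  het mutation VAF 0.35 plus loss ×2, mutation-only, loss-only). Background
  somatic variants never land in designated genes, so the planted gene-level
  truth stays exact.
- **Determinism**: one global seed with per-sample substreams
  (`default_rng([seed, 1000 + sample_index])`), so adding a sample does not
  perturb earlier samples' draws and a fixed seed yields a byte-identical
  file tree.

Each emitted variant carries a truth record including a `functional` flag
computed from the planted attributes by mirroring the cascade definitions.
That flag is exact when predictor concordance is 1 and the missing rate 0
(the no-noise test configuration); under the noisy defaults predictor
errors can legitimately flip individual vote outcomes, which is why exact
set-equality tests run on no-noise cohorts and the noisy cohorts are
checked against closed-form detection expectations (within 4 SD of the
binomial consensus count) instead.

### What the generator does not emulate

No read-level artifacts (strand bias, mapping error, FFPE damage), no
sequence-context mutational signatures beyond the six-class mix, no
subclonal copy-number or purity/ploidy structure, no allele-specific copy
number, and caller errors are independent across callers (real callers
share failure modes). Passing the recovery tests therefore demonstrates
the pipeline's bookkeeping and decision rules are exact under the stated
error model — not that the thresholds are optimal for any particular real
cohort.

## Problem sizes in the shipped tests

The test suite and acceptance script generate their cohorts at run time:
15 pairs × (~200 somatic + 400 germline + 120 caller false positives) per
sample, which keeps a full generate-plus-pipeline cycle to a few seconds
while leaving > 3,000 planted somatic variants for the distributional
checks. The exhaustive oracles (3^6 predictor vectors, the 3×4 two-hit
grid, hypergeometric populations to N = 60, rank-sum enumerations to pooled
n = 12) are complete, not sampled.

## Known limitations

- Homozygosity from tumor VAF conflates copy-neutral LOH, high purity and
  true homozygous mutation; without SNP BAFs or allele-specific copy number
  this is the best available proxy and is flagged in outputs.
- The compound-het-as-biallelic assumption can over-call TWO_HIT when two
  variants are in cis.
- Multi-interval genes collapse to a spanning interval, which can overlap
  unrelated segments in genes with very long introns.
- The expression filter is binary membership; partial or sample-specific
  expression is out of scope.
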