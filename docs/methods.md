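# Methods

## Scope and model

`rarelex` implements a recurrence-based prioritization of rare,
predicted-damaging ("high-impact") exonic variants in a three-cohort
reading-disorder design: a discovery cohort of unrelated dyslexia cases, an
independent follow-up cohort split into reading-difficulty (RD) cases and
typically developing (TD) controls, and small nuclear families of discovery
probands used only for segregation. The underlying genetic model is
qualitative: rare heterozygous variants of individually large but variably
expressed effect, prioritized by recurrence across unrelated carriers rather
than by a formal burden statistic, with exact carrier tests applied
post hoc to the single most recurrent variant.

## Filter definition and its edge cases

A call is high-impact iff it passes, in fixed order:

1. **qc** — site `QUAL >= min_qual` (default 20) and genotype depth
   `DP >= min_depth` (default 10). A missing depth fails: there is no
   evidence the genotype is supported. "Quality" is the site QUAL by
   default; `Thresholds.qual_source` records the alternative (genotype-level
   quality) as a declared switch for datasets where site QUAL is
   uninformative.
2. **rare** — gnomAD-NFE `AF < max_af` (default 0.01). A variant absent
   from gnomAD counts as rare: absence from a large reference panel is
   evidence of rarity, and novel variants must survive (one candidate
   variant in the data this emulates has no population record at all). Only
   the NFE frequency is consulted; no per-population maximum is taken.
3. **consequence** — synonymous, intronic and intergenic variants are
   removed; everything else (missense, stop, frameshift, splicing, UTR,
   unknown exonic) is retained.
4. **damaging** — unanimous "damaging" verdicts from the five predictors
   (SIFT, PolyPhen2, LRT, MutationTaster, FATHMM), or a ClinVar
   pathogenic / likely-pathogenic assertion, which rescues regardless of
   predictors. A missing predictor call breaks the consensus (conservative);
   the exclusion log counts these so the effect of that choice is auditable.

The removal conditions are applied as OR-of-removals (a call failing any one
is removed); each removed call is logged with its first failing predicate in
the order above. Hom-alt genotypes are retained — the heterozygosity of all
observed candidate variants is a finding, not a rule — and carrier counting
downstream is per individual, not per allele.

## Phenotype classification

Scores are standardized against the population distribution
(`pop_mean = 100`, `pop_sd = 15`). Boundary strictness follows the
selection criteria's wording literally:

| class | rule |
|---|---|
| discovery case | min reading z **≤ −1** (inclusive) and PIQ z ≥ −1 |
| RD case | min over {SWR, NWR, ACC, COMP, RR} z **< −1** (strict), PIQ z ≥ −1, no ASD diagnosis |
| TD control | SWR z **> 0** (strict), PIQ z ≥ −1, no ASD diagnosis |
| mild | min reading z < −1 **or** mean reading z ≤ −0.25 |

Whether the discovery "1 SD below" bound was inclusive is not decidable from
the selection criteria as stated; inclusive was chosen and
`Thresholds.discovery_reading_inclusive` exposes the alternative. Missing
measures are ignored (min/mean over present measures); a profile with no
reading measures is unclassifiable and raises rather than silently counting
as unaffected. Parents are never classified from scores — their status comes
from self-report, with "maybe" kept distinct from "no". The ASD exclusion
applies to the follow-up classes only; the discovery cohorts excluded such
diagnoses at recruitment, which the simulator models as their absence.

Twin selection seeds a generator from the run seed plus the pair id, so the
choice is reproducible per pair and unbiased across pairs.

## Gates

The discovery gate requires `min_discovery_cases = 3` distinct unrelated
discovery carriers per gene. Sequenced relatives never enter recurrence
counts; they exist for segregation only. The follow-up gate additionally
requires `min_rd_cases = 1` RD carrier (any variant in the gene) and at most
`max_td_case_variant_carriers = 0` TD carriers of a *case-carried* variant.
The TD exclusion is variant-level, not gene-level: the gene-level reading
would disqualify genes whose TD carrier holds an unrelated variant, which
contradicts the worked example this package reproduces; such genes are
flagged (`flag_td_variant_differs`, the report's asterisk) instead. No
significance threshold gates candidacy.

## Statistics

- Cases vs TD controls: two-sided Fisher exact test on the carrier 2×2
  table (scipy), cross-checked in the test suite against full
  hypergeometric enumeration for margins ≤ 30.
- Cases vs population: one-sided (greater) exact binomial test of the
  observed alternate-allele count among `2 × N_cases` alleles against a
  fixed population frequency. The population panel's allele denominator is
  orders of magnitude larger than the cohort, so treating its frequency as
  known is the appropriate approximation; a carrier-based 2×2 against the
  panel is not reconstructible without its denominator. Cases pool discovery
  and RD carriers (N = 91 at default study conditions).
- Cohort contrasts: Welch two-sample t-tests (group sizes and variances
  differ), absolute t reported, `p_adjusted = min(1, p × bonferroni_m)` with
  `bonferroni_m = 6` applied uniformly to every tested measure.
- Gene-set overlap: upper-tail hypergeometric probability; the background
  gene-universe size is an explicit argument (CLI default 20 000, an
  assumption, since overlap P-values are meaningless without a stated
  universe).

## Segregation

Affection per member: children affected iff discovery-case or mild criteria
hold, unaffected iff classifiable and neither; parents from self-report
("maybe"/missing → unknown). "Some form of reading difficulties" is
operationalized as (case ∨ mild ∨ parent self-report yes). Unknowns are
excluded from violation checks — the dominance claim is conditioned on
members with available data. A family is *violated* iff any carrier is
unaffected; *uninformative* with fewer than two genotyped members of known
affection (preventing vacuous support); otherwise *consistent*. No LOD or
transmission statistics are computed; the assessment is deliberately the
descriptive pattern classification the design supports.

## Synthetic cohorts

`simulate_cohort` emulates the study conditions; its defaults are fixed at
the analyzed design: `n_discovery = 53`, `n_rd = 38`, `n_td = 82`,
`background_hi_rate = 11` filter-passing variants per individual, four
nuclear families, six DZ twin pairs.

- **Background variation.** A pool of exonic missense sites with AFs drawn
  log-uniform on `af_range = [1e-5, 9e-3]` — a heavy-tailed stand-in for the
  rare end of the site-frequency spectrum — sized so the expected
  per-individual count of filter-passing variants equals
  `background_hi_rate` after QC losses. Each individual carries each site
  independently with probability 2·AF (Hardy–Weinberg heterozygote rate),
  so counts are approximately Poisson and occasional background genes
  acquire two or three carriers, as in real cohorts of this size. A
  `predictor_discordance_rate` fraction (default 0.15) of sites get one
  tolerated predictor call and must be excluded by the consensus rule; a
  `qc_fail_rate` fraction (default 0.05) of carried genotypes get
  sub-threshold depth.
- **Planted variants** specify exact carrier counts per cohort and an
  additive displacement of the latent reading liability
  (`liability_shift`, default −0.8 z) applied equally to all reading
  measures of non-control carriers. The default plant set mirrors the
  recurrence structure the pipeline is meant to detect: a strongly
  recurrent variant (5 discovery / 1 RD / 0 TD), two moderate genes
  (3/1/0), and a decoy whose case variant also appears in a TD control.
- **Phenotypes** are multivariate normal over the battery with exchangeable
  correlation `measure_corr = 0.6`, centered on the cohorts' observed mean
  z-profiles, then rejection-sampled so every emitted individual satisfies
  its class definition (and follow-up individuals satisfy exactly one of
  RD/TD, making the selected cohorts a partition by construction). DZ
  co-twins share each planted variant with probability 0.5.

What the simulator does **not** model: linkage disequilibrium and haplotype
structure, relatedness beyond nuclear families, ascertainment history of the
original recruitment waves, genotype uncertainty beyond a depth cutoff, and
any realistic gene length/constraint variation (background genes are
exchangeable). Passing tests therefore demonstrate the pipeline's logic and
calibration under the stated generative model, not robustness to those real
data features.

At default conditions background genes occasionally pass both gates (the
design's false-positive channel — with ~1 000 genes carrying qualifying
variants, spurious (≥3, ≥1, 0) patterns arise by chance); the exact-recovery
test therefore runs at a scaled-down background (`background_hi_rate = 2`,
`af_range = (1e-5, 5e-4)`) where spurious recurrence is improbable, checked
over 20 seeded cohorts.

## Numerical and format choices

- VCF I/O uses pysam. pysam stores INFO floats in single precision, so AF
  and QUAL are normalized to 6 significant digits on read and written with
  at most 6 significant digits, making write-then-read round-trips exact.
- Variant keys are `chrom-pos-ref-alt` with a leading `chr` stripped on
  read; coordinates are 1-based as in VCF. Multiallelic sites are split one
  record per ALT with genotypes recoded per allele.
- ClinVar strings are matched case-insensitively; combined
  pathogenic/likely-pathogenic labels count as pathogenic; "conflicting
  interpretations of pathogenicity" does not.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical parameters give byte-identical
  output files.
- Degenerate inputs: an empty call set yields an empty report with an
  explicitly undefined mean; a zero population frequency with observed
  carriers yields p = 0 with a warning; identical constant groups give
  t = 0, p = 1, while zero-variance unequal groups raise.

## Problem sizes

The test and acceptance runs simulate full-size cohorts (173 selected
individuals plus relatives and twins, ~4–5 thousand variant records, ~11
passing variants per individual) in a few seconds each; the 20-cohort
recovery check uses the scaled-down background above and completes in under
half a minute. These sizes were chosen to match the emulated study design
while keeping the complete suite fast enough to run on every change.
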