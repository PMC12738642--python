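# rarelex

Rare-variant prioritization for whole-exome reading-disorder cohorts.

`rarelex` is a tested, reusable implementation of a candidate-gene
prioritization pipeline for dyslexia / reading-difficulty exome studies of
modest size, where burden tests are underpowered and prioritization rests on
recurrence of *high-impact* variants across unrelated cases. It is aimed at
statistical geneticists and bioinformaticians who need the whole chain —
variant filtering, phenotype-based cohort classification, recurrence gating,
exact carrier tests and pedigree segregation — as importable, auditable
Python rather than a one-off analysis script.

## The method

**High-impact filter (ACMG PM2 + PP3 style).** A genotype call survives iff

- QC: site `QUAL >= 20` and genotype depth `DP >= 10`;
- rarity: gnomAD-NFE allele frequency `< 0.01`, with absence from gnomAD
  counting as rare;
- consequence: not synonymous, intronic or intergenic;
- deleteriousness: unanimous "damaging" from SIFT, PolyPhen2, LRT,
  MutationTaster and FATHMM, **or** ClinVar pathogenic / likely pathogenic.

The same criteria apply to every cohort; after filtering, a typical exome
retains ~11 high-impact heterozygous variants.

**Phenotype classes** from scores standardized to z = (raw − 100)/15:
discovery cases need min reading z ≤ −1 with PIQ z ≥ −1; replication (RD)
cases need a follow-up battery score strictly below −1 with PIQ z ≥ −1 and
no ASD diagnosis; TD controls need SWR z > 0 with PIQ z ≥ −1; relatives are
"mild" with one reading z < −1 or mean reading z ≤ −0.25. When both twins of
a pair qualify, one is selected at random, reproducibly from a seed.

**Gene gates.** A gene is a candidate when high-impact variants occur in
≥ 3 unrelated discovery cases (carriers counted as distinct individuals);
it warrants follow-up when additionally ≥ 1 RD case carries a high-impact
variant in the gene (any variant) and **no** variant carried by a discovery
or RD case appears in a TD control. The TD exclusion is variant-level: a
TD-only variant in the same gene is flagged (the report's asterisk), not
disqualifying.

**Statistics.** For a recurrent variant with carrier counts
(k cases of N, 0 controls of M) the package computes the two-sided Fisher
exact test on the carrier 2×2 table and a one-sided exact binomial test of
the 2N case alleles against a fixed population allele frequency p₀, plus the
case allele frequency k/2N and its fold-change over p₀. Cohort phenotype
contrasts use Welch t-tests with Bonferroni adjustment, and candidate lists
can be compared against external gene sets with the upper-tail
hypergeometric overlap test.

**Segregation.** Per family and focal variant, members are affected
(children: case or mild; parents: self-report "yes"), unaffected, or
unknown. The pattern is *consistent with a dominant effect under variable
expressivity* when no carrier with known phenotype is unaffected; a single
unaffected carrier makes it *violated*; fewer than two informative genotyped
members make it *uninformative*. Affected non-carriers never violate.

Because the underlying study's individual-level data are not redistributable,
the package ships a synthetic-cohort simulator (`rarelex.simulate`) that
emits annotated VCF + phenotype TSV + PED files with the same statistical
structure (cohort sizes 53/38/82, ~11 passing variants per individual,
planted recurrent genes, correlated reading measures, DZ twin pairs, nuclear
pedigrees) together with truth tables, so every stage is testable end to end.

## Worked example

```bash
python examples/04_association_tests.py
```

```
case allele frequency: 3.3%  (4.21-fold the population frequency of 0.78%)
Fisher exact (cases vs TD controls, two-sided): P = 0.030
exact binomial (case alleles vs population AF, one-sided): P = 0.0033
```

Six heterozygous carriers among 91 cases give a case allele frequency of
6/182 = 3.3%, about 4.2× the population frequency of 0.0078335; the carrier
excess over 82 controls is nominally significant (P ≈ 0.03) and the allele
count exceeds the population expectation at P ≈ 0.003.

```bash
python examples/03_prioritize_worked_example.py
```

```
 CACNA1D: discovery=3 rd=1 td=0   -> PASS
 CACNA1G: discovery=4 rd=1 td=0   -> PASS
    CFTR: discovery=7 rd=1 td=1   -> fail (case variant in TD)
   CLDN3: discovery=5 rd=1 td=1*  -> PASS
   CNGB1: discovery=3 rd=2 td=0   -> PASS
      CP: discovery=3 rd=1 td=1*  -> PASS
```

Exactly five genes pass both gates; the CFTR-like gene is excluded because
one of its discovery variants recurs in a control, while the asterisked TD
carriers of CLDN3 and CP hold a *different* variant and are therefore only
flagged. The other examples cover filtering (`01`), classification (`02`),
segregation (`05`) and the full simulate-analyze-report loop (`06`).

A thin CLI mirrors the library:

```bash
rarelex simulate --seed 1 --out-dir cohort/
rarelex run --config config.yaml
```

## Layout

- `src/rarelex/` — `io_formats` (VCF dialect, TSV, PED, report),
  `filtering`, `phenotypes`, `prioritize`, `association`, `segregation`,
  `simulate`, `pipeline`, `cli`
- `examples/` — one short narrative script per capability
- `tests/` — unit, property and acceptance suites
- `docs/methods.md` — model, assumptions, parameter choices, limitations
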