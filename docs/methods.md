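# Methods

## Model and scope

`famprio` operationalizes the standard prioritization recipe for a
dominant, fully or highly penetrant susceptibility allele in a single
multiplex family: a variant shared by all affected members, absent from
unaffected controls, protein-altering, and too rare in the matched
population to explain a low-prevalence phenotype.  The package covers
everything downstream of variant calling and annotation: genotypes
arrive as a biallelic VCF, the family as a PED file, and functional and
population annotation (region, function class, catalogue allele
frequencies, SIFT / PolyPhen2-HDIV / MutationTaster scores and calls) as
a flat TSV.  Computing those annotations, alignment, and calling itself
are out of scope — they are inputs produced by the usual upstream tools.

Only the autosomal-dominant sharing model is implemented.  Recessive,
compound-heterozygous and X-linked analyses, as well as Bayesian
cosegregation frameworks, are deliberately not.

## The cascade

Stages run in a fixed order (affected intersection, control exclusion,
region, function, zygosity, rarity); the final candidate set is the
conjunction of the six per-variant predicates, so the four
annotation/zygosity predicates commute — only the audit counts depend on
order.  Decisions that needed fixing:

* **Missing genotypes.**  A missing call in an affected member fails the
  intersection (carriage cannot be confirmed — the conservative
  reading); a missing call in a control does not count as carriage.
  `MISSING` is a distinct sentinel and is never coerced to 0.
* **Rarity screen.**  Only the East-Asian columns (`af_1000g_eas`,
  `af_exac_eas`) are screened by default, matching a family of East
  Asian ancestry; the threshold comparison is strict (frequency exactly
  0.001 is kept), and a variant NA in every screened column passes
  (`na_policy="pass"`): absence from catalogues is itself evidence of
  rarity.  Both are configurable.
* **Zygosity.**  "Homozygous in all affected" is evaluated per variant:
  call 2 in every affected member.
* **Multiallelic sites** are rejected with an error naming the site
  rather than silently split; silent splitting risks genotype
  misassignment, and the intended inputs are biallelic SNVs.
* Chromosome labels are normalized (leading `chr` stripped) for variant
  identity, since annotation sources differ.

## Hazard score

Each predictor contributes a weight: 1 for SIFT D (score ≤ 0.05), 1 for
PolyPhen2-HDIV D (score ≥ 0.957), 0.5 for P (0.453–0.956), 1 for
MutationTaster A or D; everything else, including an NA slot, adds 0.
This per-category weighting reproduces the published scores of all five
retained reference candidates exactly (2, 1, 3, 2.5, 3).  The printed
scores of four of the seven frequency-excluded reference variants are
*not* reproducible under any simple per-category weighting consistent
with the retained five (they would score 0, 0, 0 and 0.5 rather than
1, 1, 1 and 1); since those rows are eliminated on frequency before
scoring matters, the package reproduces the retained five and documents
the discrepancy here rather than guessing a different rule.

Two further choices: MutationTaster "P" ("polymorphism automatic") is a
benign category and weighs 0; and the open score gaps the PolyPhen2 band
definitions leave at (0.452, 0.453) and (0.956, 0.957) are assigned to
the lower, more benign band.  When an annotation row ships both a score
and a categorical call, the call wins; banding from the score only fills
NA calls.

Ranking is by hazard score descending, ties broken by PolyPhen2 score
descending, then SIFT score ascending (NA last), then gene symbol.  The
ordering is advisory; no automatic single-gene selection is performed.

## Cosegregation evidence

`informative_meioses` counts genotyped non-founder carriers with a
genotyped carrier parent — observed transmissions of the variant allele.
The chance-cosegregation probability is (1/2)^m; for the reference
family (carrier mother, three carrier offspring) m = 3 and the
probability is 12.5%, i.e. supporting evidence only.  An alternative
convention would also count a genotyped unaffected non-carrier offspring
(here III9) as an informative meiosis, giving m = 4; the package counts
carrier transmissions only, and documents rather than adopts the
alternative.

## Cohort screening

`screen_cohort` counts carriers (call 1 or 2) and alternate alleles;
missing genotypes are excluded from the allele-frequency denominator
(standard AF convention).  The `absent` claim is carrier-based, not
allele-based, mirroring per-patient Sanger-style validation.  Catalogue
lookup returns an `ABSENT` sentinel rather than raising, because absence
from a population resource is an expected, informative outcome.

## Synthetic studies

The generator emulates the structure the cascade assumes, not
sequencing-level realism:

* **Pedigree.**  The default template is the bundled two-generation
  family: an affected founder mother (II3), her three affected and one
  unaffected children, an unaffected elderly control (II2), plus the
  unsequenced paternal line; six members are genotyped.  Custom member
  lists build arbitrary families.
* **Background variants** (default n = 5,000, roughly the scale of a
  post-intersection family exome) draw a catalogue class — uncatalogued
  (weight 0.1), rare U(0, 0.001] (0.2), common U(0.001, 0.2] (0.7) —
  reflecting that most catalogued exome variants are common.  Founder
  genotypes are Hardy–Weinberg draws at the variant's frequency;
  offspring receive one allele per parent (a missing parent contributes
  a population allele).  Uncatalogued variants segregate at founder
  frequency 5×10⁻⁴: "not catalogued" means unseen, not impossible, and
  this allows rare background survivors so specificity is testable.
* **Causal variant** (default: the chr14:91942196 C>T substitution) is
  planted heterozygous in the affected members — under a no-phenocopy
  dominant model an affected individual is a carrier — and an unaffected
  child of a carrier is a silent carrier with probability
  (1 − p)/(2 − p), the Mendelian carrier probability conditioned on
  being unaffected at penetrance p.  At the default p = 1.0 the
  template's affection states force the carrier set exactly.
* **Annotations.**  The causal variant is exonic, nonsynonymous, NA in
  every catalogue, with SIFT ~ U(0, 0.05), PolyPhen2 ~ U(0.957, 1) and
  MutationTaster D with probability 0.9 (else N) — a deleterious profile
  that still exercises the score-3 vs score-2 distinction.  Background
  variants draw regions from a mixture dominated by exonic (0.55) and
  intronic (0.20) classes, a 0.40 synonymous fraction within coding
  regions, catalogue frequencies equal to their simulated frequency, and
  benign-leaning predictor scores (10% of SIFT draws deleterious, 5% of
  PolyPhen2 draws probably-damaging, 11% of MutationTaster calls
  harmful, 5% NA per predictor).
* **Determinism.**  Each stage (variant set, genotypes, annotations,
  cohort) uses an independent stream spawned from the single integer
  seed; fixed config + seed yields byte-identical output files.

What passing tests on synthetic data do *not* show: robustness to
genotyping error, linkage disequilibrium between background variants,
annotation disagreement between resources, or non-SNV variant classes —
none of which the generator models.

The recovery benchmark (200 seeds at defaults) checks that the planted
variant always survives and ranks in the top three in ≥95% of runs, and
that the background-survivor count matches a closed-form expectation
computed by exact enumeration over founder genotypes and Gauss–Legendre
integration over the rare-frequency class, within binomial error.

## Numerical and degenerate-input choices

* Genotypes are int8 with MISSING = −1; probabilities of the form
  (1/2)^m are computed as exact binary floats.
* An empty variant input yields an empty candidate table with all-zero
  stage counts; an empty cohort denominator yields allele frequency 0.
* Conservation excludes alignment gaps from the denominator (a deletion
  says nothing about residue identity) and is exact-identity based — the
  claim it supports is literal preservation of the residue, not
  biochemical similarity.  A gap at the reference row is an error.
* 2^−ΔΔCT requires finite positive cycle thresholds; ΔΔCT is
  (CT_target − CT_ref)_case − (CT_target − CT_ref)_control.

## Known limitations

* Variant identity assumes point substitutions; indel normalization
  (left/right alignment) is not implemented, and indels in the input are
  accepted only as plain allele strings.
* The cascade's control set and the validation controls are distinct
  roles: by default the elderly control is the sole cascade control and
  the unaffected sibling is checked post hoc through the segregation
  result, mirroring how such families are typically analyzed.
* Cohort screening takes any supplied genotype matrix or frequency
  table; it does not download or parse external cancer-genome or
  population databases.
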