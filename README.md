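# famprio — family-based germline variant prioritization

`famprio` implements the variant-prioritization workflow used to hunt
susceptibility genes in Mendelian cancer families, built around the worked
example of a familial non-medullary thyroid carcinoma (FNMTC) kindred in
which a private *PPP4R3A* missense variant (chr14:91942196 C>T,
p.Asp409Asn) emerges as the top candidate.  It is a library first: you
import it from Python, feed it a family VCF, a PED file and a per-variant
annotation table, and get back a ranked, fully audited candidate table.
A thin `famprio` CLI wraps the three shell-level uses (run, screen,
simulate).

It is aimed at analysts doing pedigree-based rare-variant work who want
the standard filtering recipe as tested, composable functions rather
than a one-off script.

## The method

Starting from the variants called in a sequenced family, the cascade
applies, in order:

1. **Affected intersection** — keep variants carried (genotype 0/1 or
   1/1) by *every* genotyped affected member.
2. **Control exclusion** — drop variants carried by any designated
   unaffected control.
3. **Region filter** — keep exonic and splice-site variants.
4. **Function filter** — drop synonymous changes.
5. **Zygosity filter** — drop variants homozygous-alternate in every
   affected member (inconsistent with a rare dominant allele).
6. **Rarity filter** — drop variants whose East-Asian catalogue
   frequency (1000 Genomes EAS, ExAC EAS) exceeds 0.001 (strict
   inequality; variants absent from every catalogue pass).

Survivors are ranked by a composite **hazard score** over three
predictors,

    H = w_SIFT + w_PolyPhen2 + w_MutationTaster

with w = 1 for a harmful call (SIFT D, i.e. score ≤ 0.05; PolyPhen2-HDIV
D, score ≥ 0.957; MutationTaster A or D), w = 0.5 for PolyPhen2 P
(0.453 ≤ score ≤ 0.956), and 0 otherwise, so H ∈ {0, 0.5, …, 3}.

Cosegregation of a candidate with the phenotype is quantified as the
chance probability (1/2)^m over m informative meioses (genotyped carrier
offspring of a genotyped carrier parent) — ACMG-style *supporting*
evidence.  Cohort screening reports carrier counts and allele
frequencies of a candidate in sporadic-case panels, and population
catalogue lookup returns `ABSENT` for uncatalogued variants.

A seeded synthetic-study generator (`famprio.simulate`) emits complete
runnable studies — VCF, PED, annotation TSV, cohort VCF and a truth
file — with a fully penetrant dominant variant planted in the affected
founder, so the entire pipeline can be exercised and benchmarked with no
external data.

## Worked example

```bash
python examples/prioritize_family_candidates.py
```

runs the cascade on the bundled reference family (twelve shared exonic
candidates, four affected members, one elderly control) and prints:

```
Filter cascade audit:
  stage=intersect_affected in=12 out=12
  stage=exclude_controls in=12 out=12
  stage=filter_region in=12 out=12
  stage=filter_function in=12 out=12
  stage=filter_zygosity in=12 out=12
  stage=filter_af in=12 out=5

Ranked candidates (hazard score = SIFT + PolyPhen2 + MutationTaster weights):
  1. VWF      12:6153513:C:T         hazard=3.0
  2. IQSEC3   12:283790:C:T          hazard=3.0
  3. MYL1     2:211179708:G:A        hazard=2.5
  4. PPP4R3A  14:91942196:C:T        hazard=2.0
  5. MANSC1   12:12483454:G:C        hazard=1.0

Top private candidate 14:91942196:C:T (PPP4R3A p.Asp409Asn):
  segregates with phenotype : True
  affected carriers         : 4/4
  informative meioses       : 3
  chance cosegregation      : 12.5%  (supporting evidence only)
```

The twelve shared candidates all pass the genotype- and
annotation-based stages; the East-Asian rarity screen removes the seven
catalogued above 0.001 and retains five (*PPP4R3A*, *MANSC1*, *IQSEC3*,
*MYL1*, *VWF*, hazard scores 2, 1, 3, 2.5, 3).  *PPP4R3A* is the only
retained variant absent from every catalogue; its three observed
carrier transmissions give a 12.5% probability of chance cosegregation.

The other examples cover synthetic-study generation and recovery
(`simulate_and_recover.py`), sporadic-cohort and catalogue screening
(`screen_sporadic_cohort.py`), and the conservation / 2^−ΔΔCT evidence
helpers (`conservation_and_expression.py`).

## Command line

```bash
famprio simulate --seed 17 --out study
famprio run --vcf study/study.vcf --ped study/family.ped \
    --annotations study/annotations.tsv \
    --affected II3,III3,III5,III7 --controls II2 --out results
famprio screen --vcf study/cohort.vcf --variant chr14:91942196:C:T --out screen.json
```

`run` writes `candidates.tsv` plus a `candidates.tsv.stages.json`
sidecar with the per-stage audit counts and segregation results.

## Truth file schema

`famprio simulate` writes `truth.json` with the planted variant's
identity and carriers:

```json
{
  "causal_vid": "14:91942196:C:T",
  "carrier_ids": ["II3", "III3", "III5", "III7"],
  "expected_segregation": true
}
```

See `docs/methods.md` for the model, parameter defaults, numerical
choices and limitations.
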