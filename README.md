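# varclass

ACMG/AMP variant classification with rare-variant case-control enrichment,
built for clinical-genetics analysts who need to (re)classify candidate
variants in recessive disease from desk-scale inputs: population-database
allele counts, an in-silico predictor panel, gene-level variant statistics,
family pedigrees, and a case-control proband cohort. The package ships a
deterministic replica of a published study of two *RPE65* missense variants
(c.247T>C / p.Phe83Leu and c.560G>A / p.Gly187Glu, NM_000329.3) in a
513-family Brazilian inherited-retinal-dystrophy cohort, in which both
variants move from *uncertain significance* to *likely pathogenic* once
co-segregation and case-control enrichment are added to the evidence.

## What it computes

Each evidence source feeds one or two ACMG/AMP criteria:

| source | pathogenic criterion | benign counterpart |
|---|---|---|
| population allele counts | PM2 (absent / AF < 1e-4, no homozygotes) | BA1, BS1 |
| 16-predictor panel | PP3 (deleterious fraction ≥ τ = 0.75) | BP4 |
| gene variant-class counts | PP2 (missense mechanism, few benign) | BP1 |
| pedigrees | PP1 (recessive co-segregation) | BS4 |
| case-control cohort | PS4 (enrichment in cases) | — |

The enrichment statistic is the odds ratio of the 2×2 proband table
(case/control × homozygous/not). With a zero cell, the Haldane–Anscombe
correction adds 0.5 to **all four** cells before the cross-product ratio

    OR = (a'·d') / (b'·c'),   SE(log OR) = sqrt(1/a' + 1/b' + 1/c' + 1/d')

and the Wald interval on the log scale is `exp(log OR ± z·SE)` at a
Bonferroni-adjusted confidence level `1 − (1 − 0.95)/m` for `m` variants
tested (two variants → 97.5%, z ≈ 2.2414). PS4 fires when OR ≥ 3 and the
interval excludes 1. Met criteria are tallied by strength and combined by
the standard ACMG/AMP rules into the five tiers (pathogenic, likely
pathogenic, uncertain significance, likely benign, benign), with the firing
rule and a per-criterion rationale kept for audit.

## Worked example

```python
from varclass import VariantPathogenicityModel, Thresholds, presets

study = presets.paper_replica()["p.Phe83Leu"]
results = VariantPathogenicityModel(
    study.variant,
    frequency_records=study.frequency_records,
    prediction_profile=study.prediction_profile,
    gene_summaries=study.gene_summaries,
    pedigrees=study.pedigrees,
    cohort=study.cohort,
    thresholds=Thresholds(n_tests=2),
).fit()
print(results.summary())
```

prints (abridged):

```
ACMG/AMP classification: RPE65:c.247T>C (p.Phe83Leu)
================================================================
criterion strength    met  rationale
----------------------------------------------------------------
PM2       moderate    yes  absent from all queried databases
...
PP3       supporting  yes  16/16 tools deleterious, 0/16 benign ...
PP2       supporting  yes  pathogenic missense fraction 0.754 (ClinVar/...
PP1       supporting  yes  4/4 informative families consistent with rec...
PS4       strong      yes  OR=42.285, 97.5% CI (1.481, 1206.994); thres...
----------------------------------------------------------------
table (a,b,c,d)      (4, 89, 0, 420)
odds ratio           42.285
97.5% CI            (1.481, 1206.994)
----------------------------------------------------------------
tier: likely_pathogenic   (rule fired: LP2)
what-if escalations:
  add PM3 (moderate)    -> pathogenic
  PP1 -> moderate       -> pathogenic
  PP1 -> strong         -> pathogenic
```

Four case probands are homozygous versus none of 420 controls, so the
corrected odds ratio is (4.5·420.5)/(89.5·0.5) = 42.285 with a 97.5%
interval excluding 1 — PS4 at strong. Together with PM2 (moderate) and the
three supporting criteria this satisfies the "1 strong + 1–2 moderate"
likely-pathogenic rule; adding PM3 (a confirmed pathogenic allele in trans)
or promoting PP1 would reach pathogenic.

The same run is available from the shell:

```sh
varclass classify --preset paper_replica --out run/
varclass combine PS4,PM2,PP1,PP2,PP3
varclass simulate --cases 93 --controls 420 --exposed-cases 4 --out sim/
varclass assoc sim/cohort.tsv --n-tests 2
```

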