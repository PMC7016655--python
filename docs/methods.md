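# Methods

## The classification framework

`varclass` operationalizes ACMG/AMP five-tier variant classification for
autosomal-recessive disease. Each evidence source is reduced to coded
criteria with a direction (pathogenic/benign), a strength (stand-alone,
very strong, strong, moderate, supporting) and a met flag; the verdict is a
deterministic function of the multiset of met (direction, strength) pairs
through the standard combining rules. Rules are evaluated in a fixed order
(pathogenic, then likely pathogenic, then benign, then likely benign) and
the first satisfied rule per side is reported as `rule_fired`; the tier is
order-independent, only the label of the rule depends on the ordering. A
tally satisfying rules on both sides resolves to uncertain significance
with `rule_fired = "conflicting"`.

Criteria that are narrative rather than computable (PM1 hot-spot status,
PM3 in-trans configuration, PP4 phenotype specificity, PP5/BP6
reputable-source assertions) are representable as manually asserted
`EvidenceItem`s passed through `extra_evidence`, and are not met by
default. Strength modulation is supported everywhere: an item counts in the
bucket of its *assigned* strength, which is what makes the co-segregation
escalation queries (`what_if`, `reweight`) meaningful.

## Evidence evaluators and their thresholds

All thresholds live in `Thresholds` (config-overridable); defaults encode
curation practice for a severe recessive childhood disease.

- **PM2** — met iff, in every population-database record, the variant is
  absent or has allele frequency strictly below `af_max = 1e-4` with at
  most `hom_max = 0` homozygotes. "No data" counts as absence, so a variant
  reported by no database meets PM2. The frequency cutoff is a package
  default, not a value taken from any single study; 1e-4 is the
  conventional recessive-disease ceiling for PM2 and is deliberately
  conservative relative to the carrier frequencies that would be needed to
  explain observed case counts.
- **BA1/BS1** — any database frequency ≥ 0.05 is stand-alone benign;
  ≥ 0.01 (without BA1) is strong benign. Both comparisons are inclusive,
  PM2's is strict; the asymmetry avoids the degenerate case of a frequency
  exactly at a threshold satisfying neither side.
- **PP3/BP4** — each of the 16 predictors maps to a
  deleterious/benign/ambiguous call via a per-tool rule: categorical tools
  (PolyPhen2, SIFT, PROVEAN, LRT, MutationTaster, MutationAssessor, FATHMM,
  FATHMM-MKL, M-CAP, MetaSVM, MetaLR) through label tables
  ("Possibly/Probably damaging", "Medium/High impact" → deleterious);
  numeric tools through cutoffs with a direction: DANN > 0.9, CADD > 20
  (Phred scale), PhyloP 20-way > 0.5, PhyloP 100-way > 2.0, GERP RS > 4.0,
  all higher-is-damaging. PP3 fires when the deleterious fraction of mapped
  calls reaches τ = 0.75; BP4 when the benign fraction reaches 0.75 and PP3
  did not fire, so the two are mutually exclusive by construction.
  Near-unanimity (15 or 16 of 16) is typical for a true positive; τ = 0.75
  keeps the criterion robust to one or two dissenting tools rather than
  demanding exact unanimity. Conservation-only tools count in the same
  pool: conservation of the residue and predicted functional damage are
  treated as interchangeable lines of computational support. Unknown labels
  are ambiguous (count in the denominator, never the numerator);
  unregistered tools are a configuration error.
- **PP2/BP1** — from per-source gene summaries. PP2 needs the best
  pathogenic-missense fraction across sources ≥ 0.5 *and*, where benign
  counts exist, a benign fraction ≤ 0.10; BP1 needs the missense fraction
  ≤ 0.1. When sources conflict the most favorable source may satisfy each
  condition, mirroring how curators cite whichever database documents the
  mechanism.
- **PP1/BS4** — a pedigree is consistent iff it has ≥ 1 affected
  homozygote, no affected member of any other genotype, and no unaffected
  homozygote; members with missing genotype or unknown affection carry no
  weight. PP1 is met when at least one family is consistent and none
  contradicts; BS4 when any family contradicts. Reduced penetrance is
  deliberately not modeled — one unaffected homozygote breaks the family —
  matching the fully penetrant presentation of childhood retinal dystrophy.
  PP1 strength escalation (moderate at ≥ 3 consistent families with ≥ 6
  informative unaffected carriers, strong at ≥ 5 families) is exposed but
  disabled by default: within a single cohort of one ancestry the promotion
  is not justified, and the defaults reflect that conservatism.
- **PS4** — from the 2×2 proband table (one proband per family, enforced at
  cohort parsing). Zero cells trigger the Haldane–Anscombe correction:
  +0.5 to all four cells, applied *only* when a zero is present — the
  always-add variant would not reproduce the replica odds ratios of 42.285
  and 32.525. The Wald interval uses the same corrected cells for the
  standard error, at confidence `1 − (1 − 0.95)/m` (m = 2 variants →
  97.5%, z computed from the normal quantile at double precision,
  2.241403). PS4 fires at OR ≥ 3 with the interval excluding 1. Probands
  with missing genotype count as unexposed (with a logged warning): an
  ungenotyped proband cannot support enrichment. Fisher-exact and
  conditional intervals are out of scope; the Wald-with-correction form is
  the method being reproduced.

## The replica preset and the synthetic generator

`presets.paper_replica()` carries the study inputs as printed values: the
five-database frequency records, both 16-tool predictor profiles, the
gene-level counts (69 pathogenic / 52 missense; 191 / 103; 8 benign of 93
classified), and a 513-proband cohort (93 LCA/EORD, 420 other IRD) with 4
and 3 homozygous case probands for the two variants. Replica pedigrees are
nuclear families — het unaffected parents, the published number of affected
homozygous children per family (A, E, F: two; G: three; B, C, D: one), and
one unaffected het sib. They are *representative* of the published
pedigrees at the level of genotyped members, not exact replicas of the
drawn family structures (extended relatives and ungenotyped members are
omitted; the CI upper bound for the first variant follows the running-text
value, whose magnitude the recomputation confirms, over the table cell that
drops a digit).

`synthetic.generate_cohort` generalizes the design: exposure counts are
planted exactly (never sampled), so 2×2 tables are recoverable from the
spec; sibship sizes draw from {2: 0.5, 3: 0.3, 4: 0.2}; sibling genotypes
follow het × het Mendelian segregation; penetrance applies to homozygous
children. `generate_null_cohorts` breaks the genotype–phenotype link
(exposure independent of stratum) for calibration: per-replicate generators
spawn from the master `SeedSequence`, so any replicate is reproducible in
isolation. What the generator does **not** emulate: genotyping error,
population structure or relatedness between families, ascertainment bias in
who gets recruited, compound heterozygosity, and locus heterogeneity within
the case stratum. Passing tests therefore demonstrate the pipeline's
arithmetic and decision logic under the study's design assumptions, not
robustness of the criteria to real-cohort artifacts.

## Numerical and design choices

- Problem sizes: the whole suite is desk-scale. The null-calibration check
  uses 1000 replicate cohorts of 513 probands (trigger rate is compared
  against 5% with a 3σ binomial Monte-Carlo margin); the enrichment oracle
  sweeps all 2×2 tables with entries 0–6 at 1e-12 relative agreement; the
  combiner oracle enumerates all tallies with counts ≤ 3.
- Determinism: identical configuration and seed give byte-identical
  reports; all randomness flows through `numpy.random.default_rng` seeded
  from the spec or CLI.
- Degenerate inputs: empty cohorts, empty margins, zero allele-number
  denominators, unknown criterion codes, duplicate met criteria, duplicated
  probands per family and parental cycles are all rejected with typed
  errors; empty predictor profiles and all-uninformative pedigree sets are
  "not met" with an explanatory rationale rather than errors.
- Known limitations: no LOD-score segregation statistic, no popmax-style
  subpopulation frequency logic, no automated PM3 phasing, no Bayesian
  point-scale recalibration of the framework, and HGVS strings are
  validated for form only, not against the reference sequence.
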