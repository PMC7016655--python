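"""The deterministic "paper_replica" study preset.

A self-contained replica of the published RPE65 reclassification study inputs:
a 513-family Brazilian IRD cohort (93 LCA/EORD probands, 420 other-IRD
probands) with four homozygous p.Phe83Leu case probands (families A-D) and
three homozygous p.Gly187Glu case probands (families E-G); nuclear-family
pedigrees mirroring the published pedigrees at the level of genotyped members
(A, E, F: two affected homozygous sibs; G: three; B, C, D: one); the
population-database records; the 16-predictor score profiles; and the
gene-level variant count summaries. All values are in-study printed numbers;
pedigree structures are representative nuclear families, not exact replicas
of the drawn pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass

from .frequency import PopulationFrequencyRecord
from .gene_context import GeneVariantSummary
from .insilico import PredictionProfile
from .types import (
    Affection,
    CohortProband,
    Consequence,
    DiagnosisGroup,
    Genotype,
    Individual,
    Pedigree,
    Sex,
    VariantRecord,
)

PHE83LEU = VariantRecord(
    gene="RPE65", transcript="NM_000329.3",
    cdna_change="c.247T>C", protein_change="p.Phe83Leu",
    consequence=Consequence.missense)

GLY187GLU = VariantRecord(
    gene="RPE65", transcript="NM_000329.3",
    cdna_change="c.560G>A", protein_change="p.Gly187Glu",
    consequence=Consequence.missense)

#: Population-database records. p.Phe83Leu is absent from all five databases;
#: p.Gly187Glu was seen in two heterozygotes in gnomAD and one in ExAC.
FREQUENCY_RECORDS = {
    "p.Phe83Leu": [
        PopulationFrequencyRecord("gnomAD"),
        PopulationFrequencyRecord("ExAC"),
        PopulationFrequencyRecord("ESP"),
        PopulationFrequencyRecord("1000Genomes"),
        PopulationFrequencyRecord("ABraOM"),
    ],
    "p.Gly187Glu": [
        PopulationFrequencyRecord("gnomAD", 2, 251106, 0),
        PopulationFrequencyRecord("ExAC", 1, 120880, 0),
        PopulationFrequencyRecord("ESP"),
        PopulationFrequencyRecord("1000Genomes"),
        PopulationFrequencyRecord("ABraOM"),
    ],
}

#: 16-predictor panel output for each variant, as published.
PREDICTION_PROFILES = {
    "p.Phe83Leu": PredictionProfile({
        "PolyPhen2": "Possibly damaging",
        "SIFT": "Damaging",
        "DANN": 0.9955,
        "PROVEAN": "Damaging",
        "LRT": "Deleterious",
        "MutationTaster": "Disease-causing",
        "MutationAssessor": "Medium impact",
        "FATHMM": "Damaging",
        "FATHMM-MKL": "Damaging",
        "M-CAP": "Damaging",
        "CADD": 24.9,
        "MetaSVM": "Damaging",
        "MetaLR": "Damaging",
        "PhyloP20way": 1.199,
        "PhyloP100way": 8.735,
        "GERP_RS": 5.03,
    }),
    "p.Gly187Glu": PredictionProfile({
        "PolyPhen2": "Probably damaging",
        "SIFT": "Damaging",
        "DANN": 0.9979,
        "PROVEAN": "Damaging",
        "LRT": "Deleterious",
        "MutationTaster": "Disease-causing",
        "MutationAssessor": "Medium impact",
        "FATHMM": "Damaging",
        "FATHMM-MKL": "Damaging",
        "M-CAP": "Damaging",
        "CADD": 32.0,
        "MetaSVM": "Damaging",
        "MetaLR": "Damaging",
        "PhyloP20way": 0.807,
        "PhyloP100way": 7.461,
        "GERP_RS": 5.54,
    }),
}

#: Gene-level counts: ClinVar/UniProt report 69 pathogenic RPE65 variants of
#: which 52 are missense; HGMD lists 191 disease-causing of which 103 are
#: missense; Varsome classifies 8 of 93 catalogued variants as benign.
GENE_SUMMARIES = [
    GeneVariantSummary("ClinVar/UniProt", pathogenic_total=69,
                       pathogenic_missense=52),
    GeneVariantSummary("HGMD", pathogenic_total=191, pathogenic_missense=103),
    GeneVariantSummary("Varsome", pathogenic_total=0, pathogenic_missense=0,
                       benign_count=8, total_classified=93),
]

# Number of genotyped affected homozygotes per family (the published
# pedigrees also contain ungenotyped affected relatives, which carry no
# weight here).
_FAMILY_AFFECTED = {
    "p.Phe83Leu": {"A": 2, "B": 1, "C": 1, "D": 1},
    "p.Gly187Glu": {"E": 2, "F": 2, "G": 3},
}


def _replica_family(family_id: str, n_affected: int) -> Pedigree:
    """Nuclear family: het unaffected parents, homozygous affected children,
    plus one unaffected het sib as an informative non-carrier meiosis."""
    father = Individual(f"{family_id}-I:1", family_id, None, None,
                        Sex.male, Affection.unaffected, Genotype.het)
    mother = Individual(f"{family_id}-I:2", family_id, None, None,
                        Sex.female, Affection.unaffected, Genotype.het)
    members = [father, mother]
    for k in range(1, n_affected + 1):
        members.append(Individual(
            f"{family_id}-II:{k}", family_id, father.individual_id,
            mother.individual_id, Sex.male if k % 2 else Sex.female,
            Affection.affected, Genotype.hom_alt))
    members.append(Individual(
        f"{family_id}-II:{n_affected + 1}", family_id, father.individual_id,
        mother.individual_id, Sex.female, Affection.unaffected, Genotype.het))
    return Pedigree(family_id=family_id, members=tuple(members))


def replica_pedigrees(variant_key: str) -> list[Pedigree]:
    return [_replica_family(fam, n)
            for fam, n in _FAMILY_AFFECTED[variant_key].items()]


def replica_cohort(variant_key: str) -> list[CohortProband]:
    """The 513-proband cohort with homozygotes for one candidate variant.

    93 LCA/EORD probands (the carrier families first, then non-carriers) and
    420 other-IRD probands, none of whom carries either variant.
    """
    carrier_families = list(_FAMILY_AFFECTED[variant_key])
    cohort = []
    for fam in carrier_families:
        cohort.append(CohortProband(f"{fam}-II:1", fam,
                                    DiagnosisGroup.lca_eord,
                                    Genotype.hom_alt))
    for i in range(len(carrier_families), 93):
        fam = f"CASE{i + 1:04d}"
        cohort.append(CohortProband(f"{fam}-P", fam, DiagnosisGroup.lca_eord,
                                    Genotype.hom_ref))
    for i in range(420):
        fam = f"CTRL{i + 1:04d}"
        cohort.append(CohortProband(f"{fam}-P", fam, DiagnosisGroup.other_ird,
                                    Genotype.hom_ref))
    return cohort


@dataclass(frozen=True)
class ReplicaStudy:
    """All replica inputs for one candidate variant."""

    variant: VariantRecord
    frequency_records: tuple[PopulationFrequencyRecord, ...]
    prediction_profile: PredictionProfile
    gene_summaries: tuple[GeneVariantSummary, ...]
    pedigrees: tuple[Pedigree, ...]
    cohort: tuple[CohortProband, ...]


def paper_replica() -> dict[str, ReplicaStudy]:
    """Both candidate variants with their full replica input sets.

    The enrichment analysis tested two variants, so association confidence
    intervals for this preset should use a Bonferroni n_tests of 2
    (95% -> 97.5%).
    """
    out = {}
    for key, variant in (("p.Phe83Leu", PHE83LEU), ("p.Gly187Glu", GLY187GLU)):
        out[key] = ReplicaStudy(
            variant=variant,
            frequency_records=tuple(FREQUENCY_RECORDS[key]),
            prediction_profile=PREDICTION_PROFILES[key],
            gene_summaries=tuple(GENE_SUMMARIES),
            pedigrees=tuple(replica_pedigrees(key)),
            cohort=tuple(replica_cohort(key)),
        )
    return out
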