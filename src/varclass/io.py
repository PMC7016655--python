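"""Readers and writers for the tabular and pedigree formats the pipeline uses.

Formats: PLINK-style PED (six mandatory columns plus one genotype column per
declared candidate variant), TSV cohort / population-frequency / predictor /
gene-summary tables, and optionally a minimal VCF as a genotype source.
Identifiers are case-sensitive; both tab and space delimiters are accepted in
PED files.
"""

from __future__ import annotations

import io as _io
from collections import OrderedDict
from typing import Iterable, Optional

import pandas as pd

from .types import (
    Affection,
    CohortProband,
    DiagnosisGroup,
    Genotype,
    Individual,
    ParseError,
    Pedigree,
    Sex,
    ValidationError,
)

# Both the slash-separated ({0/0, 0/1, 1/1, ./.}) and the dosage ({0, 1, 2,
# NA}) genotype encodings map onto the same enum.
_GENOTYPE_CODES: dict[str, Genotype] = {
    "0/0": Genotype.hom_ref, "0|0": Genotype.hom_ref,
    "0/1": Genotype.het, "1/0": Genotype.het,
    "0|1": Genotype.het, "1|0": Genotype.het,
    "1/1": Genotype.hom_alt, "1|1": Genotype.hom_alt,
    "./.": Genotype.missing, ".|.": Genotype.missing,
    "0": Genotype.hom_ref, "1": Genotype.het, "2": Genotype.hom_alt,
    "NA": Genotype.missing, ".": Genotype.missing,
}

_SEX_CODES = {"1": Sex.male, "2": Sex.female, "0": Sex.unknown}
# PLINK convention: 1 = unaffected, 2 = affected, 0 / -9 = unknown.
_AFFECTION_CODES = {
    "1": Affection.unaffected,
    "2": Affection.affected,
    "0": Affection.unknown,
    "-9": Affection.unknown,
}

_GENOTYPE_TO_PED = {
    Genotype.hom_ref: "0/0",
    Genotype.het: "0/1",
    Genotype.hom_alt: "1/1",
    Genotype.missing: "./.",
}

_AFFECTION_TO_PED = {
    Affection.unaffected: "1",
    Affection.affected: "2",
    Affection.unknown: "0",
}

_SEX_TO_PED = {Sex.male: "1", Sex.female: "2", Sex.unknown: "0"}


def parse_genotype(token: str) -> Genotype:
    try:
        return _GENOTYPE_CODES[token.strip()]
    except KeyError:
        raise ParseError(
            f"unrecognized genotype code {token!r}; expected one of "
            f"{sorted(_GENOTYPE_CODES)}") from None


def parse_ped(text: str, genotype_column: int = 6) -> list[Pedigree]:
    """Parse PED content into pedigrees grouped by family id.

    Parameters
    ----------
    text
        PED-format content: family id, individual id, father id, mother id,
        sex, affection, then at least one genotype column. Unknown parents are
        coded "0" and become ``None``.
    genotype_column
        Zero-based index of the genotype column for the candidate variant
        (default 6, the column right after the six mandatory fields).
    """
    families: "OrderedDict[str, list[Individual]]" = OrderedDict()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) <= genotype_column:
            raise ParseError(
                f"line {lineno}: expected at least {genotype_column + 1} "
                f"columns, got {len(fields)}")
        fam, iid, fid, mid, sex_code, aff_code = fields[:6]
        if sex_code not in _SEX_CODES:
            raise ValidationError(
                f"line {lineno}: invalid sex code {sex_code!r}")
        if aff_code not in _AFFECTION_CODES:
            raise ValidationError(
                f"line {lineno}: invalid affection code {aff_code!r} "
                f"(expected 1=unaffected, 2=affected, 0/-9=unknown)")
        try:
            genotype = parse_genotype(fields[genotype_column])
        except ParseError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        member = Individual(
            individual_id=iid,
            family_id=fam,
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            sex=_SEX_CODES[sex_code],
            affection=_AFFECTION_CODES[aff_code],
            genotype=genotype,
        )
        bucket = families.setdefault(fam, [])
        if any(m.individual_id == iid for m in bucket):
            raise ValidationError(
                f"line {lineno}: duplicate individual id {iid!r} in family "
                f"{fam!r}")
        bucket.append(member)
    return [Pedigree(family_id=fam, members=tuple(members))
            for fam, members in families.items()]


def write_ped(pedigrees: Iterable[Pedigree]) -> str:
    """Serialize pedigrees to PED text; inverse of :func:`parse_ped`."""
    lines = []
    for ped in pedigrees:
        for m in ped:
            lines.append("\t".join([
                m.family_id,
                m.individual_id,
                m.father_id or "0",
                m.mother_id or "0",
                _SEX_TO_PED[m.sex],
                _AFFECTION_TO_PED[m.affection],
                _GENOTYPE_TO_PED[m.genotype],
            ]))
    return "\n".join(lines) + "\n"


_COHORT_COLUMNS = ["proband_id", "family_id", "diagnosis_group", "genotype"]


def read_cohort(text: str) -> list[CohortProband]:
    """Read a proband table (TSV) into cohort records.

    One proband per family is enforced: duplicate family ids are rejected so
    the downstream 2x2 table counts independent families.
    """
    df = pd.read_csv(_io.StringIO(text), sep="\t", dtype=str)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"cohort table missing column(s): {missing}")
    if df.empty:
        return []
    dupes = df["family_id"][df["family_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(
            f"multiple probands share family id(s) {dupes}; the analysis "
            "unit is one proband per family")
    allowed = [g.value for g in DiagnosisGroup]
    probands = []
    for row in df.itertuples(index=False):
        if row.diagnosis_group not in allowed:
            raise ValidationError(
                f"unknown diagnosis_group {row.diagnosis_group!r}; allowed: "
                f"{allowed}")
        probands.append(CohortProband(
            proband_id=row.proband_id,
            family_id=row.family_id,
            diagnosis_group=DiagnosisGroup(row.diagnosis_group),
            genotype=parse_genotype(row.genotype),
        ))
    return probands


def write_cohort(cohort: Iterable[CohortProband]) -> str:
    lines = ["\t".join(_COHORT_COLUMNS)]
    for p in cohort:
        lines.append("\t".join([
            p.proband_id, p.family_id, p.diagnosis_group.value,
            _GENOTYPE_TO_PED[p.genotype],
        ]))
    return "\n".join(lines) + "\n"


def read_frequency_table(text: str):
    """Read population-frequency records from TSV.

    Columns: database, allele_count, allele_number, homozygote_count; the
    literal ``NA`` marks "no data" (the variant was not observed or the
    database was not queried for that field).
    """
    from .frequency import PopulationFrequencyRecord

    df = pd.read_csv(_io.StringIO(text), sep="\t", dtype=str)
    required = ["database", "allele_count", "allele_number", "homozygote_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"frequency table missing column(s): {missing}")

    def _opt_int(token: Optional[str]) -> Optional[int]:
        if token is None or pd.isna(token) or token == "NA":
            return None
        return int(token)

    records = []
    for row in df.itertuples(index=False):
        records.append(PopulationFrequencyRecord(
            database=row.database,
            allele_count=_opt_int(row.allele_count),
            allele_number=_opt_int(row.allele_number),
            homozygote_count=_opt_int(row.homozygote_count),
        ))
    return records


def read_predictions(text: str) -> dict[str, dict[str, object]]:
    """Read predictor outputs from a long-format TSV.

    Columns: variant_id, tool, value. Numeric-looking values are converted to
    floats; everything else is kept as a categorical label. Returns a mapping
    variant_id -> {tool: value}.
    """
    df = pd.read_csv(_io.StringIO(text), sep="\t", dtype=str)
    required = ["variant_id", "tool", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"prediction table missing column(s): {missing}")
    profiles: dict[str, dict[str, object]] = {}
    for row in df.itertuples(index=False):
        value: object = row.value
        try:
            value = float(row.value)
        except (TypeError, ValueError):
            pass
        profiles.setdefault(row.variant_id, {})[row.tool] = value
    return profiles


def read_gene_summaries(text: str):
    """Read gene-level variant count summaries from TSV.

    Columns: source, pathogenic_total, pathogenic_missense, benign_count,
    total_classified (the latter two may be ``NA``).
    """
    from .gene_context import GeneVariantSummary

    df = pd.read_csv(_io.StringIO(text), sep="\t", dtype=str)
    required = ["source", "pathogenic_total", "pathogenic_missense"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"gene summary table missing column(s): {missing}")

    def _opt_int(row, col) -> Optional[int]:
        if col not in df.columns:
            return None
        token = getattr(row, col)
        if token is None or pd.isna(token) or token == "NA":
            return None
        return int(token)

    summaries = []
    for row in df.itertuples(index=False):
        summaries.append(GeneVariantSummary(
            source=row.source,
            pathogenic_total=int(row.pathogenic_total),
            pathogenic_missense=int(row.pathogenic_missense),
            benign_count=_opt_int(row, "benign_count"),
            total_classified=_opt_int(row, "total_classified"),
        ))
    return summaries


def genotypes_from_vcf(path: str, sample_ids: Optional[list[str]] = None
                       ) -> dict[str, Genotype]:
    """Extract per-sample genotypes for the single variant in a minimal VCF.

    Optional genotype source; requires cyvcf2 (``pip install varclass[vcf]``).
    The VCF must contain exactly one biallelic record.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "cyvcf2 is required for VCF input; install the 'vcf' extra"
        ) from exc

    vcf = VCF(path)
    samples = vcf.samples
    records = list(vcf)
    if len(records) != 1:
        raise ValidationError(
            f"expected exactly one variant record in {path}, found "
            f"{len(records)}")
    rec = records[0]
    # gt_types: 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
    code = {0: Genotype.hom_ref, 1: Genotype.het, 2: Genotype.missing,
            3: Genotype.hom_alt}
    out = {s: code[t] for s, t in zip(samples, rec.gt_types)}
    if sample_ids is not None:
        out = {s: out.get(s, Genotype.missing) for s in sample_ids}
    return out
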