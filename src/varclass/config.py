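"""Run configuration: thresholds and input paths, loadable from YAML."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .segregation import EscalationRule


class Thresholds(BaseModel):
    """Every tunable cutoff the evidence evaluators use.

    Defaults encode curation practice for a severe recessive childhood
    disease; all are overridable from the configuration file.
    """

    af_max: float = Field(1e-4, gt=0, lt=1,
                          description="PM2: max population allele frequency")
    hom_max: int = Field(0, ge=0,
                         description="PM2: max homozygotes in any database")
    ba1_af: float = Field(0.05, gt=0, lt=1)
    bs1_af: float = Field(0.01, gt=0, lt=1)
    tau: float = Field(0.75, gt=0, le=1,
                       description="PP3: deleterious consensus fraction")
    tau_benign: float = Field(0.75, gt=0, le=1)
    missense_fraction_min: float = Field(0.5, gt=0, le=1)
    benign_fraction_max: float = Field(0.10, ge=0, lt=1)
    bp1_missense_fraction_max: float = Field(0.1, ge=0, lt=1)
    or_min: float = Field(3.0, gt=0, description="PS4: minimum odds ratio")
    or_exclude: float = Field(1.0, gt=0,
                              description="PS4: CI must exclude this value")
    base_confidence: float = Field(0.95, gt=0, lt=1)
    n_tests: int = Field(1, ge=1,
                         description="Bonferroni comparisons count")
    pp1_escalation_enabled: bool = False
    pp1_moderate_min_families: int = Field(3, ge=1)
    pp1_moderate_min_informative: int = Field(6, ge=0)
    pp1_strong_min_families: int = Field(5, ge=1)

    @model_validator(mode="after")
    def _ordered(self) -> "Thresholds":
        if not self.ba1_af > self.bs1_af:
            raise ValueError("ba1_af must exceed bs1_af")
        return self

    def escalation_rule(self) -> EscalationRule:
        return EscalationRule(
            enabled=self.pp1_escalation_enabled,
            moderate_min_families=self.pp1_moderate_min_families,
            moderate_min_informative=self.pp1_moderate_min_informative,
            strong_min_families=self.pp1_strong_min_families)


class VariantInputs(BaseModel):
    """Input file paths for one candidate variant."""

    gene: str
    transcript: str
    cdna_change: str
    protein_change: str
    cohort_path: Optional[Path] = None
    ped_path: Optional[Path] = None
    frequency_path: Optional[Path] = None
    predictions_path: Optional[Path] = None
    gene_summary_path: Optional[Path] = None


class RunConfig(BaseModel):
    """Full pipeline configuration.

    Either a ``preset`` (currently ``paper_replica``) or a list of per-variant
    input paths must be supplied.
    """

    preset: Optional[str] = None
    variants: list[VariantInputs] = Field(default_factory=list)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    out_dir: Optional[Path] = None
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _has_inputs(self) -> "RunConfig":
        if self.preset is None and not self.variants:
            raise ValueError("config must name a preset or list variants")
        if self.preset is not None and self.preset != "paper_replica":
            raise ValueError(f"unknown preset {self.preset!r}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def validate_paths(self) -> None:
        """Ensure every referenced input file exists before the run starts."""
        for v in self.variants:
            for name in ("cohort_path", "ped_path", "frequency_path",
                         "predictions_path", "gene_summary_path"):
                p = getattr(v, name)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(
                        f"{v.protein_change}: {name} does not exist: {p}")
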