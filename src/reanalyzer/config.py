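"""Run configuration.

Every tunable threshold in the pipeline lives here with its default, so a run
is fully described by one YAML file.  Unknown keys are rejected rather than
ignored — a typo in a threshold name must not silently fall back to the
default.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .models import Arm, Consequence


class FiltrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: strict upper bound on the maximum population AF ("MAF < 1%")
    maf_threshold: float = Field(0.01, gt=0, le=1)
    #: keep dominant-model variants shared with an unaffected parent,
    #: flagged as possible parental mosaicism, instead of removing them
    allow_mosaic_parent: bool = False
    consequence_keep_set: list[Consequence] = [
        Consequence.missense,
        Consequence.nonsense,
        Consequence.frameshift,
        Consequence.splice_acceptor,
        Consequence.splice_donor,
    ]


class AcmgConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: PM2 allowance for recessive genes (AF must be < this; dominant genes need AF 0)
    pm2_af_max: float = 1e-4
    #: BS1: AF greater than expected for the disorder
    bs1_af: float = 0.01
    #: PP3 / VUS-PP: fraction of available missense predictors calling damaging
    pp_damaging_frac: float = 0.75
    #: minimum number of missense predictors with a call before consensus is used
    min_tools: int = 4
    #: BP4: damaging fraction at or below this is a benign consensus
    bp4_damaging_frac: float = 0.25
    #: splice-score cutoffs shared by PP3/BP7 and the VUS subtiers
    splice_high: float = 0.8
    splice_low: float = 0.2
    #: CADD scaled score mapped to a damaging call at or above this
    cadd_cut: float = 20.0
    #: PS2 needs confirmed parental relationships unless waived
    ps2_requires_confirmation: bool = True
    relationships_confirmed: bool = False
    #: curated assertions below this review level are ignored
    min_review_level: int = 1


class ReportingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: Jaccard overlap of normalized phenotype terms needed for a full match
    pheno_match_min: float = 0.25


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    arm: Arm = Arm.rare_disease
    filtration: FiltrationConfig = Field(default_factory=FiltrationConfig)
    acmg: AcmgConfig = Field(default_factory=AcmgConfig)
    reporting: ReportingConfig = Field(default_factory=ReportingConfig)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
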