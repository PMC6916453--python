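"""Domain model for family-aware exome triage.

The objects here are deliberately plain: frozen-ish dataclasses and enums that
the pipeline stages pass between each other.  A variant is always represented
in its normalized biallelic form (multi-allelic records are decomposed on
read, indels left-trimmed), keyed by ``(chrom, pos, ref, alt)``.

Genotypes are stored as alt-allele dosages: ``0``, ``1``, ``2``, or ``None``
for a missing call.  ``./.`` never silently becomes 0 — that distinction is
what separates a de novo call from an uncallable site.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

# --------------------------------------------------------------------------
# pedigree
# --------------------------------------------------------------------------


class Sex(str, enum.Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class Affection(str, enum.Enum):
    affected = "affected"
    unaffected = "unaffected"
    unknown = "unknown"


@dataclass
class SampleInfo:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` for founders and otherwise must
    resolve to another sample in the same family.  Exactly one member per
    family carries ``is_proband``.
    """

    sample_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.unknown
    affection: Affection = Affection.unknown
    is_proband: bool = False
    is_deceased: bool = False


# --------------------------------------------------------------------------
# variants
# --------------------------------------------------------------------------


class Consequence(str, enum.Enum):
    missense = "missense"
    nonsense = "nonsense"
    frameshift = "frameshift"
    splice_acceptor = "splice_acceptor"
    splice_donor = "splice_donor"
    synonymous = "synonymous"
    inframe_indel = "inframe_indel"
    noncoding = "noncoding"
    other = "other"


class Origin(str, enum.Enum):
    autosomal = "autosomal"
    mitochondrial = "mitochondrial"
    x_linked = "x_linked"


VariantKey = tuple[str, int, str, str]

#: dosage of the alt allele; None encodes a missing genotype call
Dosage = Optional[int]

_CHROM_ORDER = {f"chr{i}": i for i in range(1, 23)}
_CHROM_ORDER.update({"chrX": 23, "chrY": 24, "chrM": 25, "chrMT": 25})


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (_CHROM_ORDER.get(chrom, 99), chrom)


@dataclass
class VariantRecord:
    """One normalized biallelic variant with per-sample genotypes."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    gene: str
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: Optional[str] = None
    consequence: Consequence = Consequence.other
    genotypes: dict[str, Dosage] = field(default_factory=dict)
    origin: Origin = Origin.autosomal

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    def sort_key(self):
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


# --------------------------------------------------------------------------
# annotations
# --------------------------------------------------------------------------

POPULATION_SOURCES = ("ExAC", "1000G", "ESP", "UK10K", "gnomAD", "internal")

MISSENSE_TOOLS = ("REVEL", "MetaLR", "MT", "MA", "FATHMM", "SIFT", "CADD", "POLYPHEN2")
SPLICE_TOOLS = ("dbscSNV_Ada", "SpliceAI")
GENOMEWIDE_TOOLS = ("GenoCanyon", "fitCons", "ncER")


@dataclass
class PopulationFrequencies:
    """Per-source allele frequencies; absence from every source means AF 0."""

    by_source: dict[str, float] = field(default_factory=dict)

    @property
    def max_af(self) -> float:
        return max(self.by_source.values(), default=0.0)


class ToolCall(str, enum.Enum):
    damaging = "damaging"
    tolerated = "tolerated"
    unknown = "unknown"


@dataclass
class InSilicoScores:
    missense_calls: dict[str, ToolCall] = field(default_factory=dict)
    splice_scores: dict[str, float] = field(default_factory=dict)
    conservation: Optional[float] = None
    genomewide: dict[str, float] = field(default_factory=dict)


class AssertedClass(str, enum.Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"
    none = "none"


@dataclass
class CuratedAssertion:
    """Condensed ClinVar-like assertion for one variant.

    ``review_level`` (0–4) is a proxy for submitter count/type; level 0 means
    no assertion exists.  The substantive evidence behind a reputable-source
    assertion is carried as booleans (functional data, same-residue pathogenic
    change) so it can be applied under PS3/PS1 rather than PP5/BP6.
    """

    asserted_class: AssertedClass = AssertedClass.none
    review_level: int = 0
    functional_evidence: bool = False
    same_aa_pathogenic: bool = False
    user_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.review_level == 0 and self.asserted_class != AssertedClass.none:
            raise ValueError("review_level 0 requires asserted_class 'none'")


class GeneValidity(str, enum.Enum):
    strong = "strong"
    moderate = "moderate"
    limited = "limited"
    none = "none"


class InheritanceMode(str, enum.Enum):
    AD = "AD"
    AR = "AR"
    XL = "XL"
    MT = "MT"


@dataclass
class GeneEvidence:
    gene: str
    validity: GeneValidity = GeneValidity.none
    inheritance_modes: frozenset[InheritanceMode] = frozenset()
    phenotype_terms: frozenset[str] = frozenset()
    missense_constrained: bool = False
    lof_mechanism: bool = False
    sd_panel: bool = False
    supporting_data: bool = False
    moderate_approved: bool = False


#: returned by AnnotationStore lookups when a key has no data
NO_FREQS = PopulationFrequencies()
NO_SCORES = InSilicoScores()
NO_ASSERTION = CuratedAssertion()


@dataclass
class AnnotationStore:
    """All external knowledge, keyed by variant or gene; absent keys resolve
    to explicit "no data" sentinels, never to an error."""

    pop_freqs: dict[VariantKey, PopulationFrequencies] = field(default_factory=dict)
    scores: dict[VariantKey, InSilicoScores] = field(default_factory=dict)
    assertions: dict[VariantKey, CuratedAssertion] = field(default_factory=dict)
    genes: dict[str, GeneEvidence] = field(default_factory=dict)

    def freqs_for(self, key: VariantKey) -> PopulationFrequencies:
        return self.pop_freqs.get(key, NO_FREQS)

    def scores_for(self, key: VariantKey) -> InSilicoScores:
        return self.scores.get(key, NO_SCORES)

    def assertion_for(self, key: VariantKey) -> CuratedAssertion:
        return self.assertions.get(key, NO_ASSERTION)

    def gene_for(self, gene: str) -> GeneEvidence:
        return self.genes.get(gene, GeneEvidence(gene=gene))


# --------------------------------------------------------------------------
# inheritance
# --------------------------------------------------------------------------


class InheritanceModel(str, enum.Enum):
    de_novo = "de_novo"
    dominant_affected_parent = "dominant_affected_parent"
    recessive_hom = "recessive_hom"
    recessive_comphet = "recessive_comphet"
    mitochondrial = "mitochondrial"
    unresolved = "unresolved"


class ParentOfOrigin(str, enum.Enum):
    maternal = "maternal"
    paternal = "paternal"
    unknown = "unknown"


#: ordering used to pick a single "primary" model for reporting breakdowns
_MODEL_PRIORITY = (
    InheritanceModel.de_novo,
    InheritanceModel.recessive_hom,
    InheritanceModel.recessive_comphet,
    InheritanceModel.dominant_affected_parent,
    InheritanceModel.mitochondrial,
    InheritanceModel.unresolved,
)


@dataclass
class InheritanceCall:
    models: frozenset[InheritanceModel] = frozenset({InheritanceModel.unresolved})
    comphet_partner: Optional[VariantKey] = None
    parent_of_origin: dict[VariantKey, ParentOfOrigin] = field(default_factory=dict)

    @property
    def primary(self) -> InheritanceModel:
        for m in _MODEL_PRIORITY:
            if m in self.models:
                return m
        return InheritanceModel.unresolved


@dataclass
class FiltrationTally:
    n_input: int = 0
    n_after_consequence: int = 0
    n_after_maf: int = 0
    n_after_segregation: int = 0
    n_candidates: int = 0


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------


class Tier(str, enum.Enum):
    B = "B"
    LB = "LB"
    VUS_PB = "VUS-PB"
    VUS_U = "VUS-U"
    VUS_PP = "VUS-PP"
    LP = "LP"
    P = "P"


_TIER_RANK = {
    Tier.B: 0,
    Tier.LB: 1,
    Tier.VUS_PB: 2,
    Tier.VUS_U: 3,
    Tier.VUS_PP: 4,
    Tier.LP: 5,
    Tier.P: 6,
}


@dataclass(frozen=True)
class Classification:
    tier: Tier

    @property
    def rank(self) -> int:
        return _TIER_RANK[self.tier]


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------


class Category(str, enum.Enum):
    DV = "DV"  # diagnostic variant — reported positive
    PDV = "PDV"  # possible diagnostic variant — plausible but negative
    VUDS = "VUDS"  # uncertain diagnostic significance — negative
    NEG = "NEG"

    @property
    def precedence(self) -> int:
        return {"DV": 3, "PDV": 2, "VUDS": 1, "NEG": 0}[self.value]


@dataclass
class ReportCategory:
    category: Category
    rationale: str = ""


class Arm(str, enum.Enum):
    rare_disease = "rare_disease"
    sudden_death = "sudden_death"


class CaseStatus(str, enum.Enum):
    positive = "positive"
    plausible_negative = "plausible_negative"
    negative = "negative"


@dataclass
class Finding:
    variant: VariantRecord
    criteria: "object"  # CriteriaSet; typed loosely to avoid circular import
    classification: Classification
    report: ReportCategory
    inheritance: InheritanceCall = field(default_factory=InheritanceCall)
    flags: frozenset[str] = frozenset()


@dataclass
class CaseReport:
    proband_id: str
    arm: Arm
    findings: list[Finding] = field(default_factory=list)

    @property
    def case_status(self) -> CaseStatus:
        cats = {f.report.category for f in self.findings}
        if Category.DV in cats:
            return CaseStatus.positive
        if Category.PDV in cats:
            return CaseStatus.plausible_negative
        return CaseStatus.negative


class DeltaReason(str, enum.Enum):
    phenotype_update = "phenotype_update"
    annotation_fix = "annotation_fix"
    gene_disease_update = "gene_disease_update"
    pipeline_improvement = "pipeline_improvement"


@dataclass
class ReanalysisDelta:
    proband_id: str
    new_findings: list[Finding] = field(default_factory=list)
    upgraded: list[Finding] = field(default_factory=list)
    confirmed: list[Finding] = field(default_factory=list)
    reasons: dict[VariantKey, DeltaReason] = field(default_factory=dict)

    @property
    def reason_set(self) -> frozenset[DeltaReason]:
        return frozenset(self.reasons.values())
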