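"""ACMG/AMP evidence assignment, combination, and VUS subclassification.

The engine assigns a subset of the standard evidence codes from the loaded
annotations, combines them with the guideline combining table (respecting
explicit strength modifiers, e.g. a PS code applied at moderate counts as
moderate), and expands an uncertain result into the three VUS subtiers
(VUS-PB / VUS-U / VUS-PP) from computational evidence.

Following the ClinGen SVI recommendation, the reputable-source codes PP5 and
BP6 do not exist in this engine at all — they are not members of the code
enum and cannot be parsed from user input.  The evidence that would sit
behind them arrives as structured booleans on the curated assertion and is
applied under the substantive codes instead (functional data → PS3,
same-residue pathogenic change → PS1).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .config import AcmgConfig
from .models import (
    Classification,
    Consequence,
    CuratedAssertion,
    GeneEvidence,
    InheritanceCall,
    InheritanceMode,
    InheritanceModel,
    InSilicoScores,
    PopulationFrequencies,
    Tier,
    ToolCall,
    VariantRecord,
)


class Strength(str, enum.Enum):
    stand_alone = "stand_alone"
    very_strong = "very_strong"
    strong = "strong"
    moderate = "moderate"
    supporting = "supporting"


class Code(str, enum.Enum):
    """The representable ACMG/AMP codes.  PP5 and BP6 are deliberately absent."""

    PVS1 = "PVS1"
    PS1 = "PS1"
    PS2 = "PS2"
    PS3 = "PS3"
    PS4 = "PS4"
    PM1 = "PM1"
    PM2 = "PM2"
    PM3 = "PM3"
    PM4 = "PM4"
    PM5 = "PM5"
    PM6 = "PM6"
    PP1 = "PP1"
    PP2 = "PP2"
    PP3 = "PP3"
    PP4 = "PP4"
    BA1 = "BA1"
    BS1 = "BS1"
    BS2 = "BS2"
    BS3 = "BS3"
    BS4 = "BS4"
    BP1 = "BP1"
    BP2 = "BP2"
    BP3 = "BP3"
    BP4 = "BP4"
    BP5 = "BP5"
    BP7 = "BP7"


_DEFAULT_STRENGTH = {
    "PVS": Strength.very_strong,
    "PS": Strength.strong,
    "PM": Strength.moderate,
    "PP": Strength.supporting,
    "BA": Strength.stand_alone,
    "BS": Strength.strong,
    "BP": Strength.supporting,
}

BENIGN_CODES = frozenset(c for c in Code if c.value.startswith("B"))


def default_strength(code: Code) -> Strength:
    prefix = code.value[:3] if code.value.startswith("PVS") else code.value[:2]
    return _DEFAULT_STRENGTH[prefix]


@dataclass(frozen=True)
class EvidenceCode:
    code: Code
    strength: Strength
    provenance: str = ""

    @classmethod
    def at_default(cls, code: Code, provenance: str = "") -> "EvidenceCode":
        return cls(code, default_strength(code), provenance)

    @property
    def is_benign(self) -> bool:
        return self.code in BENIGN_CODES

    def to_string(self) -> str:
        if self.strength == default_strength(self.code):
            return self.code.value
        return f"{self.code.value}-{self.strength.value}"


_STRENGTH_ALIASES = {
    "stand_alone": Strength.stand_alone,
    "standalone": Strength.stand_alone,
    "very_strong": Strength.very_strong,
    "strong": Strength.strong,
    "moderate": Strength.moderate,
    "supporting": Strength.supporting,
}


def parse_code(text: str) -> EvidenceCode:
    """Parse ``"PM2"`` or ``"PS3-moderate"`` style strings.

    PP5/BP6 are rejected outright: their evidence must be supplied as the
    structured assertion fields and re-expressed under PS3/PS1.
    """
    parts = text.strip().split("-", 1)
    name = parts[0].strip().upper()
    if name in {"PP5", "BP6"}:
        raise ValueError(
            f"{name} is excluded (reputable-source criteria); supply the underlying "
            "evidence as functional_evidence/same_aa_pathogenic instead"
        )
    try:
        code = Code(name)
    except ValueError:
        raise ValueError(f"unknown ACMG/AMP code {name!r}") from None
    if len(parts) == 1:
        return EvidenceCode.at_default(code)
    strength = _STRENGTH_ALIASES.get(parts[1].strip().lower())
    if strength is None:
        raise ValueError(f"unknown strength modifier {parts[1]!r}")
    return EvidenceCode(code, strength)


@dataclass
class CriteriaSet:
    """The applied evidence codes for one variant; one entry per code id."""

    codes: frozenset[EvidenceCode] = frozenset()

    def __post_init__(self) -> None:
        ids = [c.code for c in self.codes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate code identifiers in CriteriaSet")

    def __contains__(self, code: Code) -> bool:
        return any(c.code == code for c in self.codes)

    def __len__(self) -> int:
        return len(self.codes)

    def get(self, code: Code) -> Optional[EvidenceCode]:
        return next((c for c in self.codes if c.code == code), None)

    def with_code(self, ec: EvidenceCode) -> "CriteriaSet":
        return CriteriaSet(self.codes | {ec})

    def to_strings(self) -> list[str]:
        return sorted(c.to_string() for c in self.codes)

    @classmethod
    def from_strings(cls, texts: Iterable[str]) -> "CriteriaSet":
        return cls(frozenset(parse_code(t) for t in texts))


# --------------------------------------------------------------------------
# criteria assignment
# --------------------------------------------------------------------------

LOF_CONSEQUENCES = frozenset(
    {Consequence.nonsense, Consequence.frameshift, Consequence.splice_acceptor, Consequence.splice_donor}
)


def _missense_consensus(sc: InSilicoScores, cfg: AcmgConfig) -> Optional[float]:
    """Fraction of available predictors calling damaging, or None if too few."""
    calls = [c for c in sc.missense_calls.values() if c != ToolCall.unknown]
    if len(calls) < cfg.min_tools:
        return None
    return sum(1 for c in calls if c == ToolCall.damaging) / len(calls)


def assign_criteria(
    v: VariantRecord,
    pf: PopulationFrequencies,
    sc: InSilicoScores,
    ca: CuratedAssertion,
    ge: GeneEvidence,
    inh: InheritanceCall,
    config: Optional[AcmgConfig] = None,
    partner_is_plp: bool = False,
) -> CriteriaSet:
    """Assign the automated criteria subset from annotations.

    Each rule checks the availability of its evidence; absent evidence simply
    means the code is not applied.  Codes with no automated trigger (PM1,
    PM4–PM6, PS4, PP4, BS2–BS4, BP1–BP3, BP5) can be passed through via the
    assertion's ``user_codes``.
    """
    cfg = config or AcmgConfig()
    codes: set[EvidenceCode] = set()
    assertion_ok = ca.review_level >= cfg.min_review_level

    # --- pathogenic direction -------------------------------------------
    if v.consequence in LOF_CONSEQUENCES and ge.lof_mechanism:
        codes.add(EvidenceCode.at_default(Code.PVS1, "LoF in a gene where LoF is the mechanism"))
    if assertion_ok and ca.same_aa_pathogenic:
        codes.add(EvidenceCode.at_default(Code.PS1, "same amino-acid change previously established pathogenic"))
    if InheritanceModel.de_novo in inh.models and (
        not cfg.ps2_requires_confirmation or cfg.relationships_confirmed
    ):
        codes.add(EvidenceCode.at_default(Code.PS2, "confirmed de novo"))
    if assertion_ok and ca.functional_evidence:
        codes.add(EvidenceCode.at_default(Code.PS3, "well-established functional studies"))
    recessive_gene = InheritanceMode.AR in ge.inheritance_modes
    if pf.max_af == 0.0 or (recessive_gene and pf.max_af < cfg.pm2_af_max):
        codes.add(EvidenceCode(Code.PM2, Strength.moderate, "absent/ultra-rare in population databases"))
    if InheritanceModel.recessive_comphet in inh.models and partner_is_plp:
        codes.add(EvidenceCode.at_default(Code.PM3, "in trans with a pathogenic variant"))
    if InheritanceModel.dominant_affected_parent in inh.models:
        codes.add(EvidenceCode.at_default(Code.PP1, "cosegregation with disease in the family"))
    if v.consequence == Consequence.missense and ge.missense_constrained:
        codes.add(EvidenceCode.at_default(Code.PP2, "missense in a missense-constrained gene"))
    consensus = _missense_consensus(sc, cfg)
    splice_hit = any(s >= cfg.splice_high for s in sc.splice_scores.values())
    if (consensus is not None and consensus >= cfg.pp_damaging_frac) or splice_hit:
        codes.add(EvidenceCode.at_default(Code.PP3, "computational consensus deleterious"))

    # --- benign direction -----------------------------------------------
    if pf.max_af > 0.05:
        codes.add(EvidenceCode.at_default(Code.BA1, "AF > 5%"))
    elif pf.max_af > cfg.bs1_af:
        codes.add(EvidenceCode.at_default(Code.BS1, "AF greater than expected for disorder"))
    if consensus is not None and consensus <= cfg.bp4_damaging_frac and not splice_hit:
        codes.add(EvidenceCode.at_default(Code.BP4, "computational consensus benign"))
    if (
        v.consequence == Consequence.synonymous
        and sc.splice_scores
        and all(s < cfg.splice_low for s in sc.splice_scores.values())
    ):
        codes.add(EvidenceCode.at_default(Code.BP7, "synonymous, no predicted splice impact"))

    # --- user pass-through ----------------------------------------------
    if assertion_ok:
        for text in ca.user_codes:
            ec = parse_code(text)
            codes.add(replace(ec, provenance="user-asserted"))

    # keep one entry per code id (pass-through may repeat an automated code)
    seen: dict[Code, EvidenceCode] = {}
    for ec in sorted(codes, key=lambda c: (c.code.value, c.strength.value)):
        seen.setdefault(ec.code, ec)
    return CriteriaSet(frozenset(seen.values()))


# --------------------------------------------------------------------------
# combination
# --------------------------------------------------------------------------


def combine_criteria(cs: CriteriaSet) -> Tier:
    """Combine applied codes into P / LP / VUS / LB / B.

    Codes count at their applied strength.  Simultaneous satisfaction of a
    pathogenic and a benign tier is a conflict and yields VUS.
    """
    vs = sum(1 for c in cs.codes if not c.is_benign and c.strength == Strength.very_strong)
    st = sum(1 for c in cs.codes if not c.is_benign and c.strength == Strength.strong)
    mo = sum(1 for c in cs.codes if not c.is_benign and c.strength == Strength.moderate)
    su = sum(1 for c in cs.codes if not c.is_benign and c.strength == Strength.supporting)
    ba = sum(1 for c in cs.codes if c.is_benign and c.strength == Strength.stand_alone)
    bst = sum(1 for c in cs.codes if c.is_benign and c.strength == Strength.strong)
    bsu = sum(1 for c in cs.codes if c.is_benign and c.strength == Strength.supporting)

    pathogenic = vs >= 1 and (st >= 1 or mo >= 2 or (mo >= 1 and su >= 1) or su >= 2)
    pathogenic = pathogenic or st >= 2
    pathogenic = pathogenic or (st >= 1 and (mo >= 3 or (mo >= 2 and su >= 2) or (mo >= 1 and su >= 4)))

    likely_pathogenic = (
        (vs >= 1 and mo >= 1)
        or (st >= 1 and 1 <= mo <= 2)
        or (st >= 1 and su >= 2)
        or mo >= 3
        or (mo >= 2 and su >= 2)
        or (mo >= 1 and su >= 4)
    )

    benign = ba >= 1 or bst >= 2
    likely_benign = (bst >= 1 and bsu >= 1) or bsu >= 2

    path_tier = Tier.P if pathogenic else Tier.LP if likely_pathogenic else None
    benign_tier = Tier.B if benign else Tier.LB if likely_benign else None

    if path_tier and benign_tier:
        return Tier.VUS_U  # conflicting evidence → uncertain
    if path_tier:
        return path_tier
    if benign_tier:
        return benign_tier
    return Tier.VUS_U


# --------------------------------------------------------------------------
# VUS subclassification
# --------------------------------------------------------------------------

_SPLICE_REGION = frozenset(
    {Consequence.splice_acceptor, Consequence.splice_donor, Consequence.synonymous}
)


def subclassify_vus(
    v: VariantRecord, sc: InSilicoScores, config: Optional[AcmgConfig] = None
) -> Tier:
    """Split an uncertain classification into VUS-PB / VUS-U / VUS-PP.

    Possibly pathogenic needs a strong computational consensus (damaging
    fraction of the missense predictors, or a high splice score for
    splice-region/synonymous variants); possibly benign is reserved for
    non-coding variants with no predicted splice impact.
    """
    cfg = config or AcmgConfig()
    consensus = _missense_consensus(sc, cfg)
    if consensus is not None and consensus >= cfg.pp_damaging_frac:
        return Tier.VUS_PP
    if v.consequence in _SPLICE_REGION and any(
        s >= cfg.splice_high for s in sc.splice_scores.values()
    ):
        return Tier.VUS_PP
    if v.consequence == Consequence.noncoding and all(
        s < cfg.splice_low for s in sc.splice_scores.values()
    ):
        return Tier.VUS_PB
    return Tier.VUS_U


def classify(
    v: VariantRecord,
    pf: PopulationFrequencies,
    sc: InSilicoScores,
    ca: CuratedAssertion,
    ge: GeneEvidence,
    inh: InheritanceCall,
    config: Optional[AcmgConfig] = None,
    partner_is_plp: bool = False,
) -> tuple[CriteriaSet, Classification]:
    """Assign criteria and produce the 7-level classification."""
    cs = assign_criteria(v, pf, sc, ca, ge, inh, config, partner_is_plp=partner_is_plp)
    tier = combine_criteria(cs)
    if tier == Tier.VUS_U:
        tier = subclassify_vus(v, sc, config)
    return cs, Classification(tier)
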