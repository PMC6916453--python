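"""Gene-evidence gating, reporting categories, case reports, and diffs.

A classified candidate only reaches the report if its gene clears the
validity gate (strong, or moderate with review-panel approval) and fits the
case phenotype — for the sudden-death arm, phenotype fit means membership in
the curated sudden-death gene panel.  Variants are then binned into the four
reporting categories:

* DV   — P/LP variant in a known phenotype-matched gene (positive)
* PDV  — P/LP with partial phenotype fit, possibly-pathogenic (VUS-PP) with a
         full fit, or a single het P/LP in a strictly recessive gene with no
         in-trans partner (plausible but negative)
* VUDS — deleterious-looking variant in a novel/uncertain candidate gene with
         additional supporting data (negative)
* NEG  — everything else
"""

from __future__ import annotations

import enum
from typing import Optional

from .config import ReportingConfig
from .models import (
    Arm,
    CaseReport,
    Category,
    Classification,
    DeltaReason,
    Finding,
    GeneEvidence,
    GeneValidity,
    InheritanceCall,
    InheritanceMode,
    InheritanceModel,
    ReanalysisDelta,
    ReportCategory,
    Tier,
    VariantKey,
)


class Match(str, enum.Enum):
    match = "match"
    partial = "partial"
    none = "none"


def gene_reportable(ge: GeneEvidence) -> bool:
    """Gene-validity gate: strong, or moderate with explicit approval."""
    return ge.validity == GeneValidity.strong or (
        ge.validity == GeneValidity.moderate and ge.moderate_approved
    )


def _normalize(term: str) -> str:
    return " ".join(term.lower().split())


def phenotype_match(
    case_terms: set[str],
    ge: GeneEvidence,
    arm: Arm,
    config: Optional[ReportingConfig] = None,
) -> Match:
    """Phenotype fit between a case and a gene.

    Rare-disease arm: Jaccard overlap of normalized terms at or above the
    configured threshold is a match; any shared term below it is partial.
    Sudden-death arm: fit is panel membership.
    """
    cfg = config or ReportingConfig()
    if arm == Arm.sudden_death:
        return Match.match if ge.sd_panel else Match.none
    a = {_normalize(t) for t in case_terms}
    b = {_normalize(t) for t in ge.phenotype_terms}
    shared = a & b
    if not a or not b or not shared:
        return Match.none
    jaccard = len(shared) / len(a | b)
    return Match.match if jaccard >= cfg.pheno_match_min else Match.partial


def categorize(
    cls: Classification,
    ge: GeneEvidence,
    pm: Match,
    inh: InheritanceCall,
    proband_dosage: int = 1,
) -> ReportCategory:
    """Assign one of the four reporting categories to a classified variant."""
    plp = cls.tier in (Tier.P, Tier.LP)
    reportable = gene_reportable(ge)

    if reportable and plp and pm == Match.match:
        strictly_recessive = ge.inheritance_modes and ge.inheritance_modes <= {
            InheritanceMode.AR,
        }
        single_het = (
            proband_dosage == 1
            and inh.comphet_partner is None
            and InheritanceModel.recessive_hom not in inh.models
        )
        if strictly_recessive and single_het:
            return ReportCategory(
                Category.PDV,
                "single heterozygous P/LP variant in a recessive gene with no in-trans partner",
            )
        return ReportCategory(Category.DV, "P/LP variant in a known phenotype-matched gene")
    if reportable and plp and pm == Match.partial:
        return ReportCategory(Category.PDV, "P/LP variant in a gene possibly associated with the phenotype")
    if reportable and cls.tier == Tier.VUS_PP and pm == Match.match:
        return ReportCategory(Category.PDV, "possibly pathogenic variant in a known phenotype-matched gene")
    novel_gene = ge.validity in (GeneValidity.limited, GeneValidity.none)
    if (cls.tier == Tier.VUS_PP or (plp and novel_gene)) and ge.supporting_data:
        return ReportCategory(Category.VUDS, "deleterious-looking variant in a candidate gene with supporting data")
    return ReportCategory(Category.NEG, "insufficient variant- or gene-level evidence")


def build_case_report(proband_id: str, arm: Arm, findings: list[Finding]) -> CaseReport:
    """Assemble the per-proband report; findings sorted by category then tier."""
    ordered = sorted(
        findings,
        key=lambda f: (-f.report.category.precedence, -f.classification.rank, f.variant.sort_key()),
    )
    return CaseReport(proband_id=proband_id, arm=arm, findings=ordered)


_DEFECT_REASONS = {
    "affection_flip": DeltaReason.phenotype_update,
    "splice_misannotation": DeltaReason.annotation_fix,
    "missense_to_noncoding": DeltaReason.annotation_fix,
    "gene_link_removed": DeltaReason.gene_disease_update,
}


def diff_reports(
    initial: CaseReport,
    reanalysis: CaseReport,
    provenance: Optional[dict[VariantKey, str]] = None,
) -> ReanalysisDelta:
    """Diff two reports for the same proband.

    New findings are DV/PDV variants in the re-analysis that were absent or
    lower-category initially; a prior DV finding may never silently vanish.
    Reasons come from a defect provenance log when available, otherwise
    ``pipeline_improvement``.
    """
    if initial.proband_id != reanalysis.proband_id:
        raise ValueError(
            f"proband mismatch: {initial.proband_id!r} vs {reanalysis.proband_id!r}"
        )
    init_cat = {f.variant.key: f.report.category for f in initial.findings}
    delta = ReanalysisDelta(proband_id=initial.proband_id)
    for f in reanalysis.findings:
        if f.report.category not in (Category.DV, Category.PDV):
            continue
        prior = init_cat.get(f.variant.key)
        if prior is None or prior in (Category.VUDS, Category.NEG):
            # absent from the initial report, or present but not reported —
            # either way the amended report treats it as a new finding
            delta.new_findings.append(f)
        elif prior.precedence < f.report.category.precedence:
            delta.upgraded.append(f)
        else:
            delta.confirmed.append(f)
    for f in delta.new_findings + delta.upgraded:
        defect = (provenance or {}).get(f.variant.key)
        delta.reasons[f.variant.key] = _DEFECT_REASONS.get(
            defect, DeltaReason.pipeline_improvement
        )
    # a prior positive must reappear (possibly upgraded) in the re-analysis
    re_keys = {f.variant.key for f in reanalysis.findings if f.report.category == Category.DV}
    dropped = [
        k for k, c in init_cat.items() if c == Category.DV and k not in re_keys
    ]
    if dropped:
        raise ValueError(f"prior positive findings dropped in re-analysis: {dropped}")
    return delta
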