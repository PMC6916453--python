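"""End-to-end orchestration: filtration → classification → categorization →
case report, per family, over an in-memory cohort dataset.

The same code path serves files loaded from disk (via io_formats) and
synthetic cohorts generated in memory, which is what makes the degraded-vs-
clean re-analysis experiment a pure function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io_formats
from .acmg import classify
from .config import RunConfig
from .filtration import Candidate, run_filtration
from .models import (
    AnnotationStore,
    Arm,
    CaseReport,
    Classification,
    FiltrationTally,
    Finding,
    SampleInfo,
    Tier,
    VariantKey,
    VariantRecord,
)
from .reporting import build_case_report, categorize, phenotype_match


@dataclass
class CohortDataset:
    """Everything one cohort run consumes, in memory.

    ``variants`` maps family_id → that family's normalized variant records
    (each record's genotype map covers exactly the family's samples).
    """

    pedigree: list[SampleInfo]
    variants: dict[str, list[VariantRecord]]
    store: AnnotationStore
    phenotypes: dict[str, set[str]] = field(default_factory=dict)
    arm: Arm = Arm.rare_disease

    def families(self) -> dict[str, list[SampleInfo]]:
        out: dict[str, list[SampleInfo]] = {}
        for s in self.pedigree:
            out.setdefault(s.family_id, []).append(s)
        return out

    def proband_of(self, family_id: str) -> SampleInfo:
        return next(
            s for s in self.pedigree if s.family_id == family_id and s.is_proband
        )


def classify_candidates(
    candidates: list[Candidate],
    store: AnnotationStore,
    config: RunConfig,
) -> dict[VariantKey, tuple[object, Classification]]:
    """Classify filtered candidates with two-pass compound-het handling.

    PM3 (in trans with a pathogenic variant) needs the partner's
    classification, so comphet candidates are classified once without PM3 and
    re-classified with it when the partner lands P/LP on the first pass.
    """
    results: dict[VariantKey, tuple[object, Classification]] = {}
    by_key = {c.variant.key: c for c in candidates}
    for c in candidates:
        ge = store.gene_for(c.variant.gene)
        results[c.variant.key] = classify(
            c.variant,
            store.freqs_for(c.variant.key),
            store.scores_for(c.variant.key),
            store.assertion_for(c.variant.key),
            ge,
            c.inheritance,
            config.acmg,
        )
    for c in candidates:
        partner = c.inheritance.comphet_partner
        if partner is None or partner not in results:
            continue
        if results[partner][1].tier in (Tier.P, Tier.LP):
            ge = store.gene_for(c.variant.gene)
            results[c.variant.key] = classify(
                c.variant,
                store.freqs_for(c.variant.key),
                store.scores_for(c.variant.key),
                store.assertion_for(c.variant.key),
                ge,
                c.inheritance,
                config.acmg,
                partner_is_plp=True,
            )
    return results


def analyze_family(
    family: list[SampleInfo],
    variants: list[VariantRecord],
    store: AnnotationStore,
    phenotype_terms: set[str],
    arm: Arm,
    config: Optional[RunConfig] = None,
) -> tuple[CaseReport, FiltrationTally]:
    """Run the full triage for one family; returns the proband's case report."""
    cfg = config or RunConfig(arm=arm)
    proband = next(s for s in family if s.is_proband)
    candidates, tally = run_filtration(variants, family, store, cfg.filtration)
    classified = classify_candidates(candidates, store, cfg)
    findings = []
    for c in candidates:
        cs, cls = classified[c.variant.key]
        ge = store.gene_for(c.variant.gene)
        pm = phenotype_match(phenotype_terms, ge, arm, cfg.reporting)
        report = categorize(
            cls, ge, pm, c.inheritance, c.variant.genotypes[proband.sample_id]
        )
        findings.append(
            Finding(
                variant=c.variant,
                criteria=cs,
                classification=cls,
                report=report,
                inheritance=c.inheritance,
                flags=frozenset(c.flags),
            )
        )
    return build_case_report(proband.sample_id, arm, findings), tally


def analyze_cohort(
    dataset: CohortDataset, config: Optional[RunConfig] = None
) -> tuple[dict[str, CaseReport], dict[str, FiltrationTally]]:
    """Analyze every family; returns reports and tallies keyed by proband id."""
    cfg = config or RunConfig(arm=dataset.arm)
    reports: dict[str, CaseReport] = {}
    tallies: dict[str, FiltrationTally] = {}
    for family_id, members in sorted(dataset.families().items()):
        proband = dataset.proband_of(family_id)
        terms = dataset.phenotypes.get(proband.sample_id, set())
        report, tally = analyze_family(
            members, dataset.variants.get(family_id, []), dataset.store, terms, dataset.arm, cfg
        )
        reports[proband.sample_id] = report
        tallies[proband.sample_id] = tally
    return reports, tallies


def load_dataset(
    vcf_dir: str | Path,
    ped: str | Path,
    annotations: dict[str, str | Path],
    phenotypes: dict[str, set[str]],
    arm: Arm = Arm.rare_disease,
    cadd_cut: float = 20.0,
) -> CohortDataset:
    """Load a cohort from disk: one VCF per family under ``vcf_dir`` (named
    ``<family_id>.vcf``), a cohort PED, and the annotation TSVs."""
    pedigree = io_formats.read_ped(ped)
    store = io_formats.read_annotations(
        pop_af=annotations.get("pop_af"),
        scores=annotations.get("scores"),
        assertions=annotations.get("assertions"),
        genes=annotations.get("genes"),
        cadd_cut=cadd_cut,
    )
    by_family: dict[str, list[SampleInfo]] = {}
    for s in pedigree:
        by_family.setdefault(s.family_id, []).append(s)
    variants = {}
    for family_id, members in sorted(by_family.items()):
        path = Path(vcf_dir) / f"{family_id}.vcf"
        variants[family_id] = io_formats.read_vcf(path, members)
    return CohortDataset(
        pedigree=pedigree, variants=variants, store=store, phenotypes=phenotypes, arm=arm
    )
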