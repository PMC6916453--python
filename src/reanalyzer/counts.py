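"""Expand published case-level count tables into stub case reports.

Cohort-level yield arithmetic only needs how many cases exist, which were
diagnostic before and after re-analysis, and the inheritance mode of each
diagnostic finding.  This module turns a small JSON counts table into
minimal stub reports so the same ``summarize`` code path that serves full
pipeline output can reproduce published yield figures.

Counts JSON schema (per arm)::

    {"rare_disease": {"n_cases": 51, "n_dv_initial": 13, "n_dv_final": 16,
                      "n_vuds_final": 18,
                      "dv_inheritance": {"de_novo": 8, "recessive": 6,
                                         "dominant": 1, "mitochondrial": 1}},
     "sudden_death": {...}}
"""

from __future__ import annotations

import json
from pathlib import Path

from .acmg import CriteriaSet
from .models import (
    Arm,
    CaseReport,
    Category,
    Classification,
    Finding,
    InheritanceCall,
    InheritanceModel,
    ReportCategory,
    Tier,
    VariantRecord,
)

_GROUP_TO_MODEL = {
    "de_novo": InheritanceModel.de_novo,
    "recessive": InheritanceModel.recessive_hom,
    "dominant": InheritanceModel.dominant_affected_parent,
    "mitochondrial": InheritanceModel.mitochondrial,
    "unresolved": InheritanceModel.unresolved,
}


def _stub_finding(n: int, category: Category, tier: Tier, model: InheritanceModel) -> Finding:
    v = VariantRecord(chrom="chr1", pos=n, ref="A", alt="C", gene=f"STUB{n}")
    return Finding(
        variant=v,
        criteria=CriteriaSet(),
        classification=Classification(tier),
        report=ReportCategory(category, rationale="counts-fixture stub"),
        inheritance=InheritanceCall(models=frozenset({model})),
    )


def reports_from_counts(counts: dict) -> tuple[list[CaseReport], list[CaseReport]]:
    """Build (initial, final) stub report lists reproducing the given counts.

    The initial diagnostic cases are the first ``n_dv_initial`` of the final
    diagnostic cases — prior positives stay positive on re-analysis.
    """
    initial: list[CaseReport] = []
    final: list[CaseReport] = []
    pos = 1
    for arm_name in sorted(counts):
        c = counts[arm_name]
        arm = Arm(arm_name)
        models: list[InheritanceModel] = []
        for group, n in sorted(c.get("dv_inheritance", {}).items()):
            models += [_GROUP_TO_MODEL[group]] * n
        if len(models) < c["n_dv_final"]:
            models += [InheritanceModel.unresolved] * (c["n_dv_final"] - len(models))

        for i in range(c["n_cases"]):
            pid = f"{arm_name}_{i + 1:03d}"
            if i < c["n_dv_final"]:
                f = _stub_finding(pos, Category.DV, Tier.P, models[i])
                pos += 1
                final.append(CaseReport(pid, arm, [f]))
                initial.append(
                    CaseReport(pid, arm, [f] if i < c["n_dv_initial"] else [])
                )
            elif i < c["n_dv_final"] + c.get("n_vuds_final", 0):
                f = _stub_finding(pos, Category.VUDS, Tier.VUS_PP, InheritanceModel.unresolved)
                pos += 1
                final.append(CaseReport(pid, arm, [f]))
                initial.append(CaseReport(pid, arm, []))
            else:
                final.append(CaseReport(pid, arm, []))
                initial.append(CaseReport(pid, arm, []))
    return initial, final


def load_counts(path: str | Path) -> tuple[list[CaseReport], list[CaseReport]]:
    with open(path) as fh:
        return reports_from_counts(json.load(fh))
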