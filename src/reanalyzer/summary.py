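"""Cohort-level aggregation: diagnostic yields, re-analysis deltas, and the
inheritance-mode breakdown of diagnostic findings.

Yields are percentages of cases with at least one diagnostic variant,
rounded half-away-from-zero to one decimal; the relative increase is
expressed against the initial yield and rounded to the nearest integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .models import Arm, CaseReport, CaseStatus, Category, InheritanceModel


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (what a printed table does), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


#: reporting groups for the breakdown: both recessive models count as "recessive"
_MODE_GROUP = {
    InheritanceModel.de_novo: "de_novo",
    InheritanceModel.recessive_hom: "recessive",
    InheritanceModel.recessive_comphet: "recessive",
    InheritanceModel.dominant_affected_parent: "dominant",
    InheritanceModel.mitochondrial: "mitochondrial",
    InheritanceModel.unresolved: "unresolved",
}


@dataclass
class ArmSummary:
    n_cases: int = 0
    n_dv_initial: int = 0
    n_dv_final: int = 0
    n_pdv: int = 0
    n_vuds: int = 0
    yield_initial_pct: float = 0.0
    yield_final_pct: float = 0.0
    new_dv: int = 0
    new_dv_pct: float = 0.0
    relative_increase_pct: int = 0
    inheritance_breakdown: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortSummary:
    arms: dict[str, ArmSummary] = field(default_factory=dict)

    def __getitem__(self, arm: str) -> ArmSummary:
        return self.arms[arm]


def _dv_cases(reports: list[CaseReport]) -> set[str]:
    return {r.proband_id for r in reports if r.case_status == CaseStatus.positive}


def inheritance_breakdown(final_dv_reports: list[CaseReport]) -> dict[str, float]:
    """Percent of diagnostic cases per (grouped) primary inheritance model."""
    counts: dict[str, int] = {}
    total = 0
    for r in final_dv_reports:
        dv = [f for f in r.findings if f.report.category == Category.DV]
        if not dv:
            continue
        group = _MODE_GROUP[dv[0].inheritance.primary]
        counts[group] = counts.get(group, 0) + 1
        total += 1
    if total == 0:
        return {}
    return {g: round_half_away(100.0 * n / total, 2) for g, n in sorted(counts.items())}


def _summarize_arm(
    initial: list[CaseReport], final: list[CaseReport], n_cases: int
) -> ArmSummary:
    dv_i, dv_f = _dv_cases(initial), _dv_cases(final)
    s = ArmSummary(n_cases=n_cases, n_dv_initial=len(dv_i), n_dv_final=len(dv_f))
    s.n_pdv = sum(1 for r in final if r.case_status == CaseStatus.plausible_negative)
    s.n_vuds = sum(
        1
        for r in final
        if r.case_status == CaseStatus.negative
        and any(f.report.category == Category.VUDS for f in r.findings)
    )
    s.yield_initial_pct = round_half_away(100.0 * s.n_dv_initial / n_cases, 1)
    s.yield_final_pct = round_half_away(100.0 * s.n_dv_final / n_cases, 1)
    s.new_dv = len(dv_f - dv_i)
    s.new_dv_pct = round_half_away(100.0 * s.new_dv / n_cases, 1)
    if s.n_dv_initial > 0:
        s.relative_increase_pct = int(
            round_half_away(100.0 * (s.n_dv_final - s.n_dv_initial) / s.n_dv_initial, 0)
        )
    s.inheritance_breakdown = inheritance_breakdown(
        [r for r in final if r.proband_id in dv_f]
    )
    return s


def summarize(
    reports_initial: list[CaseReport], reports_final: list[CaseReport]
) -> CohortSummary:
    """Aggregate initial and re-analysis reports into per-arm and combined yields."""
    if not reports_final:
        raise ValueError("no cases to summarize")
    if {r.proband_id for r in reports_initial} != {r.proband_id for r in reports_final}:
        raise ValueError("initial and re-analysis report sets cover different probands")

    out = CohortSummary()
    arms_present = sorted({r.arm for r in reports_final}, key=lambda a: a.value)
    for arm in arms_present:
        ini = [r for r in reports_initial if r.arm == arm]
        fin = [r for r in reports_final if r.arm == arm]
        out.arms[arm.value] = _summarize_arm(ini, fin, len(fin))
    out.arms["combined"] = _summarize_arm(
        reports_initial, reports_final, len(reports_final)
    )
    return out


def summary_table(summary: CohortSummary):
    """CohortSummary as a tidy DataFrame (one row per arm)."""
    import pandas as pd

    rows = []
    for arm, s in summary.arms.items():
        row = {
            "arm": arm,
            "n_cases": s.n_cases,
            "n_dv_initial": s.n_dv_initial,
            "n_dv_final": s.n_dv_final,
            "n_pdv": s.n_pdv,
            "n_vuds": s.n_vuds,
            "yield_initial_pct": s.yield_initial_pct,
            "yield_final_pct": s.yield_final_pct,
            "new_dv": s.new_dv,
            "new_dv_pct": s.new_dv_pct,
            "relative_increase_pct": s.relative_increase_pct,
        }
        for mode, pct in s.inheritance_breakdown.items():
            row[f"dv_{mode}_pct"] = pct
        rows.append(row)
    return pd.DataFrame(rows)
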