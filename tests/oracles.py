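"""Independent brute-force oracles used by the tests.

These deliberately re-derive expected results from first principles —
literal rule tables and exhaustive enumeration — without calling into the
package's own logic, so agreement is a genuine cross-check.
"""

from __future__ import annotations

# --------------------------------------------------------------------------
# evidence-combination oracle: a literal transcription of the combining
# table as (min very-strong, min strong, min moderate, min supporting) rows
# --------------------------------------------------------------------------

_PATHOGENIC_ROWS = [
    (1, 1, 0, 0),  # 1 very strong + >=1 strong
    (1, 0, 2, 0),  # 1 very strong + >=2 moderate
    (1, 0, 1, 1),  # 1 very strong + 1 moderate + 1 supporting
    (1, 0, 0, 2),  # 1 very strong + >=2 supporting
    (0, 2, 0, 0),  # >=2 strong
    (0, 1, 3, 0),  # 1 strong + >=3 moderate
    (0, 1, 2, 2),  # 1 strong + 2 moderate + >=2 supporting
    (0, 1, 1, 4),  # 1 strong + 1 moderate + >=4 supporting
]

_LIKELY_PATHOGENIC_ROWS = [
    (1, 0, 1, 0),  # 1 very strong + 1 moderate
    (0, 1, 1, 0),  # 1 strong + 1-2 moderate
    (0, 1, 0, 2),  # 1 strong + >=2 supporting
    (0, 0, 3, 0),  # >=3 moderate
    (0, 0, 2, 2),  # 2 moderate + >=2 supporting
    (0, 0, 1, 4),  # 1 moderate + >=4 supporting
]


def combine_oracle(pathogenic_strengths: list[str], benign_strengths: list[str]) -> str:
    """Expected 5-level outcome for applied strengths, read off the rule table.

    ``pathogenic_strengths``: entries from {very_strong, strong, moderate,
    supporting}; ``benign_strengths``: entries from {stand_alone, strong,
    supporting}.
    """
    counts = (
        pathogenic_strengths.count("very_strong"),
        pathogenic_strengths.count("strong"),
        pathogenic_strengths.count("moderate"),
        pathogenic_strengths.count("supporting"),
    )

    def meets(rows):
        return any(all(c >= r for c, r in zip(counts, row)) for row in rows)

    path = "P" if meets(_PATHOGENIC_ROWS) else "LP" if meets(_LIKELY_PATHOGENIC_ROWS) else None

    ba = benign_strengths.count("stand_alone")
    bst = benign_strengths.count("strong")
    bsu = benign_strengths.count("supporting")
    if ba >= 1 or bst >= 2:
        ben = "B"
    elif (bst >= 1 and bsu >= 1) or bsu >= 2:
        ben = "LB"
    else:
        ben = None

    if path and ben:
        return "VUS"
    return path or ben or "VUS"


# --------------------------------------------------------------------------
# trio inheritance oracle: exhaustive case analysis on observed dosages
# --------------------------------------------------------------------------


def trio_models_oracle(
    dp: int,
    df: int,
    dm: int,
    father_affected: bool = False,
    mother_affected: bool = False,
    mitochondrial: bool = False,
) -> set[str]:
    """Expected model set for one variant in a full trio with observed genotypes."""
    models: set[str] = set()
    if dp >= 1 and df == 0 and dm == 0:
        models.add("de_novo")
    if dp == 2 and df >= 1 and dm >= 1:
        models.add("recessive_hom")
    if dp == 1 and ((df >= 1 and father_affected) or (dm >= 1 and mother_affected)):
        models.add("dominant_affected_parent")
    if mitochondrial and dp >= 1 and dm >= 1:
        models.add("mitochondrial")
    return models or {"unresolved"}


def parent_of_origin_oracle(df: int, dm: int) -> str:
    if df >= 1 and dm == 0:
        return "paternal"
    if dm >= 1 and df == 0:
        return "maternal"
    return "unknown"


def comphet_oracle(dfa: int, dma: int, dfb: int, dmb: int) -> bool:
    """Two proband-het variants are in trans iff their parental origins are
    opposite and unambiguous."""
    return {parent_of_origin_oracle(dfa, dma), parent_of_origin_oracle(dfb, dmb)} == {
        "paternal",
        "maternal",
    }


# --------------------------------------------------------------------------
# counting oracle for inheritance breakdowns
# --------------------------------------------------------------------------


def breakdown_oracle(modes: list[str]) -> dict[str, float]:
    out: dict[str, float] = {}
    for m in set(modes):
        out[m] = round(100.0 * modes.count(m) / len(modes), 2)
    return out
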