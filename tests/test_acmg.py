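"""Classification engine: criteria assignment, combination, VUS subtiers."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from reanalyzer.acmg import (
    Code,
    CriteriaSet,
    EvidenceCode,
    Strength,
    assign_criteria,
    classify,
    combine_criteria,
    parse_code,
    subclassify_vus,
)
from reanalyzer.config import AcmgConfig
from reanalyzer.models import (
    AssertedClass,
    Consequence,
    CuratedAssertion,
    GeneEvidence,
    GeneValidity,
    InheritanceCall,
    InheritanceMode,
    InheritanceModel,
    InSilicoScores,
    PopulationFrequencies,
    Tier,
    ToolCall,
    MISSENSE_TOOLS,
)
from conftest import make_variant
from oracles import combine_oracle


def cs(*texts):
    return CriteriaSet.from_strings(texts)


class TestCombineCriteria:
    @pytest.mark.parametrize(
        "codes,expected",
        [
            # splice LoF with functional support: pathogenic
            (("PVS1", "PS3", "PM2"), Tier.P),
            # LoF alone in a depleted gene: likely pathogenic only
            (("PVS1", "PM2"), Tier.LP),
            # two strongs plus a moderate: pathogenic
            (("PS1", "PS3", "PM2"), Tier.P),
            # moderate plus two supporting: still uncertain
            (("PM2", "PP3", "PP2"), Tier.VUS_U),
            ((), Tier.VUS_U),
            (("BA1",), Tier.B),
            (("BS1", "BS2"), Tier.B),
            (("BS1", "BP4"), Tier.LB),
            (("BP4", "BP7"), Tier.LB),
            # conflicting pathogenic and benign tiers resolve to uncertain
            (("PVS1", "PS3", "PM2", "BA1"), Tier.VUS_U),
            # strength-modified codes count at their applied strength
            (("PS3-moderate", "PM2", "PM1"), Tier.LP),
            (("PVS1", "PS3-supporting", "PP3"), Tier.P),
        ],
    )
    def test_worked_combinations(self, codes, expected):
        assert combine_criteria(cs(*codes)) == expected

    def test_exhaustive_oracle_equivalence(self):
        """All code subsets of size <= 6 over an alphabet spanning every
        direction x applied-strength class match the literal rule table."""
        alphabet = [
            "PVS1", "PS1", "PS2", "PS3-moderate", "PS4-supporting",
            "PM1", "PM2", "PM3-supporting", "PP1-strong", "PP2", "PP3",
            "BA1", "BS1", "BS2-supporting", "BP4", "BP7",
        ]
        parsed = [parse_code(t) for t in alphabet]
        n_checked = 0
        for k in range(0, 7):
            for combo in itertools.combinations(parsed, k):
                tier = combine_criteria(CriteriaSet(frozenset(combo)))
                path = [c.strength.value for c in combo if not c.is_benign]
                ben = [c.strength.value for c in combo if c.is_benign]
                expected = combine_oracle(path, ben)
                got = {Tier.P: "P", Tier.LP: "LP", Tier.B: "B", Tier.LB: "LB"}.get(tier, "VUS")
                assert got == expected, (combo, got, expected)
                n_checked += 1
        assert n_checked == sum(
            len(list(itertools.combinations(range(16), k))) for k in range(7)
        )

    @settings(max_examples=200, derandomize=True)
    @given(
        base=st.lists(
            st.sampled_from(["PS1", "PS3", "PM1", "PM2", "PP1", "PP2", "PP3"]),
            unique=True, max_size=5,
        ),
        extra=st.sampled_from(["PVS1", "PS2", "PM3", "PS4"]),
    )
    def test_adding_pathogenic_evidence_never_downgrades(self, base, extra):
        order = {Tier.B: 0, Tier.LB: 1, Tier.VUS_U: 2, Tier.LP: 3, Tier.P: 4}
        before = combine_criteria(cs(*base))
        after = combine_criteria(cs(*(base + [extra])))
        assert order[after] >= order[before]


class TestPP5BP6Exclusion:
    def test_codes_are_unrepresentable(self):
        assert "PP5" not in Code.__members__
        assert "BP6" not in Code.__members__

    @pytest.mark.parametrize("bad", ["PP5", "BP6", "pp5-supporting"])
    def test_parser_rejects_reputable_source_codes(self, bad):
        with pytest.raises(ValueError, match="excluded|unknown"):
            parse_code(bad)

    def test_assertion_evidence_remapped_to_substantive_codes(self):
        """Curated-assertion evidence surfaces as PS3/PS1, never PP5."""
        v = make_variant(consequence=Consequence.missense)
        ca = CuratedAssertion(asserted_class=AssertedClass.P, review_level=3,
                              functional_evidence=True, same_aa_pathogenic=True)
        out = assign_criteria(v, PopulationFrequencies(), InSilicoScores(), ca,
                              GeneEvidence("SG001"), InheritanceCall())
        assert Code.PS3 in out and Code.PS1 in out


class TestAssignCriteria:
    def test_splice_lof_with_functional_support(self):
        """Splice-acceptor LoF, absent from databases, functional data: the
        full PVS1 + PS3 + PM2 pattern."""
        v = make_variant(consequence=Consequence.splice_acceptor)
        ge = GeneEvidence("SG001", GeneValidity.strong,
                          frozenset({InheritanceMode.AD}), lof_mechanism=True)
        ca = CuratedAssertion(asserted_class=AssertedClass.P, review_level=3,
                              functional_evidence=True)
        out = assign_criteria(v, PopulationFrequencies(), InSilicoScores(), ca, ge,
                              InheritanceCall())
        assert set(out.to_strings()) == {"PVS1", "PS3", "PM2"}
        assert combine_criteria(out) == Tier.P

    def test_constrained_missense_novel_variant(self):
        """Missense in a constrained gene, absent everywhere, unanimous
        damaging consensus: PM2 + PP2 + PP3 (an uncertain variant)."""
        v = make_variant(consequence=Consequence.missense)
        ge = GeneEvidence("SG001", GeneValidity.strong,
                          frozenset({InheritanceMode.AR}), missense_constrained=True)
        sc = InSilicoScores(missense_calls={t: ToolCall.damaging for t in MISSENSE_TOOLS})
        out = assign_criteria(v, PopulationFrequencies(), sc, CuratedAssertion(), ge,
                              InheritanceCall())
        assert set(out.to_strings()) == {"PM2", "PP2", "PP3"}
        assert combine_criteria(out) == Tier.VUS_U

    def test_common_variant_gets_ba1_not_pm2(self):
        v = make_variant()
        pf = PopulationFrequencies({"gnomAD": 0.20})
        out = assign_criteria(v, pf, InSilicoScores(), CuratedAssertion(),
                              GeneEvidence("SG001"), InheritanceCall())
        assert Code.BA1 in out and Code.PM2 not in out

    def test_pm2_recessive_allowance(self):
        ge_ar = GeneEvidence("SG001", inheritance_modes=frozenset({InheritanceMode.AR}))
        ge_ad = GeneEvidence("SG001", inheritance_modes=frozenset({InheritanceMode.AD}))
        pf = PopulationFrequencies({"gnomAD": 5e-5})
        v = make_variant()
        with_ar = assign_criteria(v, pf, InSilicoScores(), CuratedAssertion(), ge_ar, InheritanceCall())
        with_ad = assign_criteria(v, pf, InSilicoScores(), CuratedAssertion(), ge_ad, InheritanceCall())
        assert Code.PM2 in with_ar and Code.PM2 not in with_ad

    def test_pm3_requires_pathogenic_partner(self):
        v = make_variant()
        inh = InheritanceCall(models=frozenset({InheritanceModel.recessive_comphet}),
                              comphet_partner=("chr1", 2000, "A", "G"))
        without = assign_criteria(v, PopulationFrequencies(), InSilicoScores(),
                                  CuratedAssertion(), GeneEvidence("SG001"), inh)
        with_ = assign_criteria(v, PopulationFrequencies(), InSilicoScores(),
                                CuratedAssertion(), GeneEvidence("SG001"), inh,
                                partner_is_plp=True)
        assert Code.PM3 not in without and Code.PM3 in with_

    def test_ps2_gated_on_relationship_confirmation(self):
        v = make_variant()
        inh = InheritanceCall(models=frozenset({InheritanceModel.de_novo}))
        args = (v, PopulationFrequencies({"gnomAD": 0.03}), InSilicoScores(),
                CuratedAssertion(), GeneEvidence("SG001"), inh)
        assert Code.PS2 not in assign_criteria(*args)
        cfg = AcmgConfig(relationships_confirmed=True)
        assert Code.PS2 in assign_criteria(*args, cfg)

    def test_synonymous_without_splice_impact_gets_bp7(self):
        v = make_variant(consequence=Consequence.synonymous)
        sc = InSilicoScores(splice_scores={"SpliceAI": 0.02, "dbscSNV_Ada": 0.1})
        out = assign_criteria(v, PopulationFrequencies({"gnomAD": 0.03}), sc,
                              CuratedAssertion(), GeneEvidence("SG001"), InheritanceCall())
        assert Code.BP7 in out

    def test_user_passthrough_codes(self):
        ca = CuratedAssertion(asserted_class=AssertedClass.VUS, review_level=2,
                              user_codes=("PM1", "PP4-moderate"))
        out = assign_criteria(make_variant(), PopulationFrequencies({"gnomAD": 0.02}),
                              InSilicoScores(), ca, GeneEvidence("SG001"), InheritanceCall())
        assert Code.PM1 in out
        assert out.get(Code.PP4).strength == Strength.moderate


class TestSubclassifyVus:
    def test_noncoding_without_splice_impact_is_possibly_benign(self):
        v = make_variant(consequence=Consequence.noncoding)
        sc = InSilicoScores(splice_scores={"SpliceAI": 0.01, "dbscSNV_Ada": 0.05})
        assert subclassify_vus(v, sc) == Tier.VUS_PB

    def test_mixed_predictor_calls_stay_uncertain(self):
        v = make_variant(consequence=Consequence.missense)
        calls = {t: (ToolCall.damaging if i < 4 else ToolCall.tolerated)
                 for i, t in enumerate(MISSENSE_TOOLS)}
        assert subclassify_vus(v, InSilicoScores(missense_calls=calls)) == Tier.VUS_U

    def test_unanimous_damaging_is_possibly_pathogenic(self):
        v = make_variant(consequence=Consequence.missense)
        sc = InSilicoScores(missense_calls={t: ToolCall.damaging for t in MISSENSE_TOOLS},
                            conservation=5.1)
        assert subclassify_vus(v, sc) == Tier.VUS_PP

    def test_high_splice_score_synonymous_is_possibly_pathogenic(self):
        v = make_variant(consequence=Consequence.synonymous)
        sc = InSilicoScores(splice_scores={"SpliceAI": 0.92})
        assert subclassify_vus(v, sc) == Tier.VUS_PP

    def test_too_few_tools_means_no_consensus(self):
        v = make_variant(consequence=Consequence.missense)
        sc = InSilicoScores(missense_calls={"REVEL": ToolCall.damaging,
                                            "SIFT": ToolCall.damaging})
        assert subclassify_vus(v, sc) == Tier.VUS_U


class TestClassify:
    def test_classify_is_pure(self):
        v = make_variant(consequence=Consequence.splice_acceptor)
        ge = GeneEvidence("SG001", GeneValidity.strong, lof_mechanism=True)
        ca = CuratedAssertion(asserted_class=AssertedClass.P, review_level=3,
                              functional_evidence=True)
        results = {
            classify(v, PopulationFrequencies(), InSilicoScores(), ca, ge,
                     InheritanceCall())[1].tier
            for _ in range(3)
        }
        assert results == {Tier.P}

    def test_rank_order(self):
        from reanalyzer.models import Classification
        ranks = [Classification(t).rank for t in
                 (Tier.B, Tier.LB, Tier.VUS_PB, Tier.VUS_U, Tier.VUS_PP, Tier.LP, Tier.P)]
        assert ranks == sorted(ranks) and len(set(ranks)) == 7

    def test_duplicate_code_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CriteriaSet(frozenset({
                EvidenceCode(Code.PM2, Strength.moderate),
                EvidenceCode(Code.PM2, Strength.strong),
            }))
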