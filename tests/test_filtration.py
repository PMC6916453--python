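"""Filtration rules and trio inheritance calling."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from reanalyzer.config import FiltrationConfig
from reanalyzer.filtration import (
    consequence_filter,
    infer_inheritance,
    maf_filter,
    run_filtration,
    segregation_filter,
)
from reanalyzer.models import (
    Affection,
    AnnotationStore,
    Consequence,
    InheritanceModel,
    Origin,
    ParentOfOrigin,
    PopulationFrequencies,
    SampleInfo,
    Sex,
)
from conftest import make_variant
from oracles import comphet_oracle, trio_models_oracle


class TestConsequenceFilter:
    @pytest.mark.parametrize(
        "csq,kept",
        [
            (Consequence.missense, True),
            (Consequence.nonsense, True),
            (Consequence.frameshift, True),
            (Consequence.splice_acceptor, True),
            (Consequence.splice_donor, True),
            (Consequence.synonymous, False),
            (Consequence.inframe_indel, False),
            (Consequence.noncoding, False),
            (Consequence.other, False),
        ],
    )
    def test_kept_classes(self, csq, kept):
        assert consequence_filter(make_variant(consequence=csq)) is kept


class TestMafFilter:
    def test_rare_passes(self):
        assert maf_filter(PopulationFrequencies({"gnomAD": 0.005}))

    def test_exactly_at_threshold_fails(self):
        # "< 1%" is strict
        assert not maf_filter(PopulationFrequencies({"ExAC": 0.01}))

    def test_absent_everywhere_passes(self):
        assert maf_filter(PopulationFrequencies())

    def test_max_over_sources(self):
        pf = PopulationFrequencies({"1000G": 0.001, "gnomAD": 0.02})
        assert pf.max_af == 0.02
        assert not maf_filter(pf)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            maf_filter(PopulationFrequencies(), threshold=0.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        af=st.floats(min_value=0, max_value=1),
        t1=st.floats(min_value=1e-6, max_value=1),
        t2=st.floats(min_value=1e-6, max_value=1),
    )
    def test_monotone_in_threshold(self, af, t1, t2):
        lo, hi = sorted((t1, t2))
        pf = PopulationFrequencies({"gnomAD": af})
        if maf_filter(pf, lo):
            assert maf_filter(pf, hi)


class TestInferInheritance:
    def test_all_27_trio_dosage_combinations(self, trio):
        """Exhaustive agreement with the case-analysis oracle, both with
        unaffected parents and with an affected father."""
        for father_affected in (False, True):
            ped = [s for s in trio]
            ped[1].affection = Affection.affected if father_affected else Affection.unaffected
            for dp, df, dm in itertools.product(range(3), repeat=3):
                v = make_variant(genotypes={"kid": dp, "dad": df, "mom": dm})
                call = infer_inheritance([v], ped, "kid")[v.key]
                expected = trio_models_oracle(dp, df, dm, father_affected=father_affected)
                got = {m.value for m in call.models} - {"recessive_comphet"}
                assert got == expected, (dp, df, dm, father_affected)

    def test_all_81_comphet_configurations(self, trio):
        """Two proband-het variants over all ordered parental genotype
        combinations agree with the in-trans oracle."""
        for dfa, dma, dfb, dmb in itertools.product(range(3), repeat=4):
            va = make_variant(pos=1000, genotypes={"kid": 1, "dad": dfa, "mom": dma})
            vb = make_variant(pos=2000, ref="C", alt="T",
                              genotypes={"kid": 1, "dad": dfb, "mom": dmb})
            calls = infer_inheritance([va, vb], trio, "kid")
            expected = comphet_oracle(dfa, dma, dfb, dmb)
            got = InheritanceModel.recessive_comphet in calls[va.key].models
            assert got == expected, (dfa, dma, dfb, dmb)
            if expected:
                assert calls[va.key].comphet_partner == vb.key
                assert calls[vb.key].comphet_partner == va.key
                origins = {calls[va.key].parent_of_origin[va.key],
                           calls[va.key].parent_of_origin[vb.key]}
                assert origins == {ParentOfOrigin.paternal, ParentOfOrigin.maternal}

    def test_homozygote_never_comphet_with_itself(self, trio):
        v = make_variant(genotypes={"kid": 2, "dad": 1, "mom": 1})
        call = infer_inheritance([v], trio, "kid")[v.key]
        assert InheritanceModel.recessive_comphet not in call.models
        assert call.comphet_partner is None

    def test_missing_parent_genotype_blocks_de_novo(self, trio):
        v = make_variant(genotypes={"kid": 1, "dad": None, "mom": 0})
        call = infer_inheritance([v], trio, "kid")[v.key]
        assert call.models == {InheritanceModel.unresolved}

    def test_singleton_homozygote_still_recessive(self):
        ped = [SampleInfo("kid", "F1", affection=Affection.affected, is_proband=True)]
        v = make_variant(genotypes={"kid": 2})
        call = infer_inheritance([v], ped, "kid")[v.key]
        assert InheritanceModel.recessive_hom in call.models

    def test_mitochondrial_carried_by_mother(self, trio):
        v = make_variant(chrom="chrM", origin=Origin.mitochondrial,
                         genotypes={"kid": 1, "dad": 0, "mom": 1})
        call = infer_inheritance([v], trio, "kid")[v.key]
        assert InheritanceModel.mitochondrial in call.models

    def test_proband_missing_from_genotypes_raises(self, trio):
        v = make_variant(genotypes={"dad": 0, "mom": 0})
        with pytest.raises(ValueError, match="absent"):
            infer_inheritance([v], trio, "kid")


class TestSegregationFilter:
    def _call(self, *models):
        from reanalyzer.models import InheritanceCall
        return InheritanceCall(models=frozenset(models))

    def test_unaffected_carrier_parent_removes_dominant_candidate(self, trio):
        v = make_variant(genotypes={"kid": 1, "dad": 1, "mom": 0})
        out = segregation_filter([(v, self._call(InheritanceModel.unresolved))], trio,
                                 allow_mosaic_parent=False)
        assert out == []

    def test_mosaic_allowance_retains_with_flag(self, trio):
        v = make_variant(genotypes={"kid": 1, "dad": 1, "mom": 0})
        out = segregation_filter([(v, self._call(InheritanceModel.unresolved))], trio,
                                 allow_mosaic_parent=True)
        assert len(out) == 1 and "possible_parental_mosaicism" in out[0].flags

    def test_unknown_affection_never_contradicts(self, trio):
        trio[1].affection = Affection.unknown
        v = make_variant(genotypes={"kid": 1, "dad": 1, "mom": 0})
        out = segregation_filter([(v, self._call(InheritanceModel.unresolved))], trio)
        assert len(out) == 1 and not out[0].flags

    @pytest.mark.parametrize(
        "model",
        [InheritanceModel.de_novo, InheritanceModel.recessive_hom,
         InheritanceModel.recessive_comphet, InheritanceModel.mitochondrial],
    )
    def test_protected_models_never_removed(self, trio, model):
        # even with an unaffected carrier in the family
        v = make_variant(genotypes={"kid": 1, "dad": 1, "mom": 0})
        out = segregation_filter([(v, self._call(model))], trio)
        assert len(out) == 1


class TestRunFiltration:
    def _store_with_af(self, variants, af):
        store = AnnotationStore()
        for v in variants:
            store.pop_freqs[v.key] = PopulationFrequencies({"gnomAD": af})
        return store

    def test_all_common_yields_no_candidates(self, trio):
        vs = [make_variant(pos=1000 + i, genotypes={"kid": 1, "dad": 1, "mom": 0})
              for i in range(5)]
        store = self._store_with_af(vs, 0.3)
        cands, tally = run_filtration(vs, trio, store)
        assert cands == [] and tally.n_after_maf == 0

    def test_tally_monotone(self, trio):
        vs = [
            make_variant(pos=1000, consequence=Consequence.synonymous),
            make_variant(pos=2000, ref="C", alt="T"),
            make_variant(pos=3000, ref="G", alt="T",
                         genotypes={"kid": 1, "dad": 1, "mom": 0}),
        ]
        store = AnnotationStore()
        store.pop_freqs[vs[1].key] = PopulationFrequencies({"gnomAD": 0.05})
        cands, t = run_filtration(vs, trio, store)
        assert t.n_input >= t.n_after_consequence >= t.n_after_maf >= t.n_after_segregation
        assert t.n_after_segregation == t.n_candidates == len(cands)

    def test_planted_de_novo_found_among_background(self, trio):
        planted = make_variant(pos=5000, ref="G", alt="A",
                               consequence=Consequence.nonsense,
                               genotypes={"kid": 1, "dad": 0, "mom": 0})
        background = [
            make_variant(pos=1000 + i, genotypes={"kid": 1, "dad": 1, "mom": 0})
            for i in range(20)
        ]
        store = self._store_with_af(background, 0.005)
        cands, _ = run_filtration(background + [planted], trio, store)
        assert [c.variant.key for c in cands] == [planted.key]
        assert InheritanceModel.de_novo in cands[0].inheritance.models
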