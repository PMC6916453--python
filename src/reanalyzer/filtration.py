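"""The three candidate-variant filtration rules and trio inheritance calling.

Filters are applied in a fixed order — functional-consequence class, then
population frequency (MAF < 1% strict), then family segregation — and a
tally of survivors at each step is kept.  Order affects only the tally, not
the final candidate set.

Inheritance calling is genotype-only (no read-backed phasing): compound-het
phase is taken from parental genotypes, so two variants both carried by one
parent are treated as in cis.  De novo status requires both parental
genotypes observed as homozygous reference; a missing parent genotype makes
the call unresolved rather than de novo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .config import FiltrationConfig
from .models import (
    Affection,
    AnnotationStore,
    Consequence,
    FiltrationTally,
    InheritanceCall,
    InheritanceModel,
    Origin,
    ParentOfOrigin,
    PopulationFrequencies,
    SampleInfo,
    VariantKey,
    VariantRecord,
)

#: models that are never removed by the segregation filter
PROTECTED_MODELS = frozenset(
    {
        InheritanceModel.de_novo,
        InheritanceModel.recessive_hom,
        InheritanceModel.recessive_comphet,
        InheritanceModel.mitochondrial,
    }
)

DEFAULT_KEEP = frozenset(
    {
        Consequence.missense,
        Consequence.nonsense,
        Consequence.frameshift,
        Consequence.splice_acceptor,
        Consequence.splice_donor,
    }
)


@dataclass
class Candidate:
    """A variant that survived filtration, with its inheritance call."""

    variant: VariantRecord
    inheritance: InheritanceCall
    flags: set[str] = field(default_factory=set)


def consequence_filter(v: VariantRecord, keep: frozenset[Consequence] = DEFAULT_KEEP) -> bool:
    """True for non-synonymous, nonsense, frameshift and canonical splice-site variants."""
    return v.consequence in keep


def maf_filter(pf: PopulationFrequencies, threshold: float = 0.01) -> bool:
    """True iff the maximum AF over all sources is strictly below ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0,1], got {threshold}")
    return pf.max_af < threshold


def _family_of(pedigree: list[SampleInfo], proband: str) -> SampleInfo:
    for s in pedigree:
        if s.sample_id == proband:
            return s
    raise ValueError(f"proband {proband!r} not in pedigree")


def infer_inheritance(
    variants_in_gene: list[VariantRecord],
    pedigree: list[SampleInfo],
    proband: str,
) -> dict[VariantKey, InheritanceCall]:
    """Call the inheritance model(s) for each variant of one gene.

    Returns one call per variant.  Compound-het partners are linked pairwise:
    two proband-heterozygous variants with opposite, unambiguous parental
    origins are in trans.
    """
    pro = _family_of(pedigree, proband)
    by_id = {s.sample_id: s for s in pedigree}
    father = by_id.get(pro.father_id) if pro.father_id else None
    mother = by_id.get(pro.mother_id) if pro.mother_id else None

    calls: dict[VariantKey, InheritanceCall] = {}
    poo: dict[VariantKey, ParentOfOrigin] = {}
    hets: list[VariantRecord] = []

    for v in variants_in_gene:
        if proband not in v.genotypes:
            raise ValueError(f"proband {proband!r} absent from genotype map of {v.key}")
        dp = v.genotypes[proband]
        df = v.genotypes.get(father.sample_id) if father else None
        dm = v.genotypes.get(mother.sample_id) if mother else None

        models: set[InheritanceModel] = set()
        if dp is not None and dp >= 1 and df == 0 and dm == 0:
            models.add(InheritanceModel.de_novo)
        if dp == 2:
            parents_ok = all(d is None or d >= 1 for d in (df, dm))
            if parents_ok:
                models.add(InheritanceModel.recessive_hom)
        if dp == 1:
            for parent, d in ((father, df), (mother, dm)):
                if parent is not None and d is not None and d >= 1 and parent.affection == Affection.affected:
                    models.add(InheritanceModel.dominant_affected_parent)
        if v.origin == Origin.mitochondrial and dp is not None and dp >= 1:
            if dm is None or dm >= 1:
                models.add(InheritanceModel.mitochondrial)

        if dp == 1:
            hets.append(v)
            if df is not None and df >= 1 and dm == 0:
                poo[v.key] = ParentOfOrigin.paternal
            elif dm is not None and dm >= 1 and df == 0:
                poo[v.key] = ParentOfOrigin.maternal
            else:
                poo[v.key] = ParentOfOrigin.unknown

        if not models:
            models.add(InheritanceModel.unresolved)
        calls[v.key] = InheritanceCall(models=frozenset(models), parent_of_origin=dict(poo))

    # compound heterozygosity: opposite unambiguous parental origins ⇒ in trans
    hets.sort(key=VariantRecord.sort_key)
    for i, a in enumerate(hets):
        if calls[a.key].comphet_partner is not None:
            continue
        for b in hets[i + 1 :]:
            pa, pb = poo[a.key], poo[b.key]
            in_trans = {pa, pb} == {ParentOfOrigin.paternal, ParentOfOrigin.maternal}
            if in_trans:
                for x, partner in ((a, b), (b, a)):
                    old = calls[x.key]
                    calls[x.key] = InheritanceCall(
                        models=frozenset(
                            (old.models - {InheritanceModel.unresolved}) | {InheritanceModel.recessive_comphet}
                        ),
                        comphet_partner=partner.key,
                        parent_of_origin=dict(poo),
                    )
                break

    return calls


def segregation_filter(
    candidates: list[tuple[VariantRecord, InheritanceCall]],
    pedigree: list[SampleInfo],
    allow_mosaic_parent: bool = False,
) -> list[Candidate]:
    """Remove dominant-model contradictions.

    A variant whose call is not protected (de novo / recessive / mitochondrial)
    is removed when an explicitly unaffected relative carries it; relatives of
    unknown affection never count as contradicting.  With
    ``allow_mosaic_parent`` a contradiction limited to a parent keeps the
    variant, flagged as possible parental mosaicism.
    """
    by_id = {s.sample_id: s for s in pedigree}
    proband_ids = {s.sample_id for s in pedigree if s.is_proband}
    out: list[Candidate] = []
    for v, call in candidates:
        if call.models & PROTECTED_MODELS:
            out.append(Candidate(v, call))
            continue
        contradicting = [
            sid
            for sid, d in v.genotypes.items()
            if sid in by_id
            and sid not in proband_ids
            and d is not None
            and d >= 1
            and by_id[sid].affection == Affection.unaffected
        ]
        if not contradicting:
            out.append(Candidate(v, call))
            continue
        parents = {p for s in pedigree if s.is_proband for p in (s.father_id, s.mother_id) if p}
        if allow_mosaic_parent and all(sid in parents for sid in contradicting):
            out.append(Candidate(v, call, flags={"possible_parental_mosaicism"}))
    return out


def run_filtration(
    variants: list[VariantRecord],
    pedigree: list[SampleInfo],
    store: AnnotationStore,
    config: Optional[FiltrationConfig] = None,
) -> tuple[list[Candidate], FiltrationTally]:
    """Apply consequence → MAF → segregation, returning candidates and a tally."""
    cfg = config or FiltrationConfig()
    keep = frozenset(cfg.consequence_keep_set)
    proband = next(s.sample_id for s in pedigree if s.is_proband)

    tally = FiltrationTally(n_input=len(variants))
    stage1 = [v for v in variants if consequence_filter(v, keep)]
    tally.n_after_consequence = len(stage1)
    stage2 = [v for v in stage1 if maf_filter(store.freqs_for(v.key), cfg.maf_threshold)]
    tally.n_after_maf = len(stage2)

    by_gene: dict[str, list[VariantRecord]] = {}
    for v in stage2:
        by_gene.setdefault(v.gene, []).append(v)
    paired: list[tuple[VariantRecord, InheritanceCall]] = []
    for gene in sorted(by_gene):
        calls = infer_inheritance(by_gene[gene], pedigree, proband)
        for v in sorted(by_gene[gene], key=VariantRecord.sort_key):
            paired.append((v, calls[v.key]))

    candidates = segregation_filter(paired, pedigree, cfg.allow_mosaic_parent)
    # only variants actually carried by the proband are candidates
    candidates = [
        c for c in candidates
        if c.variant.genotypes.get(proband) is not None and c.variant.genotypes[proband] >= 1
    ]
    tally.n_after_segregation = len(candidates)
    candidates.sort(key=lambda c: c.variant.sort_key())
    tally.n_candidates = len(candidates)
    return candidates, tally
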