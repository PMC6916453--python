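"""Synthetic family-structured cohorts with planted diagnostic variants.

The generator emits everything a run consumes — per-family VCFs, a cohort
PED, the annotation TSVs, per-proband phenotype terms — plus a truth table
of what was planted, so pipeline recovery can be scored exactly.  Four
defect types emulating documented initial-analysis failure modes can be
injected into a copy of the dataset:

* ``splice_misannotation``   — a planted splice-site variant annotated as
  non-coding (it then fails the consequence filter)
* ``missense_to_noncoding``  — same corruption for a missense variant
* ``affection_flip``         — the affected carrier parent of a dominant
  case relabeled unaffected (the variant is then removed as a segregation
  contradiction)
* ``gene_link_removed``      — the gene-disease validity of a planted gene
  downgraded to none (the variant then fails the reporting gate)

Genotypes are generated directly (no read simulation): the triage procedure
consumes genotypes, and sequencing is upstream of its scope.  One seeded
generator drives all randomness; a fixed seed gives byte-identical output
files.
"""

from __future__ import annotations

import copy
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io_formats
from .config import RunConfig
from .models import (
    Affection,
    AnnotationStore,
    Arm,
    AssertedClass,
    Consequence,
    CuratedAssertion,
    GeneEvidence,
    GeneValidity,
    InheritanceMode,
    InheritanceModel,
    InSilicoScores,
    Origin,
    PopulationFrequencies,
    SampleInfo,
    Sex,
    Tier,
    ToolCall,
    VariantKey,
    VariantRecord,
    MISSENSE_TOOLS,
    POPULATION_SOURCES,
)
from .pipeline import CohortDataset, analyze_cohort
from .reporting import diff_reports
from .summary import CohortSummary, summarize

# --------------------------------------------------------------------------
# gene universe
# --------------------------------------------------------------------------

_VOCAB = [
    "seizures", "microcephaly", "developmental delay", "intellectual disability",
    "hypotonia", "spasticity", "ataxia", "peripheral neuropathy", "short stature",
    "scoliosis", "skeletal dysplasia", "joint laxity", "hearing loss",
    "optic atrophy", "retinal dystrophy", "cataract", "cardiomyopathy",
    "ventricular arrhythmia", "long qt interval", "aortic dilatation",
    "hepatomegaly", "renal cysts", "anemia", "immunodeficiency",
    "failure to thrive", "feeding difficulties", "cleft palate", "polydactyly",
    "ichthyosis", "alopecia", "lactic acidosis", "myopathy",
]

_GENE_LOCUS_SPACING = 1_000_000


def _gene_name(i: int) -> str:
    return f"SG{i + 1:03d}"


@dataclass(frozen=True)
class GeneLocus:
    evidence: GeneEvidence
    chrom: str
    start: int


def gene_universe() -> dict[str, GeneLocus]:
    """The fixed 60-gene synthetic universe.

    Index layout: 0–9 strong AD, 10–19 strong AR, 20–21 strong mitochondrial
    (21 on the sudden-death panel), 22–31 strong AD sudden-death panel,
    32–35 strong AR sudden-death panel, 36–43 moderate (even indices
    review-approved), 44–51 limited, 52–59 no established validity.
    """
    out: dict[str, GeneLocus] = {}
    for i in range(60):
        name = _gene_name(i)
        if 20 <= i <= 21:
            chrom = "chrM"
        else:
            chrom = f"chr{(i % 22) + 1}"
        terms = frozenset(_VOCAB[(i * 3 + j) % len(_VOCAB)] for j in range(3))
        if i <= 9:
            ev = GeneEvidence(name, GeneValidity.strong, frozenset({InheritanceMode.AD}),
                              terms, missense_constrained=i % 2 == 0, lof_mechanism=True)
        elif i <= 19:
            ev = GeneEvidence(name, GeneValidity.strong, frozenset({InheritanceMode.AR}),
                              terms, missense_constrained=i % 2 == 0, lof_mechanism=True)
        elif i <= 21:
            ev = GeneEvidence(name, GeneValidity.strong, frozenset({InheritanceMode.MT}),
                              terms, sd_panel=i == 21)
        elif i <= 31:
            ev = GeneEvidence(name, GeneValidity.strong, frozenset({InheritanceMode.AD}),
                              terms, missense_constrained=i % 2 == 0, lof_mechanism=True,
                              sd_panel=True)
        elif i <= 35:
            ev = GeneEvidence(name, GeneValidity.strong, frozenset({InheritanceMode.AR}),
                              terms, lof_mechanism=True, sd_panel=True)
        elif i <= 43:
            ev = GeneEvidence(name, GeneValidity.moderate, frozenset({InheritanceMode.AD}),
                              terms, lof_mechanism=True, moderate_approved=i % 2 == 0)
        elif i <= 51:
            ev = GeneEvidence(name, GeneValidity.limited, frozenset({InheritanceMode.AD}),
                              terms, supporting_data=i % 2 == 0)
        else:
            ev = GeneEvidence(name, GeneValidity.none, frozenset(),
                              terms, supporting_data=i % 2 == 0)
        out[name] = GeneLocus(ev, chrom, _GENE_LOCUS_SPACING * (i + 1))
    return out


#: the strong-validity genes host the planted findings and are kept free of
#: background sites, so genotype-only phase linkage of planted heterozygotes
#: can never pair them with an incidental background carrier
_RESERVED_FOR_PLANTING = frozenset(_gene_name(i) for i in range(36))
_BACKGROUND_CSQ = [
    (Consequence.missense, 0.45),
    (Consequence.synonymous, 0.30),
    (Consequence.noncoding, 0.20),
    (Consequence.inframe_indel, 0.03),
    (Consequence.other, 0.02),
]


# --------------------------------------------------------------------------
# cohort spec & truth
# --------------------------------------------------------------------------


@dataclass
class CohortSpec:
    seed: int = 0
    n_families: int = 50
    family_structure_mix: dict[str, float] = field(
        default_factory=lambda: {"trio": 0.8, "quad": 0.1, "singleton": 0.1}
    )
    arm: Arm = Arm.rare_disease
    planted_dv_fraction: float = 0.2
    inheritance_mix: dict[str, float] = field(
        default_factory=lambda: {
            "de_novo": 0.5,
            "recessive_hom": 0.1875,
            "recessive_comphet": 0.1875,
            "dominant_affected_parent": 0.0625,
            "mitochondrial": 0.0625,
        }
    )
    background_variants_per_case: int = 200
    background_panel_size: int = 1000
    background_af_range: tuple[float, float] = (1e-5, 0.5)
    planted_damaging_prob: float = 0.9
    background_damaging_prob: float = 0.15

    def __post_init__(self) -> None:
        for name, mix in (("family_structure_mix", self.family_structure_mix),
                          ("inheritance_mix", self.inheritance_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} fractions must sum to 1")


class DefectType(str, enum.Enum):
    splice_misannotation = "splice_misannotation"
    missense_to_noncoding = "missense_to_noncoding"
    affection_flip = "affection_flip"
    gene_link_removed = "gene_link_removed"


@dataclass
class PlantedVariant:
    proband_id: str
    family_id: str
    key: VariantKey
    gene: str
    model: InheritanceModel
    intended_tier: Tier
    intended_category: str = "DV"
    partner_key: Optional[VariantKey] = None


@dataclass
class DefectRecord:
    proband_id: str
    key: VariantKey
    defect: DefectType


@dataclass
class TruthTable:
    planted: list[PlantedVariant] = field(default_factory=list)
    defects: list[DefectRecord] = field(default_factory=list)

    def dv_probands(self) -> set[str]:
        return {p.proband_id for p in self.planted}


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    dataset: CohortDataset
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        """Emit the cohort as the on-disk formats the run command consumes."""
        outdir = Path(outdir)
        (outdir / "vcf").mkdir(parents=True, exist_ok=True)
        io_formats.write_ped(self.dataset.pedigree, outdir / "cohort.ped")
        by_family = self.dataset.families()
        for family_id in sorted(by_family):
            samples = sorted(s.sample_id for s in by_family[family_id])
            io_formats.write_vcf(
                self.dataset.variants.get(family_id, []), samples, outdir / "vcf" / f"{family_id}.vcf"
            )
        _write_annotation_tables(self.dataset.store, outdir)
        pheno = {pid: sorted(terms) for pid, terms in sorted(self.dataset.phenotypes.items())}
        (outdir / "phenotypes.json").write_text(json.dumps(pheno, indent=2, sort_keys=True) + "\n")
        truth = {
            "planted": [
                {
                    "proband_id": p.proband_id,
                    "family_id": p.family_id,
                    "variant": list(p.key),
                    "gene": p.gene,
                    "model": p.model.value,
                    "intended_tier": p.intended_tier.value,
                    "intended_category": p.intended_category,
                    "partner": list(p.partner_key) if p.partner_key else None,
                }
                for p in self.truth.planted
            ],
            "defects": [
                {"proband_id": d.proband_id, "variant": list(d.key), "defect": d.defect.value}
                for d in self.truth.defects
            ],
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def _write_annotation_tables(store: AnnotationStore, outdir: Path) -> None:
    import pandas as pd

    af_rows = []
    for key in sorted(store.pop_freqs):
        for source, af in sorted(store.pop_freqs[key].by_source.items()):
            af_rows.append((*key, source, af))
    pd.DataFrame(af_rows, columns=["chrom", "pos", "ref", "alt", "source", "af"]).to_csv(
        outdir / "pop_af.tsv", sep="\t", index=False
    )

    sc_rows = []
    for key in sorted(store.scores):
        sc = store.scores[key]
        for tool in sorted(sc.missense_calls):
            sc_rows.append((*key, tool, "", sc.missense_calls[tool].value))
        for tool in sorted(sc.splice_scores):
            sc_rows.append((*key, tool, round(sc.splice_scores[tool], 6), ""))
        if sc.conservation is not None:
            sc_rows.append((*key, "GERP", round(sc.conservation, 6), ""))
        for tool in sorted(sc.genomewide):
            sc_rows.append((*key, tool, round(sc.genomewide[tool], 6), ""))
    pd.DataFrame(sc_rows, columns=["chrom", "pos", "ref", "alt", "tool", "value", "call"]).to_csv(
        outdir / "scores.tsv", sep="\t", index=False
    )

    as_rows = []
    for key in sorted(store.assertions):
        ca = store.assertions[key]
        as_rows.append(
            (*key, ca.asserted_class.value, ca.review_level,
             str(ca.functional_evidence).lower(), str(ca.same_aa_pathogenic).lower(),
             ";".join(ca.user_codes))
        )
    pd.DataFrame(
        as_rows,
        columns=["chrom", "pos", "ref", "alt", "asserted_class", "review_level",
                 "functional_evidence", "same_aa_pathogenic", "user_codes"],
    ).to_csv(outdir / "assertions.tsv", sep="\t", index=False)

    g_rows = []
    for gene in sorted(store.genes):
        ge = store.genes[gene]
        g_rows.append(
            (gene, ge.validity.value, ",".join(sorted(m.value for m in ge.inheritance_modes)),
             ",".join(sorted(ge.phenotype_terms)), str(ge.missense_constrained).lower(),
             str(ge.lof_mechanism).lower(), str(ge.sd_panel).lower(),
             str(ge.supporting_data).lower(), str(ge.moderate_approved).lower())
        )
    pd.DataFrame(
        g_rows,
        columns=["gene", "validity", "inheritance_modes", "phenotype_terms",
                 "missense_constrained", "lof_mechanism", "sd_panel", "supporting_data",
                 "moderate_approved"],
    ).to_csv(outdir / "genes.tsv", sep="\t", index=False)


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

_BASES = ["A", "C", "G", "T"]


def _largest_remainder(fracs: dict[str, float], total: int) -> dict[str, int]:
    raw = {k: f * total for k, f in fracs.items()}
    counts = {k: math.floor(v) for k, v in raw.items()}
    leftover = total - sum(counts.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:leftover]:
        counts[k] += 1
    return counts


def _snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _alleles(rng: np.random.Generator, af: float) -> int:
    return int(rng.random() < af) + int(rng.random() < af)


def _inherit(rng: np.random.Generator, father: int, mother: int) -> int:
    return int(rng.random() < father / 2) + int(rng.random() < mother / 2)


@dataclass
class _PanelSite:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    af: float


def _build_panel(spec: CohortSpec, universe: dict[str, GeneLocus], rng: np.random.Generator) -> list[_PanelSite]:
    host_genes = sorted(
        g for g, loc in universe.items()
        if g not in _RESERVED_FOR_PLANTING and loc.chrom != "chrM"
    )
    csq, weights = zip(*_BACKGROUND_CSQ)
    lo, hi = spec.background_af_range
    sites = []
    used_pos: set[tuple[str, int]] = set()
    for _ in range(spec.background_panel_size):
        gene = host_genes[rng.integers(len(host_genes))]
        loc = universe[gene]
        pos = int(loc.start + rng.integers(50_000))
        while (loc.chrom, pos) in used_pos:
            pos = int(loc.start + rng.integers(50_000))
        used_pos.add((loc.chrom, pos))
        ref, alt = _snv(rng)
        af = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        c = csq[int(rng.choice(len(csq), p=weights))]
        sites.append(_PanelSite(gene, loc.chrom, pos, ref, alt, c, af))
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


_PLANTED_CSQ = {
    InheritanceModel.de_novo: [Consequence.nonsense, Consequence.splice_acceptor,
                               Consequence.missense, Consequence.frameshift],
    InheritanceModel.recessive_hom: [Consequence.nonsense, Consequence.frameshift],
    InheritanceModel.dominant_affected_parent: [Consequence.missense, Consequence.splice_donor],
    InheritanceModel.mitochondrial: [Consequence.missense],
}


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a deterministic cohort per the spec (fixed seed ⇒ identical files)."""
    rng = np.random.default_rng(spec.seed)
    universe = gene_universe()
    panel = _build_panel(spec, universe, rng)

    # family structures
    struct_counts = _largest_remainder(spec.family_structure_mix, spec.n_families)
    structures = (
        ["trio"] * struct_counts.get("trio", 0)
        + ["quad"] * struct_counts.get("quad", 0)
        + ["singleton"] * struct_counts.get("singleton", 0)
    )
    rng.shuffle(structures)

    # planted model assignment: only families with parents can host most models
    n_planted_cases = int(round(spec.planted_dv_fraction * spec.n_families))
    model_counts = _largest_remainder(spec.inheritance_mix, n_planted_cases)
    with_parents = [i for i, s in enumerate(structures) if s != "singleton"]
    if n_planted_cases > len(with_parents):
        raise ValueError(
            "infeasible mix: more planted cases than families with parental genotypes"
        )
    planted_models: dict[int, InheritanceModel] = {}
    slot = 0
    for model_name in sorted(model_counts):
        for _ in range(model_counts[model_name]):
            planted_models[with_parents[slot]] = InheritanceModel(model_name)
            slot += 1

    # host genes per model
    if spec.arm == Arm.rare_disease:
        ad_hosts = [_gene_name(i) for i in range(0, 10)]
        ar_hosts = [_gene_name(i) for i in range(10, 20)]
        mt_hosts = [_gene_name(20)]
    else:
        ad_hosts = [_gene_name(i) for i in range(22, 32)]
        ar_hosts = [_gene_name(i) for i in range(32, 36)]
        mt_hosts = [_gene_name(21)]
    host_cycle = {"ad": 0, "ar": 0, "mt": 0}
    csq_cycle = {m: 0 for m in _PLANTED_CSQ}
    planted_offset = 60_000  # planted positions live above the background range

    pedigree: list[SampleInfo] = []
    variants: dict[str, list[VariantRecord]] = {}
    phenotypes: dict[str, set[str]] = {}
    truth = TruthTable()
    store = AnnotationStore(genes={g: loc.evidence for g, loc in universe.items()})
    for site in panel:
        key = (site.chrom, site.pos, site.ref, site.alt)
        n_sources = 2 + int(rng.integers(3))
        sources = sorted(rng.choice(POPULATION_SOURCES, size=n_sources, replace=False))
        store.pop_freqs[key] = PopulationFrequencies({s: round(site.af, 8) for s in sources})
        store.scores[key] = _draw_scores(rng, site.consequence, spec.background_damaging_prob)

    deceased = spec.arm == Arm.sudden_death

    for i, structure in enumerate(structures):
        family_id = f"FAM{i + 1:03d}"
        pid = f"{family_id}_P"
        members = [
            SampleInfo(pid, family_id, sex=Sex.female if i % 2 else Sex.male,
                       affection=Affection.affected, is_proband=True, is_deceased=deceased)
        ]
        father = mother = sibling = None
        if structure in ("trio", "quad"):
            father = SampleInfo(f"{family_id}_F", family_id, sex=Sex.male,
                                affection=Affection.unaffected)
            mother = SampleInfo(f"{family_id}_M", family_id, sex=Sex.female,
                                affection=Affection.unaffected)
            members[0].father_id = father.sample_id
            members[0].mother_id = mother.sample_id
            members += [father, mother]
        if structure == "quad":
            sibling = SampleInfo(f"{family_id}_S", family_id, sex=Sex.male,
                                 affection=Affection.unaffected,
                                 father_id=father.sample_id, mother_id=mother.sample_id)
            members.append(sibling)
        pedigree.extend(members)
        sample_ids = [m.sample_id for m in members]
        fam_variants: list[VariantRecord] = []

        # ---- planted diagnostic variant(s) -----------------------------
        model = planted_models.get(i)
        if model is not None:
            fam_variants += _plant(
                spec, rng, universe, store, truth, family_id, pid, sample_ids, model,
                ad_hosts, ar_hosts, mt_hosts, host_cycle, csq_cycle, planted_offset, i,
            )
            if model == InheritanceModel.dominant_affected_parent:
                father.affection = Affection.affected
            gene = truth.planted[-1].gene
            gene_terms = sorted(universe[gene].evidence.phenotype_terms)
            extra = [t for t in _VOCAB if t not in gene_terms]
            phenotypes[pid] = set(gene_terms[:2]) | {extra[int(rng.integers(len(extra)))]}
        else:
            phenotypes[pid] = set(rng.choice(_VOCAB, size=3, replace=False).tolist())

        # ---- background variants --------------------------------------
        idx = rng.choice(len(panel), size=min(spec.background_variants_per_case, len(panel)),
                         replace=False)
        for j in sorted(idx.tolist()):
            site = panel[j]
            gt: dict[str, Optional[int]] = {}
            if father is not None:
                df = _alleles(rng, site.af)
                dm = _alleles(rng, site.af)
                if df == 0 and dm == 0:
                    # the site was drawn for this family, so someone carries it
                    if rng.random() < 0.5:
                        df = 1
                    else:
                        dm = 1
                gt[father.sample_id] = df
                gt[mother.sample_id] = dm
                gt[pid] = _inherit(rng, df, dm)
                if sibling is not None:
                    gt[sibling.sample_id] = _inherit(rng, df, dm)
            else:
                d = _alleles(rng, site.af)
                gt[pid] = d if d > 0 else 1
            fam_variants.append(
                VariantRecord(
                    chrom=site.chrom, pos=site.pos, ref=site.ref, alt=site.alt,
                    gene=site.gene, transcript=f"NM_{site.gene}.1",
                    hgvs_c=f"c.{site.pos % 5000 + 1}{site.ref}>{site.alt}",
                    consequence=site.consequence, genotypes=gt, origin=Origin.autosomal,
                )
            )

        fam_variants.sort(key=VariantRecord.sort_key)
        variants[family_id] = fam_variants

    dataset = CohortDataset(
        pedigree=pedigree, variants=variants, store=store, phenotypes=phenotypes, arm=spec.arm
    )
    return SyntheticCohort(spec=spec, dataset=dataset, truth=truth)


def _draw_scores(rng: np.random.Generator, csq: Consequence, p_damaging: float) -> InSilicoScores:
    calls = {
        tool: ToolCall.damaging if rng.random() < p_damaging else ToolCall.tolerated
        for tool in MISSENSE_TOOLS
    }
    splice = {
        "SpliceAI": float(rng.uniform(0, 0.15)),
        "dbscSNV_Ada": float(rng.uniform(0, 0.15)),
    }
    if csq in (Consequence.splice_acceptor, Consequence.splice_donor):
        splice = {"SpliceAI": float(rng.uniform(0.85, 0.99)),
                  "dbscSNV_Ada": float(rng.uniform(0.85, 0.99))}
    return InSilicoScores(
        missense_calls=calls,
        splice_scores=splice,
        conservation=float(rng.uniform(-2, 6)),
        genomewide={"GenoCanyon": float(rng.uniform(0, 1))},
    )


def _plant(
    spec: CohortSpec,
    rng: np.random.Generator,
    universe: dict[str, GeneLocus],
    store: AnnotationStore,
    truth: TruthTable,
    family_id: str,
    pid: str,
    sample_ids: list[str],
    model: InheritanceModel,
    ad_hosts: list[str],
    ar_hosts: list[str],
    mt_hosts: list[str],
    host_cycle: dict,
    csq_cycle: dict,
    planted_offset: int,
    family_index: int,
) -> list[VariantRecord]:
    """Create the planted variant(s) for one diagnostic case."""
    father = f"{family_id}_F"
    mother = f"{family_id}_M"
    sibling = f"{family_id}_S" if f"{family_id}_S" in sample_ids else None

    def make_variant(gene: str, csq: Consequence, genotypes: dict, nth: int) -> VariantRecord:
        loc = universe[gene]
        pos = loc.start + planted_offset + family_index * 40 + nth * 10
        ref, alt = _snv(np.random.default_rng(spec.seed * 100_003 + pos % 97_561))
        if csq == Consequence.frameshift:
            alt = ref + alt  # one-base insertion
        origin = Origin.mitochondrial if loc.chrom == "chrM" else Origin.autosomal
        return VariantRecord(
            chrom=loc.chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            transcript=f"NM_{gene}.1",
            hgvs_c=f"c.{pos % 5000 + 1}{ref}>{alt}",
            consequence=csq, genotypes=genotypes, origin=origin,
        )

    def annotate(v: VariantRecord, missense_like: bool) -> None:
        # absent from every population source; strong computational support;
        # curated functional evidence (and same-residue match for missense)
        store.scores[v.key] = _draw_scores(rng, v.consequence, spec.planted_damaging_prob)
        store.assertions[v.key] = CuratedAssertion(
            asserted_class=AssertedClass.P,
            review_level=3,
            functional_evidence=not missense_like,
            same_aa_pathogenic=missense_like,
        )

    out: list[VariantRecord] = []
    if model == InheritanceModel.recessive_comphet:
        gene = ar_hosts[host_cycle["ar"] % len(ar_hosts)]
        host_cycle["ar"] += 1
        csq_a = [Consequence.frameshift, Consequence.nonsense][host_cycle["ar"] % 2]
        gt_a = {pid: 1, father: 1, mother: 0}
        gt_b = {pid: 1, father: 0, mother: 1}
        if sibling:
            gt_a[sibling] = 1
            gt_b[sibling] = 0
        va = make_variant(gene, csq_a, gt_a, 0)
        vb = make_variant(gene, Consequence.missense, gt_b, 1)
        annotate(va, missense_like=False)
        store.scores[vb.key] = _draw_scores(rng, vb.consequence, spec.planted_damaging_prob)
        store.assertions[vb.key] = CuratedAssertion(
            asserted_class=AssertedClass.LP, review_level=3, same_aa_pathogenic=True
        )
        truth.planted.append(PlantedVariant(pid, family_id, va.key, gene, model,
                                            Tier.P, partner_key=vb.key))
        truth.planted.append(PlantedVariant(pid, family_id, vb.key, gene, model,
                                            Tier.LP, partner_key=va.key))
        out += [va, vb]
        return out

    if model == InheritanceModel.de_novo:
        gene = ad_hosts[host_cycle["ad"] % len(ad_hosts)]
        host_cycle["ad"] += 1
        gt = {pid: 1, father: 0, mother: 0}
        if sibling:
            gt[sibling] = 0
    elif model == InheritanceModel.recessive_hom:
        gene = ar_hosts[host_cycle["ar"] % len(ar_hosts)]
        host_cycle["ar"] += 1
        gt = {pid: 2, father: 1, mother: 1}
        if sibling:
            gt[sibling] = 1
    elif model == InheritanceModel.dominant_affected_parent:
        gene = ad_hosts[host_cycle["ad"] % len(ad_hosts)]
        host_cycle["ad"] += 1
        gt = {pid: 1, father: 1, mother: 0}
        if sibling:
            gt[sibling] = 0
    elif model == InheritanceModel.mitochondrial:
        gene = mt_hosts[host_cycle["mt"] % len(mt_hosts)]
        host_cycle["mt"] += 1
        gt = {pid: 1, father: 0, mother: 1}
        if sibling:
            gt[sibling] = 1
    else:  # pragma: no cover
        raise ValueError(f"cannot plant model {model}")
    csq_list = _PLANTED_CSQ[model]
    csq = csq_list[csq_cycle[model] % len(csq_list)]
    csq_cycle[model] += 1
    v = make_variant(gene, csq, gt, 0)
    annotate(v, missense_like=csq == Consequence.missense)
    truth.planted.append(PlantedVariant(pid, family_id, v.key, gene, model, Tier.P))
    out.append(v)
    return out


def _flip_affected_parent(cohort: SyntheticCohort, planted: PlantedVariant) -> str:
    """Mark the affected carrier parent of a dominant case unaffected; returns its id."""
    fam = [s for s in cohort.dataset.pedigree if s.family_id == planted.family_id]
    v = next(
        x for x in cohort.dataset.variants[planted.family_id] if x.key == planted.key
    )
    for s in fam:
        if s.is_proband:
            continue
        if s.affection == Affection.affected and (v.genotypes.get(s.sample_id) or 0) >= 1:
            s.affection = Affection.unaffected
            return s.sample_id
    raise ValueError(f"no affected carrier parent to flip in {planted.family_id}")


def inject_defects(
    cohort: SyntheticCohort, defects: list[DefectType | str], seed: int = 0
) -> tuple[SyntheticCohort, list[DefectRecord]]:
    """Return a degraded deep copy of the cohort plus the defect log.

    Each defect targets one distinct planted single-variant diagnostic case
    chosen deterministically (shuffled by ``seed``); the original cohort is
    untouched.
    """
    defects = [DefectType(d) for d in defects]
    degraded = copy.deepcopy(cohort)
    rng = np.random.default_rng(seed)

    # comphet cases carry a second diagnostic variant, so corrupting one
    # partner would not remove the diagnosis; target single-variant cases
    singles = [p for p in degraded.truth.planted
               if p.model != InheritanceModel.recessive_comphet]
    rng.shuffle(singles)
    used: set[str] = set()
    log: list[DefectRecord] = []

    def take(pred, defect: DefectType) -> PlantedVariant:
        for p in singles:
            if p.proband_id in used:
                continue
            if pred(p):
                used.add(p.proband_id)
                return p
        raise ValueError(f"no eligible planted finding for defect {defect.value}")

    for defect in defects:
        if defect == DefectType.affection_flip:
            p = take(lambda p: p.model == InheritanceModel.dominant_affected_parent, defect)
            _flip_affected_parent(degraded, p)
        elif defect == DefectType.splice_misannotation:
            p = take(
                lambda p: _csq_of(degraded, p) in (Consequence.splice_acceptor, Consequence.splice_donor),
                defect,
            )
            _rewrite_csq(degraded, p, Consequence.noncoding)
        elif defect == DefectType.missense_to_noncoding:
            p = take(lambda p: _csq_of(degraded, p) == Consequence.missense, defect)
            _rewrite_csq(degraded, p, Consequence.noncoding)
        elif defect == DefectType.gene_link_removed:
            # the gene must host no other case's finding, or removing the
            # gene-disease link would knock out more than one diagnosis
            gene_counts: dict[str, int] = {}
            for q in degraded.truth.planted:
                gene_counts[q.gene] = gene_counts.get(q.gene, 0) + 1
            p = take(lambda p: gene_counts[p.gene] == 1, defect)
            ge = degraded.dataset.store.genes[p.gene]
            degraded.dataset.store.genes[p.gene] = GeneEvidence(
                gene=ge.gene, validity=GeneValidity.none,
                inheritance_modes=ge.inheritance_modes,
                phenotype_terms=ge.phenotype_terms,
                missense_constrained=ge.missense_constrained,
                lof_mechanism=ge.lof_mechanism, sd_panel=False,
                supporting_data=False, moderate_approved=False,
            )
        log.append(DefectRecord(p.proband_id, p.key, defect))
    degraded.truth.defects = log
    return degraded, log


def _csq_of(cohort: SyntheticCohort, planted: PlantedVariant) -> Consequence:
    v = next(x for x in cohort.dataset.variants[planted.family_id] if x.key == planted.key)
    return v.consequence


def _rewrite_csq(cohort: SyntheticCohort, planted: PlantedVariant, csq: Consequence) -> None:
    v = next(x for x in cohort.dataset.variants[planted.family_id] if x.key == planted.key)
    v.consequence = csq


# --------------------------------------------------------------------------
# validation & experiment
# --------------------------------------------------------------------------


def mendelian_violations(dataset: CohortDataset, exclude: set[VariantKey] = frozenset()) -> list[tuple]:
    """Independent transmission check for autosomal genotypes.

    Returns (family, key, child) tuples where a child's genotype cannot be
    formed from one allele of each parent.  ``exclude`` lists keys (planted
    de novos) that are deliberately non-Mendelian.
    """
    allowed = {
        (0, 0): {0}, (0, 1): {0, 1}, (0, 2): {1},
        (1, 1): {0, 1, 2}, (1, 2): {1, 2}, (2, 2): {2},
    }
    out = []
    families = dataset.families()
    for family_id, members in families.items():
        by_id = {s.sample_id: s for s in members}
        for v in dataset.variants.get(family_id, []):
            if v.key in exclude or v.origin == Origin.mitochondrial:
                continue
            for s in members:
                if not (s.father_id and s.mother_id):
                    continue
                d = v.genotypes.get(s.sample_id)
                df = v.genotypes.get(s.father_id)
                dm = v.genotypes.get(s.mother_id)
                if None in (d, df, dm):
                    continue
                lo, hi = sorted((df, dm))
                if d not in allowed[(lo, hi)]:
                    out.append((family_id, v.key, s.sample_id))
    return out


@dataclass
class ExperimentResult:
    summary: CohortSummary
    deltas: list
    defect_log: list[DefectRecord]
    reports_initial: dict
    reports_final: dict
    truth: TruthTable


def reanalysis_experiment(
    spec: CohortSpec,
    defects: list[DefectType | str],
    config: Optional[RunConfig] = None,
) -> ExperimentResult:
    """Run the degraded-then-clean re-analysis emulation.

    The degraded dataset plays the initial analysis, the clean dataset the
    re-analysis; reports are diffed per proband with the defect log as
    provenance, and yields summarized per arm.
    """
    cohort = generate_cohort(spec)
    degraded, log = inject_defects(cohort, defects, seed=spec.seed + 1)
    cfg = config or RunConfig(arm=spec.arm)
    reports_initial, _ = analyze_cohort(degraded.dataset, cfg)
    reports_final, _ = analyze_cohort(cohort.dataset, cfg)

    provenance_by_proband: dict[str, dict[VariantKey, str]] = {}
    for rec in log:
        provenance_by_proband.setdefault(rec.proband_id, {})[rec.key] = rec.defect.value
    deltas = []
    for pid in sorted(reports_final):
        delta = diff_reports(
            reports_initial[pid], reports_final[pid], provenance_by_proband.get(pid)
        )
        if delta.new_findings or delta.upgraded:
            deltas.append(delta)
    summary = summarize(list(reports_initial.values()), list(reports_final.values()))
    return ExperimentResult(summary, deltas, log, reports_initial, reports_final, cohort.truth)


def recovery_scores(
    cohort: SyntheticCohort, config: Optional[RunConfig] = None
) -> tuple[float, float]:
    """Sensitivity and specificity of diagnostic-case recovery vs the truth table."""
    cfg = config or RunConfig(arm=cohort.spec.arm)
    reports, _ = analyze_cohort(cohort.dataset, cfg)
    truth_pos = cohort.truth.dv_probands()
    called_pos = {pid for pid, r in reports.items() if r.case_status.value == "positive"}
    all_probands = set(reports)
    tp = len(truth_pos & called_pos)
    fn = len(truth_pos - called_pos)
    fp = len(called_pos - truth_pos)
    tn = len(all_probands - truth_pos - called_pos)
    sens = tp / (tp + fn) if tp + fn else 1.0
    spec_ = tn / (tn + fp) if tn + fp else 1.0
    return sens, spec_
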