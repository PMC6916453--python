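"""Readers and writers for the standard formats the pipeline touches.

VCF reading goes through cyvcf2; multi-allelic sites are decomposed into one
biallelic record per alt allele and indels are trimmed (common suffix, then
common prefix with the position advanced), so the in-memory representation is
always normalized and keyed by ``(chrom, pos, ref, alt)``.

Annotation tables are plain TSVs read with pandas; the expected headers are

* ``pop_af.tsv``      — chrom pos ref alt source af
* ``scores.tsv``      — chrom pos ref alt tool value call
* ``assertions.tsv``  — chrom pos ref alt asserted_class review_level
                        functional_evidence same_aa_pathogenic [user_codes]
* ``genes.tsv``       — gene validity inheritance_modes phenotype_terms
                        missense_constrained lof_mechanism sd_panel
                        supporting_data [moderate_approved]
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from cyvcf2 import VCF

from .models import (
    Affection,
    AnnotationStore,
    Arm,
    AssertedClass,
    CaseReport,
    Category,
    Classification,
    Consequence,
    CuratedAssertion,
    Dosage,
    Finding,
    GeneEvidence,
    GeneValidity,
    InheritanceCall,
    InheritanceMode,
    InheritanceModel,
    InSilicoScores,
    Origin,
    ParentOfOrigin,
    PopulationFrequencies,
    ReportCategory,
    SampleInfo,
    Sex,
    Tier,
    ToolCall,
    VariantKey,
    VariantRecord,
    MISSENSE_TOOLS,
    POPULATION_SOURCES,
    SPLICE_TOOLS,
    GENOMEWIDE_TOOLS,
)

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------


def trim_allele_pair(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim a ref/alt pair to its minimal representation.

    Common suffix is removed first, then common prefix (advancing ``pos``),
    always leaving at least one base on each side.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


# --------------------------------------------------------------------------
# PED
# --------------------------------------------------------------------------

_SEX_CODES = {"1": Sex.male, "2": Sex.female}
_AFF_CODES = {"1": Affection.unaffected, "2": Affection.affected}


def read_ped(path: str | Path, proband_ids: Optional[set[str]] = None) -> list[SampleInfo]:
    """Parse a whitespace-delimited 6-column PED file.

    ``0`` encodes a missing parent; phenotype 2=affected, 1=unaffected,
    0=unknown.  The proband defaults to the first affected non-founder in
    each family (first affected member if all are founders) unless
    ``proband_ids`` names them explicitly.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 PED columns, got {len(fields)}")
            if len(fields) > 6:
                log.warning("%s: line %d: ignoring %d extra PED columns", path, lineno, len(fields) - 6)
            rows.append(fields[:6])

    samples: dict[str, SampleInfo] = {}
    for fam, sid, fid, mid, sex, pheno in rows:
        if sid in samples:
            raise ValueError(f"duplicate sample_id {sid!r} in {path}")
        samples[sid] = SampleInfo(
            sample_id=sid,
            family_id=fam,
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            sex=_SEX_CODES.get(sex, Sex.unknown),
            affection=_AFF_CODES.get(pheno, Affection.unknown),
        )

    for s in samples.values():
        for pid in (s.father_id, s.mother_id):
            if pid is not None:
                if pid not in samples:
                    raise ValueError(f"sample {s.sample_id}: parent {pid!r} not in pedigree")
                if samples[pid].family_id != s.family_id:
                    raise ValueError(f"sample {s.sample_id}: parent {pid!r} in a different family")
    _check_acyclic(samples)

    by_family: dict[str, list[SampleInfo]] = {}
    for s in samples.values():
        by_family.setdefault(s.family_id, []).append(s)
    for members in by_family.values():
        chosen = None
        if proband_ids:
            chosen = next((m for m in members if m.sample_id in proband_ids), None)
        if chosen is None:
            affected = [m for m in members if m.affection == Affection.affected]
            nonfounder = [m for m in affected if m.father_id or m.mother_id]
            chosen = (nonfounder or affected or members)[0]
        chosen.is_proband = True
    return list(samples.values())


def _check_acyclic(samples: dict[str, SampleInfo]) -> None:
    state: dict[str, int] = {}  # 0 in-progress, 1 done

    def visit(sid: str, stack: list[str]) -> None:
        if state.get(sid) == 1:
            return
        if state.get(sid) == 0:
            raise ValueError(f"cyclic parentage involving {' -> '.join(stack + [sid])}")
        state[sid] = 0
        s = samples[sid]
        for pid in (s.father_id, s.mother_id):
            if pid is not None:
                visit(pid, stack + [sid])
        state[sid] = 1

    for sid in samples:
        visit(sid, [])


def write_ped(pedigree: Iterable[SampleInfo], path: str | Path) -> None:
    sex_out = {Sex.male: "1", Sex.female: "2", Sex.unknown: "0"}
    aff_out = {Affection.affected: "2", Affection.unaffected: "1", Affection.unknown: "0"}
    ordered = sorted(pedigree, key=lambda s: (s.family_id, s.sample_id))
    with open(path, "w") as fh:
        for s in ordered:
            fh.write(
                "\t".join(
                    [
                        s.family_id,
                        s.sample_id,
                        s.father_id or "0",
                        s.mother_id or "0",
                        sex_out[s.sex],
                        aff_out[s.affection],
                    ]
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

_INFO_KEYS = ("GENE", "TRANSCRIPT", "CSQ", "HGVSC", "HGVSP", "ORIGIN")


def read_vcf(path: str | Path, pedigree: list[SampleInfo]) -> list[VariantRecord]:
    """Read an annotated multi-sample VCF into normalized biallelic records.

    Every pedigree sample must be present in the VCF header.  Multi-allelic
    sites yield one record per alt allele, with genotypes recoded as the
    dosage of that alt (other alts count as 0, fully missing calls as None).
    """
    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    ped_ids = [s.sample_id for s in pedigree]
    missing = sorted(set(ped_ids) - set(vcf_samples))
    if missing:
        raise ValueError(f"pedigree/VCF mismatch: samples {missing} absent from {path}")
    sample_idx = {sid: vcf_samples.index(sid) for sid in ped_ids}

    records: list[VariantRecord] = []
    for i, v in enumerate(vcf):
        try:
            records.extend(_decompose(v, sample_idx))
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"{path}: unparseable VCF record #{i + 1} at {v.CHROM}:{v.POS}: {exc}") from exc
    records.sort(key=VariantRecord.sort_key)
    return records


def _decompose(v, sample_idx: dict[str, int]) -> list[VariantRecord]:
    out = []
    gts = v.genotypes  # [[a0, a1, phased], ...]
    for alt_i, alt in enumerate(v.ALT, start=1):
        genotypes: dict[str, Dosage] = {}
        for sid, col in sample_idx.items():
            alleles = gts[col][:-1]
            if any(a < 0 for a in alleles):
                genotypes[sid] = None
            else:
                genotypes[sid] = sum(1 for a in alleles if a == alt_i)
        pos, ref, alt_t = trim_allele_pair(v.POS, v.REF, alt)
        info = {k: v.INFO.get(k) for k in _INFO_KEYS}
        out.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=pos,
                ref=ref,
                alt=alt_t,
                gene=info["GENE"] or "",
                transcript=info["TRANSCRIPT"] or "",
                hgvs_c=info["HGVSC"] or "",
                hgvs_p=info["HGVSP"],
                consequence=Consequence(info["CSQ"]) if info["CSQ"] else Consequence.other,
                genotypes=genotypes,
                origin=Origin(info["ORIGIN"]) if info["ORIGIN"] else Origin.autosomal,
            )
        )
    return out


def write_vcf(variants: Iterable[VariantRecord], samples: list[str], path: str | Path) -> None:
    """Write normalized records as a minimal annotated VCF v4.2."""
    variants = sorted(variants, key=VariantRecord.sort_key)
    contigs = []
    for v in variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in sorted(contigs)]
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Transcript">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Functional consequence">',
        '##INFO=<ID=HGVSC,Number=1,Type=String,Description="HGVS cDNA">',
        '##INFO=<ID=HGVSP,Number=1,Type=String,Description="HGVS protein">',
        '##INFO=<ID=ORIGIN,Number=1,Type=String,Description="autosomal|mitochondrial|x_linked">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    gt_out = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
    for v in variants:
        info = [f"GENE={v.gene}", f"TRANSCRIPT={v.transcript}", f"CSQ={v.consequence.value}"]
        if v.hgvs_c:
            info.append(f"HGVSC={v.hgvs_c}")
        if v.hgvs_p:
            info.append(f"HGVSP={v.hgvs_p}")
        info.append(f"ORIGIN={v.origin.value}")
        gts = "\t".join(gt_out[v.genotypes.get(s)] for s in samples)
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{';'.join(info)}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# annotation tables
# --------------------------------------------------------------------------


def _key_of(row) -> VariantKey:
    return (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))


def read_annotations(
    pop_af: Optional[str | Path] = None,
    scores: Optional[str | Path] = None,
    assertions: Optional[str | Path] = None,
    genes: Optional[str | Path] = None,
    cadd_cut: float = 20.0,
) -> AnnotationStore:
    """Load the TSV annotation tables into an AnnotationStore.

    Raw CADD values (an empty ``call`` column) are converted to a
    damaging/tolerated call at ``cadd_cut``; all other missense tools must
    provide calls directly.
    """
    store = AnnotationStore()
    if pop_af is not None:
        df = pd.read_csv(pop_af, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        for i, row in enumerate(df.itertuples(index=False)):
            af = float(row.af)
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"{pop_af}: row {i + 2}: AF {af} outside [0,1]")
            if row.source not in POPULATION_SOURCES:
                raise ValueError(f"{pop_af}: row {i + 2}: unknown source {row.source!r}")
            pf = store.pop_freqs.setdefault(_key_of(row), PopulationFrequencies())
            if row.source in pf.by_source and pf.by_source[row.source] != af:
                raise ValueError(
                    f"{pop_af}: row {i + 2}: conflicting AF for "
                    f"{_key_of(row)} source {row.source}"
                )
            pf.by_source[str(row.source)] = af
    if scores is not None:
        df = pd.read_csv(scores, sep="\t", dtype={"chrom": str, "ref": str, "alt": str}, keep_default_na=False)
        for i, row in enumerate(df.itertuples(index=False)):
            sc = store.scores.setdefault(_key_of(row), InSilicoScores())
            tool, call = str(row.tool), str(row.call)
            value = None if row.value == "" else float(row.value)
            if tool in MISSENSE_TOOLS:
                if not call and tool == "CADD" and value is not None:
                    call = "damaging" if value >= cadd_cut else "tolerated"
                sc.missense_calls[tool] = ToolCall(call) if call else ToolCall.unknown
            elif tool in SPLICE_TOOLS:
                if value is None or not 0.0 <= value <= 1.0:
                    raise ValueError(f"{scores}: row {i + 2}: splice score {value} outside [0,1]")
                sc.splice_scores[tool] = value
            elif tool == "GERP":
                sc.conservation = value
            elif tool in GENOMEWIDE_TOOLS:
                if value is None or not 0.0 <= value <= 1.0:
                    raise ValueError(f"{scores}: row {i + 2}: score {value} outside [0,1]")
                sc.genomewide[tool] = value
            else:
                raise ValueError(f"{scores}: row {i + 2}: unknown tool {tool!r}")
    if assertions is not None:
        df = pd.read_csv(assertions, sep="\t", dtype={"chrom": str, "ref": str, "alt": str}, keep_default_na=False)
        for row in df.itertuples(index=False):
            codes = tuple(c for c in str(getattr(row, "user_codes", "")).split(";") if c)
            store.assertions[_key_of(row)] = CuratedAssertion(
                asserted_class=AssertedClass(str(row.asserted_class)),
                review_level=int(row.review_level),
                functional_evidence=_as_bool(row.functional_evidence),
                same_aa_pathogenic=_as_bool(row.same_aa_pathogenic),
                user_codes=codes,
            )
    if genes is not None:
        df = pd.read_csv(genes, sep="\t", keep_default_na=False)
        for row in df.itertuples(index=False):
            store.genes[str(row.gene)] = GeneEvidence(
                gene=str(row.gene),
                validity=GeneValidity(str(row.validity)),
                inheritance_modes=frozenset(
                    InheritanceMode(m) for m in str(row.inheritance_modes).split(",") if m
                ),
                phenotype_terms=frozenset(
                    t.strip() for t in str(row.phenotype_terms).split(",") if t.strip()
                ),
                missense_constrained=_as_bool(row.missense_constrained),
                lof_mechanism=_as_bool(row.lof_mechanism),
                sd_panel=_as_bool(row.sd_panel),
                supporting_data=_as_bool(row.supporting_data),
                moderate_approved=_as_bool(getattr(row, "moderate_approved", False)),
            )
    return store


def _as_bool(x) -> bool:
    return str(x).strip().lower() in {"1", "true", "yes"}


# --------------------------------------------------------------------------
# case reports
# --------------------------------------------------------------------------


def _finding_to_dict(f: Finding) -> dict:
    from .acmg import CriteriaSet  # local import to avoid cycle at module load

    assert isinstance(f.criteria, CriteriaSet)
    return {
        "variant": {
            "chrom": f.variant.chrom,
            "pos": f.variant.pos,
            "ref": f.variant.ref,
            "alt": f.variant.alt,
            "gene": f.variant.gene,
            "transcript": f.variant.transcript,
            "hgvs_c": f.variant.hgvs_c,
            "hgvs_p": f.variant.hgvs_p,
            "consequence": f.variant.consequence.value,
            "origin": f.variant.origin.value,
        },
        "criteria": f.criteria.to_strings(),
        "classification": f.classification.tier.value,
        "category": f.report.category.value,
        "rationale": f.report.rationale,
        "inheritance": sorted(m.value for m in f.inheritance.models),
        "flags": sorted(f.flags),
    }


def write_case_report(report: CaseReport, path: str | Path, format: str = "json") -> None:
    """Serialize a case report deterministically (sorted keys, fixed columns)."""
    path = Path(path)
    payload = {
        "proband_id": report.proband_id,
        "arm": report.arm.value,
        "case_status": report.case_status.value,
        "findings": [_finding_to_dict(f) for f in report.findings],
    }
    for f in payload["findings"]:
        for code in f["criteria"]:
            if code.split("-")[0] in {"PP5", "BP6"}:
                raise AssertionError("PP5/BP6 must never be serialized")
    if format == "json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        cols = [
            "proband_id", "arm", "case_status", "chrom", "pos", "ref", "alt", "gene",
            "hgvs_c", "consequence", "criteria", "classification", "category",
            "inheritance", "rationale",
        ]
        rows = []
        if not report.findings:
            rows.append({
                "proband_id": report.proband_id, "arm": report.arm.value,
                "case_status": report.case_status.value,
            })
        for f in payload["findings"]:
            rows.append({
                "proband_id": report.proband_id,
                "arm": report.arm.value,
                "case_status": report.case_status.value,
                **{k: f["variant"][k] for k in ("chrom", "pos", "ref", "alt", "gene", "hgvs_c", "consequence")},
                "criteria": ";".join(f["criteria"]),
                "classification": f["classification"],
                "category": f["category"],
                "inheritance": ";".join(f["inheritance"]),
                "rationale": f["rationale"],
            })
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_case_report(path: str | Path) -> CaseReport:
    """Parse a JSON case report back into objects (round-trip of write)."""
    from .acmg import CriteriaSet

    data = json.loads(Path(path).read_text())
    findings = []
    for f in data["findings"]:
        v = f["variant"]
        findings.append(
            Finding(
                variant=VariantRecord(
                    chrom=v["chrom"], pos=v["pos"], ref=v["ref"], alt=v["alt"],
                    gene=v["gene"], transcript=v["transcript"], hgvs_c=v["hgvs_c"],
                    hgvs_p=v["hgvs_p"], consequence=Consequence(v["consequence"]),
                    origin=Origin(v["origin"]),
                ),
                criteria=CriteriaSet.from_strings(f["criteria"]),
                classification=Classification(Tier(f["classification"])),
                report=ReportCategory(Category(f["category"]), rationale=f["rationale"]),
                inheritance=InheritanceCall(
                    models=frozenset(InheritanceModel(m) for m in f["inheritance"])
                ),
                flags=frozenset(f["flags"]),
            )
        )
    return CaseReport(proband_id=data["proband_id"], arm=Arm(data["arm"]), findings=findings)
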