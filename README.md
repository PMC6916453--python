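# reanalyzer

Family-aware triage of clinical exome data for **re-analysis** studies:
rare-variant filtration, automated ACMG/AMP classification, gene-evidence
gating, four-category clinical reporting, initial-vs-reanalysis diffing,
and cohort diagnostic-yield summarization — with a seeded synthetic-cohort
generator so the whole procedure can be exercised and scored end to end.

## Who this is for

Undiagnosed rare-disease and molecular-autopsy programs periodically
re-analyze old exomes: annotations improve, gene-disease links accumulate,
and family histories get corrected, so cases negative at first analysis can
become diagnostic years later. This package implements that triage loop as
a deterministic, testable pipeline over standard inputs (multi-sample VCF,
6-column PED, TSV annotation tables), for people who want to study *why*
re-analysis yields new diagnoses rather than to run a production lab stack.

## The procedure

For each family, candidate variants survive three filters —

1. consequence class ∈ {missense, nonsense, frameshift, splice acceptor/donor},
2. max population AF over {ExAC, 1000G, ESP, UK10K, gnomAD, internal} < 1% (strict),
3. family segregation: a non-protected variant carried by an explicitly
   unaffected relative is removed (de novo, homozygous/compound-het
   recessive, and mitochondrial calls are protected; *unknown* affection
   never contradicts)

— then receive ACMG/AMP evidence codes (PVS1, PS1–PS3, PM2, PM3, PP1–PP3,
BA1, BS1, BP4, BP7 auto-assigned; the rest user-assertable), combined by
the standard rule table with strength modifiers respected, into
B < LB < VUS-PB < VUS-U < VUS-PP < LP < P. Following the ClinGen SVI
recommendation, the reputable-source codes **PP5/BP6 are unrepresentable**;
curated-assertion evidence enters as PS3 (functional) or PS1 (same residue)
instead. Classified candidates are gated by gene validity (strong, or
moderate with panel approval) and phenotype fit (term-overlap Jaccard, or
sudden-death panel membership), and reported as:

| category | meaning | case status |
|----------|---------|-------------|
| DV   | P/LP in a known phenotype-matched gene | positive |
| PDV  | P/LP with partial fit; VUS-PP with full fit; single-het P/LP in a recessive gene | plausible but negative |
| VUDS | deleterious-looking variant in a candidate gene with supporting data | negative |
| NEG  | everything else | negative |

Diagnostic yield is `100 · positive cases / cases` (one decimal,
half-away-from-zero); the re-analysis gain is reported absolutely and
relative to the initial yield. See `docs/methods.md` for every rule,
threshold, and design decision.

## Worked example

Simulate a 50-family rare-disease cohort with four injected
initial-analysis defects, analyze the degraded ("initial") and clean
("re-analysis") datasets, and diff:

```
$ reanalyzer simulate --out sim --seed 42 \
    --defects affection_flip,splice_misannotation,missense_to_noncoding,gene_link_removed
wrote cohort of 50 families to sim

$ reanalyzer run --vcf-dir sim/clean/vcf --ped sim/clean/cohort.ped \
    --pop-af sim/clean/pop_af.tsv --scores sim/clean/scores.tsv \
    --assertions sim/clean/assertions.tsv --genes sim/clean/genes.tsv \
    --phenotypes sim/clean/phenotypes.json --out reports_clean
analyzed 50 cases: 10 positive

$ reanalyzer run --vcf-dir sim/degraded/vcf ... --out reports_initial
analyzed 50 cases: 6 positive

$ reanalyzer diff --initial reports_initial --reanalysis reports_clean --out deltas.json
4 cases with new or upgraded findings

$ reanalyzer summarize --initial reports_initial --reanalysis reports_clean --out summary
         arm  n_cases  n_dv_initial  n_dv_final  yield_initial_pct  yield_final_pct  new_dv  relative_increase_pct
rare_disease       50             6          10               12.0             20.0       4                     67
```

Reading this: the generator planted 10 diagnostic cases; each injected
defect hid exactly one of them from the initial run (10 → 6 positives), and
re-analysis of the corrected data recovered all four, raising the yield
from 12.0% to 20.0%. A recovered finding in a case report looks like:

```json
{
  "category": "DV",
  "classification": "P",
  "criteria": ["PM2", "PS3", "PVS1"],
  "inheritance": ["de_novo"],
  "rationale": "P/LP variant in a known phenotype-matched gene",
  "variant": {"chrom": "chr1", "pos": 1060000, "ref": "G", "alt": "A",
              "gene": "SG001", "consequence": "nonsense"}
}
```

— a de novo nonsense variant in a loss-of-function disease gene, absent
from population databases (PM2) with functional evidence (PS3), combining
to Pathogenic and reported as the diagnostic variant. The same flow is
available as library calls (`generate_cohort`, `inject_defects`,
`analyze_cohort`, `diff_reports`, `summarize`) — see
`reanalyzer.synthetic.reanalysis_experiment` for the one-call version.

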