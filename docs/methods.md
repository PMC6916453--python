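# Methods

## Scope and model of the procedure

`reanalyzer` implements a clinical exome **triage** procedure, not a variant
caller: it consumes a multi-sample VCF with functional annotations already
attached, a 6-column PED pedigree, and external-knowledge tables (population
allele frequencies, in-silico predictor output, curated variant assertions,
gene-disease evidence), and produces per-proband case reports and
cohort-level diagnostic-yield statistics. The procedure has five stages:

1. **Filtration.** Three rules applied in a fixed order: functional
   consequence class (keep missense, nonsense, frameshift, canonical splice
   acceptor/donor), population frequency (maximum AF over ExAC / 1000G /
   ESP / UK10K / gnomAD / internal strictly below `maf_threshold`, default
   1% — a variant absent from every source counts as AF 0), and family
   segregation. The order affects only the tally of survivors per step, not
   the final candidate set.
2. **Inheritance calling.** Genotype-only trio logic. De novo requires both
   parental genotypes *observed* as homozygous reference — a missing call
   (`./.`) yields `unresolved`, never a de novo, which is why missing
   genotypes are represented as an explicit null dosage rather than 0.
   Compound-heterozygote phase is inferred from parental genotypes alone: a
   variant is paternal (maternal) when only the father (mother) carries it,
   and two proband hets in one gene are in trans only when their origins are
   opposite and unambiguous. Both variants carried by one parent are in cis.
   There is no read-backed phasing. Homozygous proband genotypes are never
   paired with themselves.
3. **Classification.** An ACMG/AMP evidence engine (below).
4. **Gene gating and categorization.** A candidate reaches the report only
   if its gene has strong disease validity (or moderate with explicit
   review-panel approval) and fits the case phenotype; findings are then
   binned DV / PDV / VUDS / NEG.
5. **Aggregation.** Initial-vs-reanalysis report diffs with reason codes,
   and per-arm diagnostic yields.

## Segregation semantics

Only dominant-model contradictions remove a variant: a candidate whose
inheritance call is not protected (de novo, homozygous recessive,
compound het, mitochondrial) is dropped when an *explicitly unaffected*
relative carries it. Relatives with unknown affection never contradict —
an unknown-affection carrier parent is exactly the situation in which a
truly dominant variant would be lost if unknown were treated as unaffected.
With `allow_mosaic_parent` the variant is instead retained and flagged
`possible_parental_mosaicism`, covering the confirmed-mosaic-parent
scenario. Mitochondrial variants are protected despite unaffected carrier
relatives because heteroplasmy makes carrier status weakly informative;
heteroplasmy fractions themselves are ignored (any non-zero dosage counts
as carried). X-linked variants are handled under the autosomal rules — a
documented limitation, acceptable because hemizygous male logic never
changes the outcome for the genotype patterns the generator produces.

## The classification engine

Codes are assigned from annotations, each rule checking evidence
availability (absent evidence means the code is simply not applied):

| code | trigger |
|------|---------|
| PVS1 | LoF consequence in a gene where LoF is the disease mechanism |
| PS1  | same amino-acid change previously established pathogenic |
| PS2  | de novo, only when parental relationships are confirmed (`relationships_confirmed`) |
| PS3  | well-established functional evidence on the curated assertion |
| PM2  | absent from every population source (AF 0); for recessive genes AF < `pm2_af_max` (1e-4) suffices. Applied at moderate strength. |
| PM3  | in trans with a P/LP partner (two-pass: partners classified without PM3 first) |
| PP1  | co-segregation with an affected carrier parent |
| PP2  | missense in a missense-constrained gene |
| PP3 / BP4 | predictor consensus: fraction of available missense predictors calling damaging ≥ `pp_damaging_frac` (0.75) / ≤ `bp4_damaging_frac` (0.25), requiring ≥ `min_tools` (4) calls; a splice score ≥ `splice_high` (0.8) also triggers PP3 |
| BA1 / BS1 | max AF > 5% / > `bs1_af` (1%) |
| BP7  | synonymous with all splice scores < `splice_low` (0.2) |

Codes without an automated trigger (PM1, PM4–PM6, PS4, PP4, BS2–BS4,
BP1–BP3, BP5) are accepted as user-asserted pass-through via the assertion
table, optionally strength-modified (`"PP4-moderate"`). CADD arrives as a
scaled score and is mapped to a damaging call at `cadd_cut` (20) so all
eight missense predictors share one call vocabulary. Curated assertions
below `min_review_level` (1) are ignored entirely.

**Reputable-source exclusion.** PP5 and BP6 are not members of the code
enum; the parser rejects them, and report serialization asserts their
absence. The evidence such assertions summarize enters as structured
booleans — functional data as PS3, same-residue pathogenic change as PS1 —
so the substance survives while the circular "someone asserted it" code
cannot.

**Combination** follows the standard rule table with codes counted at their
*applied* strength (a PS code demoted to moderate counts as moderate).
Combinations the table does not cover fall to VUS, as does simultaneous
satisfaction of a pathogenic and a benign tier (conflict). An uncertain
result is then subclassified: VUS-PP on strong computational consensus
(missense consensus, or a high splice score for splice-region/synonymous
variants), VUS-PB for non-coding variants with no predicted splice impact,
VUS-U otherwise. The 7-level scale is strictly ordered
B < LB < VUS-PB < VUS-U < VUS-PP < LP < P.

## Reporting categories

* **DV** — P/LP in a reportable, phenotype-matched gene (case positive).
  Exception: a single heterozygous P/LP in a *strictly* recessive gene with
  no in-trans partner is demoted to PDV.
* **PDV** — P/LP with partial phenotype fit, or VUS-PP with full fit, or the
  single-het recessive case (reported "plausible but negative").
* **VUDS** — deleterious-looking variant (VUS-PP, or P/LP in a gene of
  limited/no validity) in a candidate gene *with* supporting data (animal
  model / CNV / expression); reported negative.
* **NEG** — everything else. Case status is the best finding's category;
  VUDS-only cases are negative.

Phenotype fit in the rare-disease arm is the Jaccard overlap of normalized
(lower-cased, whitespace-collapsed) phenotype terms: overlap ≥
`pheno_match_min` (0.25) is a match, any shared term below that is partial.
This is a deliberately simple, auditable proxy for a phenotype-ranking
filter; it ignores term ontology structure (no HPO graph traversal), which
is adequate for the controlled vocabularies used here but coarse for
free-text clinical terms. In the sudden-death arm fit is membership in the
curated sudden-death panel, full stop.

Report diffs classify re-analysis DV/PDV findings as *new* (absent or
unreported initially), *upgraded* (PDV→DV), or *confirmed*; a prior DV that
disappears raises an error rather than being silently dropped. Reasons
attach from a defect provenance log when one exists (synthetic runs);
real-world diffs default to `pipeline_improvement`.

## Yield arithmetic

Diagnostic yield is the percentage of cases whose report is positive,
rounded half-away-from-zero to one decimal; the relative increase is
computed against the initial yield and rounded to the nearest integer
(0 when the initial count is 0). The inheritance breakdown groups both
recessive models as "recessive" and uses each diagnostic case's primary
model (priority: de novo > hom > comphet > dominant > mitochondrial).

## The synthetic cohort generator

The generator emulates a family-structured exome cohort *after* upstream
annotation: genotypes are produced directly — no reads, no coverage or
error model — because that is the representation the triage consumes.
Defaults describe one study arm: 50 families (80% trios, 10% quads with an
unaffected sibling, 10% singletons), 20% of cases carrying a planted
diagnostic finding whose inheritance-model mix (50% de novo, 37.5%
recessive split between homozygous and compound het, 6.25% dominant from an
affected parent, 6.25% mitochondrial) mirrors the diagnostic-finding
breakdown the procedure is meant to reproduce. Each case also receives 200
background variants drawn from a cohort-wide panel of 1000 sites with
log-uniform allele frequencies on [1e-5, 0.5]; per-tool damaging-call
probabilities are 0.9 for planted variants and 0.15 for background.

A fixed 60-gene universe covers every validity level, inheritance mode and
panel-membership combination the reporting logic branches on. Planted
findings live in strong-validity genes with matching phenotype terms and
receive annotations sufficient for their intended tier under the default
configuration (AF absent everywhere, functional or same-residue curated
evidence, LoF or unanimous-damaging computational support). Two deliberate
simplifications keep truth-table recovery exact and are the main ways the
synthetic data differ from real cohorts: background sites are confined to
non-truncating consequence classes, and they avoid the 36 planted-host
genes entirely, so a planted heterozygote can never be phase-linked to an
incidental background carrier and no background variant can reach P/LP.
Passing recovery tests therefore demonstrates the *logic* is right, not
that real-exome noise (incidental LoF carriers, shared haplotypes, missing
parental genotypes) is handled gracefully — those situations are covered
only by targeted unit tests. Background genotypes are Mendelian-consistent
by construction (child alleles drawn from parents) and checked by an
independent validator; sites are forced to have at least one carrier parent
per family that draws them, a mild conditioning that emulates "variants
observed in this family's VCF".

Defect injection degrades a deep copy of the cohort, never the original:
splice or missense consequences rewritten to non-coding (the variant then
fails the consequence filter), an affected carrier parent relabeled
unaffected (the dominant variant then looks like a segregation
contradiction and is removed), or a gene's validity downgraded to none (the
finding then fails the reporting gate). Targets are restricted to
single-variant cases in genes hosting no other case's finding, so each
defect removes exactly one diagnosis; the re-analysis experiment runs the
degraded dataset as "initial" and the clean one as "re-analysis" and diffs.

All randomness flows through one `numpy` generator seeded from the cohort
spec; a fixed seed yields byte-identical output files.

## Numerical and design choices

* Coordinates are 1-based VCF convention with `chr`-prefixed names; no
  liftover. Multi-allelic records are decomposed per alt allele (other alts
  recoded as dosage 0) and trimmed minimal; transcripts are taken from the
  annotation input as-is.
* Yield rounding is half-away-from-zero (what printed tables do), not
  banker's rounding.
* Tie-breaks are lexicographic everywhere (variant sort keys, comphet
  partner selection, report ordering), making every pipeline output
  invariant under input permutation.
* Problem sizes in the test suite (30–50-family cohorts in most tests,
  five 200-family cohorts for the recovery property) were chosen as the
  smallest sizes at which every planted model and defect type occurs;
  the whole suite runs in well under a minute.
* Configuration is strict: unknown keys are rejected, and every threshold
  above is exposed in one YAML block with the defaults stated here.

## Known limitations

* No gene-specific rule specifications, no points-based (Tavtigian-style)
  scoring, no literature mining: the engine is the criteria-table subset
  with documented triggers.
* The mapping from curated-assertion review features to evidence strength
  is reduced to a single ordinal `review_level` gate.
* Single proband per family; multi-proband segregation ("including
  multiple probands") reduces to the unaffected-carrier contradiction rule.
* No CNV/SV, repeat-expansion, or non-coding regulatory analysis; the
  consequence vocabulary is the nine classes listed in the data model.
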