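# Methods

## Scope and model

`mendelsieve` implements panel-based interpretation of annotated exome
variants for Mendelian retinal dystrophy cohorts. The unit of analysis is
the (proband, variant) genotype call; the pipeline is deterministic
rule-based triage, not statistical inference. Its model assumptions are the
classical ones of diagnostic exome interpretation in a fully penetrant,
predominantly autosomal-recessive disease:

* causal genotypes are biallelic in a recessive panel gene (homozygous or
  compound heterozygous) or monoallelic in a dominant panel gene;
* pathogenic alleles are rare (population MAF ≤ 0.01 in every source) and
  protein-altering or splice-disrupting;
* two heterozygous candidates in one recessive gene are presumed *trans*
  until pedigree evidence contradicts — phase is unknowable from a single
  proband, and cohorts routinely include families without genotypable
  relatives;
* penetrance is complete (appropriate for juvenile-onset macular
  dystrophy): an unaffected biallelic carrier falsifies a candidate.

## The exclusion cascade

Four rules, with an audit trace assigning every input pair exactly one
status:

1. **Consequence.** Synonymous, intronic, UTR and other non-coding variants
   are removed unless a splice site is affected. Splice effect =
   external-predictor flag (`splice_flag`, consumed as annotation, never
   recomputed) OR a canonical offset parsed from the HGVS c. name
   (|intron offset| ∈ {1, 2}; donor +1/+2, acceptor −1/−2). An unparseable
   cDNA name never rescues, with a warning.
2. **Frequency.** MAF per source is AC/AN where counts are given, else the
   reported MAF; the filter uses the maximum over sources and removes
   strictly above 0.01. The boundary is kept (the exclusion criterion is a
   strict inequality). A missing source is *no observation*, never zero;
   a variant with no observations anywhere is kept. An allele number of 0
   is an evidence error, not a zero frequency.
3. **Recessive zygosity.** In mode-AR genes, a proband-gene group holding
   exactly one distinct heterozygote and no homozygote is removed. AD and
   AR_AD genes are exempt, as are genes absent from the panel (flagged
   off-panel instead).
4. **Benign consensus.** Missense and in-frame indels are removed only when
   all three predictors are present and benign-class (PolyPhen B, SIFT T,
   PROVEAN N). NA never counts toward the consensus — nothing is excluded
   on missing evidence. Truncating and splice-site variants bypass the
   predictors entirely (they are damaging by mechanism and usually NA).

**Ordering.** Steps 1/2/4 are per-variant predicates and commute; step 3 is
evaluated on the group *surviving* them, because a heterozygote accompanied
only by later-excluded variants is still single in the final accounting.
Removal labels keep the analyst-facing step numbers, so a trace reads like
the manual protocol. The alternative ordering (zygosity before benign
consensus) differs exactly on gene groups mixing a pathogenic het with
unanimously benign hets; on the packaged cohort's published calls the two
orderings agree, which a test asserts. The chosen order is also what makes
the `partial_one_pathogenic` near-miss state observable.

## Diagnosis calling

Per proband, per surviving panel-gene group: homozygote ⇒
`solved_homozygous`; ≥2 distinct heterozygotes in an AR or AR_AD gene ⇒
`solved_compound_het`; any candidate in an AD or AR_AD gene ⇒
`solved_dominant` (flagged). The dominant-solved state is an explicit
status of its own rather than an overload of the recessive states, since
its evidence requirement (one allele) differs. When several genes qualify,
all candidates are reported, the status comes from the best-ranked gene —
STGD phenotype-group genes first, then alphabetical — and a `multi-gene`
flag is raised.

Near-misses are graded from the filter trace: a lone heterozygote removed
at step 3 yields `partial_one_pathogenic` when its gene group also lost
variants to the benign consensus (≥2 rare hets, only one predicted
pathogenic), else `partial_single_het`. Probands present in the genotype
table with nothing surviving are classified (partial or `unsolved`), so
cohort denominators equal the genotype table's proband count.

## Segregation rules

For a biallelic hypothesis (two variant ids, or one for homozygotes):
(a) each genotyped unaffected parent carries exactly one candidate allele —
both ⇒ cis ⇒ inconsistent; neither ⇒ inconsistent unless `allow_denovo`
downgrades it to a warning; (b) genotyped affected relatives carry the full
candidate genotype; (c) genotyped unaffected relatives do not. Verdict is
`uninformative` iff no genotyped relative constrains the hypothesis
(relatives of unknown affection status do not constrain). An individual
present in the genotype mapping is genotyped; candidate variants absent
from their entry are reference — consistent with the cohort-table
convention that absent pairs are reference calls. Trans phase is marked
established when the two parents each carry a different single allele.
These are the standard co-segregation criteria; no linkage statistics are
computed.

## Reporting conventions

The solved percentage is rounded half-up to one decimal (19/33 →
57.5757…% → 57.6%), implemented with decimal arithmetic rather than
binary-float `round`. Distinct variants are counted by variant id over
solved probands only; an allele shared by several solved probands counts
once. Novel/known is an input flag carried from the annotation, never
computed. The per-variant report writes one row per (solved proband,
candidate variant) — near-miss candidates of partial probands belong in a
separate supplement — and renders count-based frequencies as `AC/AN`
verbatim; control-cohort carrier screens (e.g. `0/192`, `2/456`) are
reporting evidence passed through untouched, not a filter.

## The packaged cohort fixture

`make_table1_fixture()` rebuilds a published 33-proband Stargardt cohort:
28 distinct ABCA4 variants (13 novel / 15 known) observed as 37 genotype
calls — 36 heterozygous plus one homozygous canonical splice variant — in
19 probands, with per-source frequency evidence (EVS MAFs, ExAC allele
counts) and predictor calls stored per variant. Synthetic elements are
documented in the module: placeholder genomic coordinates (the source
prints HGVS names only), constructed decoys, the ids of the 14 unexplained
probands, one damaging call retained where the source prints conflicting
PolyPhen calls for the same allele in different probands, and NA for two
predictor tokens outside the controlled vocabulary. The 14 unexplained
probands mirror the published near-miss split — four carry a lone
pathogenic het, four a lone pathogenic het plus a unanimously benign het,
six only consequence/frequency decoys — so the fixture exercises every
removal step and both partial states while leaving the solved tally at 19.

## The synthetic cohort generator

`simulate_cohort` emulates the post-annotation state of a panel-restricted
exome cohort; it does not simulate reads, alignment or variant calling.
Defaults are the reference cohort's conditions: 33 probands, solved
fraction 19/33, one in nineteen solved probands homozygous. Each solved
proband receives a planted genotype in a random AR panel gene (damaging
missense + truncating pair for compound hets) and a trio pedigree with
unaffected carrier parents in trans. Decoy load per proband — 10 common
(MAF ~ U(0.011, 0.5)), 8 non-coding/synonymous, 3 unanimously benign
missense, 1 lone pathogenic het in a distinct AR gene — reproduces a
pre-filter funnel of roughly 700–800 panel variants per 33-proband cohort.
Rare variants draw MAF from U(0, 0.009) or carry no population observation
(half each); the 0.01 boundary is deliberately unsampled, because boundary
semantics are pinned by a fixed unit test, not by sampling luck. Lone-het
decoys are placed one per gene and never in the causal gene, so decoys can
never assemble into a false compound heterozygote: planted-status recovery
is exact by construction, and the end-to-end tests assert precision and
recall of 1.0. Optional forced-cis control families put both candidate
alleles on one parent as a negative control for the segregation checker.
All randomness flows from one mandatory integer seed through a single
`numpy.random.Generator`; outputs are byte-identical across runs.

What passing on synthetic cohorts does *not* show: robustness to
annotation noise (mis-annotated consequences, discordant frequency
sources), genotyping error, pseudogene artifacts, non-canonical splice
effects, or causal genes outside the panel. The generator's decoys fail
exactly one rule each by design; real exomes contain variants failing
several at once (those are covered by the randomized oracle-equivalence
tests, whose cohorts are adversarial rather than realistic).

## Panels

Two pinned YAML panels ship with the package: the five STGD genes (ABCA4
and PROM1 recessive; ELOVL4, PRPH2, BEST1 dominant) and a 214-gene virtual
panel adding 209 further retinal-dystrophy genes with curated modes.
Panels are config, not code, because curated disease-gene lists drift;
users may override any gene's mode. X-linked genes are carried with mode
AR — hemizygous logic is out of scope in this version, as are
mitochondrial inheritance, de novo dominant analysis, ACMG/AMP scoring and
quantitative pathogenicity scores (CADD/REVEL).

## Problem sizes used in the test suite

The packaged fixture is the published scale (33 probands, 32 variants, 61
genotype calls). Oracle-equivalence runs 100 random cohorts of up to 200
variants against an independently written brute-force filter;
recovery/segregation checks run 20 seeded cohorts at the default 33-proband
shape plus 2 cis-control families each. The whole suite completes in a few
seconds on one CPU.
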