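# Methods

## Somatic zygosity inference

The zygosity model treats the tumor specimen as a two-population mixture:
a fraction φ of cells are tumor with local allele-specific copy number
(TCN, LCN), and 1 − φ are diploid normal cells heterozygous for the
germline variant.  A variant on *m* of the TCN tumor copies then has
expected VAF

E[VAF] = (φ·m + (1 − φ)) / (φ·TCN + 2·(1 − φ)),

which reduces to 1/2 at φ = 0 and to m/TCN at φ = 1, and is monotone
non-decreasing in *m*.  The denominator "MCN" sometimes seen in shorthand
statements of this formula is read as the total copy number TCN, consistent
with its own gloss (LCN and TCN being the lesser and total copy number),
and the numerator's copy count is generalized to *m* so that every
hypothesis shares one formula.

**Acceptance intervals.**  A state is accepted when the observed VAF lies in
the central `level` (default 95%) region of Binomial(depth, E[VAF]), using
equal-tail exact binomial quantiles (the smallest alt counts at or above the
α/2 and 1 − α/2 CDF levels).  Exact quantiles were chosen over a normal
approximation because loss-of-wild-type states push E[VAF] close to 1,
where the normal approximation fails; the interval correctly collapses to a
point at p ∈ {0, 1}.

**Decision cascade.**  The prose rules of two-hit calling leave the
acceptance regions overlapping, so they are resolved by a fixed cascade
(first match wins): (0) missing segment, missing purity or a homozygous
germline call → indeterminate; (2) inside the balanced interval, or below
its lower bound when TCN > 2 (a gain diluting a single-copy variant) →
heterozygous; (3) LCN = 0 and inside-or-above the m = TCN interval →
loss_of_WT; (4) inside-or-below the m = 0 interval → loss_of_mutant;
(5) inside-or-above the m = TCN − LCN interval, provided the major allele
strictly exceeds the minor → ASI_two_hit; (7) otherwise indeterminate
("discordant VAF").  Where a step admits several sub-hypotheses (odd TCN
balanced states), the reported mutant copy number maximizes the binomial
likelihood of the observed alt count.  "Greater than the 95% CI" in the
imbalance rule is resolved as *above the upper bound* (the mutant allele
over-represented), and ASI requires the mutant on the major allele; the
mirror-image imbalance is what the loss-of-mutant rule captures.

Balanced heterozygosity is undefined below TCN = 2: a single-copy locus is
either mutant-retained (loss of WT) or mutant-lost.  For odd TCN ≥ 3 both
nearest-balanced states ⌊TCN/2⌋ and ⌈TCN/2⌉ are tried and either may accept.

A germline variant coupled with a functional somatic mutation (missense,
nonsense, frameshift or splice) in the same gene and patient is a compound
biallelic event.  When copy-number evidence already calls a two-hit state
(ASI or loss of WT) that state is kept and the somatic hit recorded as
corroborating evidence; otherwise the call becomes `biallelic_compound`.

**What recovery tests show.**  With per-state copy-number templates
(het 2/1, ASI 4/1, CN-LOH 2/0, deletion 1/0), planted states are recovered
in ≈98% of simulated variants at depth 500 and purity 0.4–0.9.  Recovery
rises with depth and purity but saturates near, not at, 100%: a 95%
acceptance band leaves ≈5% of genuinely heterozygous draws outside the
balanced interval at any depth, and the cascade deliberately reports those
as indeterminate rather than guessing.  This is a property of the interval
rule, not a small-sample artifact.

## HRD scoring

Three components are counted on canonically merged segments (adjacent
identical (TCN, LCN) runs merged, so counts are invariant under splitting a
segment at an interior point):

- **NtAI** — allelic imbalance (TCN ≠ 2·LCN, which covers LOH and
  unbalanced gains) touching a telomere, not crossing the centromere, and
  longer than 11 Mb;
- **LOH** — LCN = 0 with TCN ≥ 1 (homozygous deletions excluded), longer
  than 15 Mb and shorter than the whole chromosome (a config flag can relax
  the whole-chromosome exclusion);
- **LST** — per chromosome arm, after discarding segments under 3 Mb and
  re-merging across the gaps, breakpoints whose two flanks are each ≥ 10 Mb
  and differ in copy state.  Breakpoints falling inside the centromere
  belong to no arm and are not counted.

The thresholds (11/15/10/3 Mb) follow the literature-standard component
definitions and are exposed as keyword arguments.  The ploidy correction is
LSTm = LST − 15.5·ψ, so a uniformly diploid genome scores
NtAI + LOH + LSTm = −31.  The synthetic segment builder constructs each
planted event on a dedicated chromosome so that it triggers exactly one
component (telomeric-AI events fill a p-arm; LOH runs are buffered by
sub-10 Mb spacers; LST transitions use balanced states on both flanks),
giving exact construction-by-design recovery.

## Germline triage

Quality thresholds are inclusive ("at least"): depth ≥ 20, alternate-allele
depth ≥ 10, VAF ≥ 0.30, applied uniformly to SNVs and indels; a missing
metric fails quality with reason "missing metric", and the reason always
names the first failed rule.  Pathogenicity needs both annotators in
{P, LP}; both in {VUS, LB, B} excludes; discordant pairs are queued for
manual review with the ClinVar label attached as advisory, because
resolving discordance is a curation judgement no rule reproduces.  An
optional third annotation breaks ties by majority.  Penetrance tiers follow
relative risk: RR > 5 high, 2 ≤ RR ≤ 5 moderate, RR < 2 low, uncharacterized
genes uncertain, with an autosomal-recessive override.  An optional
gene-role table flags inactivating (nonsense/frameshift/splice) variants in
oncogenes as role-inconsistent and routes them to review.  Gene symbols are
matched case-sensitively after whitespace stripping; alias resolution is a
curation task out of scope.

## Interaction and enrichment statistics

Both analyses use the two-sided Fisher exact test on raw counts; the
Haldane–Anscombe 0.5 correction applies only to the displayed odds ratio
and its normal-approximation CI when a cell is empty, never to the test
itself.  P values are adjusted by Benjamini–Hochberg within each tested
family (all germline×somatic pairs; all genes in a case–control screen),
and interaction direction (co-occurrence vs mutual exclusivity) is called
at FDR < 0.05 by the side of the odds ratio.  Genes significant in the
case–control screen form the cohort's empirical predisposition-gene set.
An optional covariate-adjusted logistic comparison (sharing the risk-model
fitting engine) supports frequency contrasts adjusted for age/histology.

## Risk calculators and validation

Covariate coding (not stated alongside the printed coefficients, chosen
here and shipped as an overridable manifest): age in years; grade 1–3 and
T/N/M as ordinal integers (single coefficient each); ER/PR/HER2 and the
history flags 0/1; Ki67 in percent 0–100, consistent with its small
per-unit coefficient (~0.02).  The linear predictor is affine in the
covariates; probabilities use the logistic link.

Refitting uses maximum-likelihood logistic regression (Newton), falling
back to a small-ridge penalized GLM (α = 10⁻⁴ L2) when the data are
separable or the MLE fails to converge; the results object flags the
fallback.  The 70/30 train/validation split is a seeded permutation with
⌊0.7·n⌋ training rows.  Missing covariates are completed by
chained-equation imputation: medians/modes initialize, then each missing
column is re-imputed by least squares on the others for a fixed number of
cycles, with discrete columns snapped to their observed domain; the default
is a single deterministic completion, and `m > 1` adds residual-scale noise
per completion with Rubin's rules available for pooling.  Validation
reports the tie-corrected rank-statistic AUC with its Hanley–McNeil CI, a
decile-of-risk Hosmer–Lemeshow chi-square with df = groups − 2 (equal-count
deciles, probabilities clipped away from 0/1), and the operating threshold
minimizing |sensitivity − specificity| over midpoints of adjacent unique
scores, ties toward higher sensitivity.  The HL test's df = g − 2 reference
is the classical fitted-model null, so its calibration (≈5% rejection) is
assessed on models fitted to data simulated from themselves.

AUC stability across seeds is assessed at the cohort scale (n = 4000): the
end-to-end pipeline (simulate → split → impute → fit) runs per seed and the
fitted model is scored on an independent same-size cohort.  A 30% split of
a 6%-prevalence cohort holds only ~75 events, whose binomial noise alone
(se ≈ 0.025) exceeds any meaningful stability bound, so the split-level AUC
is reported per run but stability is measured where the sample supports it.

## Synthetic cohort generator

The generator emulates the statistical structure of a prospective
tumor–blood panel cohort: per-gene germline carrier frequencies at the
observed spectrum (BRCA2 2.5%, BRCA1 2.2%, PALB2 0.9%, MUTYH 0.6%, CHEK2
0.4%, ATM 0.3%, TP53 0.2%); clinical covariates with marginals typical of
an Asian surgical cohort (age ~ N(49, 11), Ki67 ~ 100·Beta(1.8, 3.5),
ER 65%, HER2 25%, subtype derived from receptor status); carrier status for
high-penetrance genes drawn from the shipped carrier-risk logistic model on
those covariates (≈6% prevalence, enabling coefficient-recovery tests),
with the carrier's gene allocated proportionally to the configured
frequencies; somatic functional-mutation flags Bernoulli at their marginals
except where a pairwise germline–somatic log-OR is planted, in which case
the conditional probabilities are solved in closed form from the marginals
and the odds ratio (any finite log-OR is attainable for non-degenerate
marginals).  Per-carrier tumors draw purity ~ U(0.4, 0.9), panel depth
~ Poisson(500), a zygosity state from the configured per-gene two-hit
fractions (default BCDG-like: BRCA1 0.76, BRCA2 0.77, PALB2 0.59, CHEK2
0.35, TP53 0.89, others 0.35; two-hit mass split 60/25/15 across
ASI/loss-of-WT/compound), segment templates per state, and binomial alt
reads at the expected VAF.  Planted states define same-gene somatic status,
so the generator never emits a functional somatic hit contradicting a
non-compound planted state.  Decoy germline calls (benign/VUS, low-quality,
discordant-annotation) exercise the triage cascade.  A single global seed
fans out through `SeedSequence.spawn`, so adding a stage never perturbs
earlier draws, and every latent value is recorded in truth tables.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: subclonal copy-number states and purity error
(purity and (TCN, LCN) are taken as exact), sequencing artifacts and
mapping bias in VAFs, linkage or household structure beyond pairwise
odds ratios, realistic mutation positions within genes, and informative
(non-MAR) missingness in covariates.

## Numerical and interface choices

Coordinates are 1-based inclusive throughout (SEG convention).  Copy-number
lookups require the variant position to fall in exactly one segment;
multiple overlaps raise.  TCN = 0 with φ = 1 means no tumor DNA at the
locus and is indeterminate.  Writers emit tab-separated text with fixed
column order and `%.6g` floats, so identical configurations reproduce
byte-identical run directories; the manifest embeds the package version,
seed and a configuration hash (excluding output paths).  Pipeline problem
sizes in the shipped examples (cohorts of 300–4000 patients, 100-replicate
recovery studies, 1000-cohort null screens) were chosen so the whole suite
runs comfortably on a single CPU while keeping Monte-Carlo error well below
the asserted margins.

## Known limitations

- The cascade classifies against a fixed hypothesis set; subclonal events
  produce intermediate VAFs that are reported as indeterminate rather than
  modelled.
- Control-population carrier counts are consumed as given; no
  quality-filter harmonization or ancestry matching is attempted.
- The review queue is an output state, not a resolution mechanism; counts
  passing through it depend on upstream annotator quality.
- The imputation engine is a pragmatic chained-equations implementation
  (linear models per column), not a full conditional-specification MICE
  with predictive mean matching.
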