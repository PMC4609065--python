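# Methods

## Study design the package models

A cohort of fluoropyrimidine-treated gastric cancer patients (119 evaluable,
58 of them on S-1 monotherapy) genotyped on a genome-wide SNP panel, with
tumor response as a 4-level ordered RECIST outcome (CR < PR < NC < PD) and
a derived binary grouping (responders CR+PR vs non-responders NC+PD).  The
S-1 subset is the discovery ("first") dataset; the full cohort is the
validation ("second") dataset.  Because the discovery set is nested inside
the validation set, the two stages are dependent, which shapes the
permutation design below.

## Genetic-model contingency analysis

For a SNP with per-subject minor-allele dose d ∈ {0,1,2}, three collapsed
2×2 tables are tested against the binary response: allele (each subject
contributes two alleles; columns minor/major), dominant (d ≥ 1 vs d = 0)
and recessive (d = 2 vs d ≤ 1), plus the uncollapsed 2×3 genotype table.

The two-sided Fisher exact p is the sum of conditional hypergeometric point
probabilities not exceeding the observed table's, with a relative tie
tolerance of 1e-7 — the definition used by R's `fisher.test`, which
matters because the solver must match p-values as that software printed
them.  Odds ratios are offered in two conventions: the sample cross-product
and the conditional MLE of the noncentral hypergeometric model (solved by
bracketed root-finding of the conditional mean equation; boundary tables
give 0 or ∞).  Exhaustive enumeration against the study's printed values
shows the printed ORs are conditional MLEs, so that is the default where a
single convention is needed.  Confidence intervals: Woolf log-limits
(Haldane 0.5 correction for the finite bound of zero-cell tables) or the
conditional-exact tail-inversion interval.

The r×c exact test enumerates all tables with the observed margins
depth-first (totals ≤ 400 by default) and falls back, on request, to a
seeded margin-preserving Monte-Carlo estimate with the add-one estimator.
The Hardy-Weinberg exact test conditions on allele counts and sums the
conditional probabilities of heterozygote counts no more probable than the
observed one.  Benjamini-Hochberg q-values delegate to statsmodels.

## Knowledge-based prefiltering

The screen is restricted to literature-supported SNPs: keep SNPs with at
least one PubMed link, optionally removing those already flagged as
cancer-related (the study's design, which had analyzed cancer-linked SNPs
separately).  Basic QC defaults — call rate ≥ 0.95, MAF ≥ 0.05, HWE exact
p ≥ 1e-6 on the full cohort — are conventional GWAS per-marker values; the
original study's exact thresholds are not published, so these are explicit
configuration, and the filter count they produce is not asserted anywhere.

## Two-stage screening with min-T permutation control

Each SNP gets a stage p-value in the discovery subset and in the full
cohort (allele model by default, configurable).  The combined statistic is
T = max(p₁, p₂): a SNP is only as strong as its weaker stage, the simplest
statistic consistent with "significant in both stages".  Family-wise
control: response labels are permuted once across the full cohort; the
discovery stage sees the induced restriction, preserving the nesting (the
realized discovery-stage margin varies across permutations, which the
implementation handles by grouping permutations by their induced responder
count).  With T*min the per-permutation minimum of T over the panel, the
adjusted p of SNP s is (1 + #{T*min ≤ T_s})/(B + 1), bounded below by
1/(B+1).  Candidates must pass both stage thresholds (default 0.05) and
the adjusted threshold 0.05; BH q-values over the stage-1 p-values of the
screened set are reported alongside.

For complete-call panels the permutation loop is a single pass of
vectorized hypergeometric lookups: at a fixed genetic model, every 2×2
table's margins are determined by the permuted responder count, so
two-sided p-values for all (SNP, permutation) pairs come from shared
per-margin lookup tables (log-gamma pmf, sorted cumulative sums).  Panels
with missing calls take a per-table path with pairwise-complete cases.

## Regression model comparison

The ten-model battery spans the empty model, each SNP (additive 0/1/2
coding), creatinine grade, chemotherapy history, and their combinations.
AIC comparison uses the 4-level proportional-odds (cumulative-logit) fit,
k = slopes + 3 thresholds; ROC analysis scores every model against the
binary grouping using the fitted responder probability (for ordinal fits,
P(outcome ≤ PR | x)).  Convergence: statsmodels Newton (binary) or BFGS
(ordinal); complete separation is flagged — scores perfectly split the
classes and the likelihood reaches its supremum — rather than raised, and
the stopped-iterate likelihood is reported.  Best cutoffs maximize
Youden's J with ties broken by higher specificity, then higher cutoff;
comparison keys are rounded at 1e-9 so exact ties are not split by
floating-point noise.

## Integrated minor-allele index

The index of a sample is its total minor-allele count over the index SNPs
(0–4 for two SNPs), missing if any constituent call is missing.  Per level:
response rate RR = 100·responders/total; across levels: exact r×c test;
dichotomized at index ≥ 2 (the levels observed to carry 0% RR in the
motivating study are 0 and 1): 2×2 Fisher test and ROC with the index as
score.  An equal-coefficient two-SNP regression score is a strictly
monotone transform of the index, so their ROC curves coincide exactly in
that limit — the sense in which the index "performs the same" as the
two-SNP model.

## Inverse table reconstruction

Printed (p, OR) pairs at 2–3 significant digits define half-open bands
(half-up rounding of the significand; a truncation mode is provided).  The
solver enumerates all 2×3 genotype-by-response tables with totals in a
given range whose statistics fall in every band, staged for speed: allele
2×2 tables first (vectorized p over the full margin×count grid per block),
then expansion of survivors into compatible genotype splits checked against
the remaining constraints.  Both row orientations and both OR conventions
are tried; solutions are deduplicated and reported with the protective
orientation (allele OR ≤ 1).  Totals may run below the cohort size to
absorb unreported per-SNP missingness.

Printed p-values have a characteristic failure mode: the mantissa survives
transcription, the power of ten does not.  When a constraint set admits no
table, an optional exponent-slack retry shifts one constraint's p by up to
a configurable number of decades (smallest shift first) and annotates any
rescued solution.  On the motivating study this matters once: the second
dataset's three printed p-values are mutually inconsistent at every total
in 100–119 under every two-sided convention tried, while the allele +
recessive pair pins a unique table whose dominant statistics match the
printed mantissa and OR at one decade above the printed exponent — a
decade misprint, which the rescue recovers.  The reconstructed second-
dataset table is, cell by cell, a superset of the reconstructed first-
dataset table (58 + 61 patients), a strong internal consistency check
since nothing in the search enforces nesting.

## Synthetic cohort generator

Genotypes: per SNP, MAF ~ U(0.05, 0.5) (configurable), genotypes drawn
from Hardy-Weinberg proportions, independent SNPs by default (the
motivating platform's SNPs are not tag SNPs; an optional haplotype-
frequency LD pair generator exists for sensitivity checks), Bernoulli
missingness (default 0: the study's per-SNP missingness is unreported and
its printed tables are consistent with complete calls).

Response: latent score = Σ β_j·(coded dose_j − mean) + γ_Cr·grade +
γ_Chem·history + logistic noise, cut at three thresholds into RECIST
classes (CR best).  Logistic noise makes the proportional-odds fit
correctly specified; centring the effects keeps the cutpoints in control
of the marginal RECIST mix.  Default cutpoints (−3.48, −0.94, 0.99) give
roughly 3/25/45/27% CR/PR/NC/PD — a realistic fluoropyrimidine response
mix — with ~28% responders at the null; strong protective effects raise
the realized rate to ~35%.  Covariates: creatinine grade multinomial
(mostly 0), chemotherapy history Bernoulli(0.3).  Regimens: first
n_first samples S-1, the rest split 27:33:1 like the study's cohort.

Effect-size calibration for recovery experiments: the observable quantity
is the allele-model table OR, and with two protective causal SNPs it
saturates near 0.15 as the latent effect grows (each SNP's latent variance
dilutes the other, and allele-level marginalization compresses strong
per-subject effects), so the recovery fixtures use latent per-allele
OR 0.01, realizing a median allele-model OR ≈ 0.15 with MAF 0.3.  Recovery
runs screen a 30-SNP panel — the study's screened set (1,767 of 109,365)
scaled by the same factor as the synthetic 2,000-SNP panel.

What passing on synthetic data does not show: the generator has no linkage
disequilibrium, no population structure, no genotyping error, and its
covariates are independent of genotype; real-data behaviour under those
features is untested here.

## Numerical choices and degenerate inputs

Fisher ties compared at 1e-7 relative tolerance; hypergeometric pmfs in
log-gamma space (exact-rational brute-force oracles back the tests);
degenerate margins give p = 1 by convention; the conditional-MLE root is
bracketed in log-OR ∈ [−80, 80]; monomorphic SNPs are flagged and carry
all-zero doses; frequency ties in minor-allele orientation go to the
lexicographically smaller nucleotide; empty SNP sets, constant responses
and single-level outcomes raise or warn explicitly rather than propagate.

## Known limitations

The exact r×c enumerator is exponential in table size and intended for the
small index tables; large tables need the Monte-Carlo path.  The
permutation fast path requires complete calls — panels with missingness
fall back to a slower loop.  The solver's staged search requires an
allele-model constraint.  Ordinal-fit scores assume the proportional-odds
constraint holds; no partial-proportional-odds relaxation is provided.
Annotation quality is taken as given: the knowledge filter consumes a
prepared table and does not mine dbSNP/PubMed.
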