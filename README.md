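# pgxscreen

Pharmacogenomic SNP screening for small oncology cohorts: knowledge-based
prefiltering, genetic-model exact tests, two-stage permutation screening, and
an integrated minor-allele predictive index — plus an inverse solver that
reconstructs published contingency tables from nothing but their printed
statistics.

The package is built around the design of a fluoropyrimidine response study
in gastric cancer: 119 patients genotyped genome-wide, of whom 58 received
S-1 monotherapy and form a nested discovery subset.  Tumor response is the
4-level ordered RECIST outcome (CR < PR < NC < PD), grouped into responders
(CR+PR) vs non-responders (NC+PD) for contingency analysis.  It is aimed at
biostatisticians who need the whole chain — filter, screen, model, index —
reproducible, seeded and testable on synthetic data.

## What it computes

* **Knowledge-based filter** (`pgxscreen.qc`): keep PubMed-linked SNPs,
  drop cancer-flagged ones, intersect with per-marker QC (call rate, MAF,
  exact Hardy-Weinberg test).
* **Genetic-model exact statistics** (`pgxscreen.stats`): allele
  (2 alleles/subject), dominant (carrier vs non-carrier) and recessive
  (hom-minor vs rest) 2×2 tables; two-sided Fisher exact p (sum of point
  probabilities ≤ observed); odds ratios as cross-products or conditional
  MLEs with Woolf or conditional-exact intervals; BH q-values.
* **Two-stage screen** (`pgxscreen.screen`): per SNP
  T = max(p_discovery, p_full); family-wise adjusted p by min-T permutation,
  permuting labels once across the full cohort so the nested discovery
  subset sees the induced restriction; add-one estimator
  (1 + #{T*min ≤ T_s})/(B + 1).
* **Model comparison** (`pgxscreen.models`): binary logistic and
  proportional-odds fits, AIC = 2k − 2ℓ, ROC/AUC, Youden-J best cutoff; a
  ten-model preset over two SNPs and two clinical covariates.
* **Integrated index** (`pgxscreen.index`): per-sample total minor-allele
  count over the index SNPs (0–4 for two SNPs), per-level response rates
  RR = 100·(CR+PR)/(all), exact r×c test, dichotomization at index ≥ 2.
* **Table solver** (`pgxscreen.solver`): enumerate every 2×3
  genotype-by-response table whose model statistics reproduce a set of
  printed (p, OR) pairs at their printed precision — figure-only tables can
  be recovered exactly from the text.

## Worked example

The numbered scripts under `analysis/` run the full chain on a synthetic
study-shaped cohort (119 patients, 58-sample S-1 subset, 2,000-SNP panel,
two injected protective SNPs).  `python analysis/03_two_stage_screen.py`
prints:

```
screened 80 SNPs (stage 1 n=58, stage 2 n=119, 1000 permutations)
candidates (both stages < 0.05, family-wise permutation p < 0.05): ['rs000002', 'rs000001']
  rs000001: p1=0.000506 p2=9.05e-11 perm p=0.00699 q1=0.0202
  rs000002: p1=2.54e-05 p2=1.28e-06 perm p=0.002 q1=0.00204
```

Both injected SNPs pass both stages and survive the family-wise permutation
adjustment over the 80-SNP screened panel.  `analysis/04_model_comparison.py`
then ranks the ten-model battery — the two-SNP model attains the lowest AIC
(158.2, against 306.8 for the empty model) — and
`analysis/05_integrated_index.py` tabulates the allele-count index:

```
 level  n_resp  n_nonresp  rr_pct
     0       0         30     0.0
     1      11         48    18.6
     2      22          0   100.0
     3       8          0   100.0
dichotomized (index >= 2) table [[30, 0], [11, 78]], Fisher p = 2.48e-19
```

Response rate rises monotonically with the index level, and dichotomizing
at index ≥ 2 yields a strongly significant 2×2 exact test — the qualitative
behaviour the index is designed to exhibit.

`analysis/06_reconstruct_published_tables.py` runs the inverse solver on the
study's printed statistics; see below.

A `pgxscreen` command line mirrors the library
(`simulate | filter | assoc | screen | model | index | solve | run`).

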