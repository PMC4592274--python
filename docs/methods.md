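# Methods

This note documents the models implemented by `psacorrect`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish about real data.

## Score algebra

The combined genetic effect (CGE) of a SNP panel is
`Π_s effect_size_s ^ e_s(dosage_s)`, where the exponent map `e_s` is the
SNP's genetic-model contrast: additive (`e = dosage`), shifted additive
(`e = dosage − 1`; used for KLK3 rs17632542, whose zero-dosage class does
not occur in screened cohorts — encountering dosage 0 there raises an error
naming the subject rather than silently remapping), dominant
(`e = 1[dosage ≥ 1]`) and recessive (`e = 1[dosage = 2]`). Effect sizes are
carried at full precision (1.105, 1.102, 1.083, 1.391); the 2-decimal
values seen in reports (1.11, 1.10, 1.08, 1.39) are display artefacts,
rounded decimal-half-up only at presentation.

The corrected score defaults to **subtraction**, `PSA − CGE`, exactly as
the method defines it, even though this subtracts a dimensionless product
from a concentration; a **division** variant (`PSA / CGE`), which is the
exact inverse of the multiplicative generative model, is provided opt-in
and labelled non-canonical. Whether the method's authors intended division
is not guessed; both are computed, the default follows the stated formula.

The aggressive-disease panel multiplies published odds ratios under the
contrast each OR was published for. Per-allele ORs (rs11672691, rs11704416,
rs4054823) are additive; grouped contrasts of the form "XX vs rest" are
recessive (rs10788165, rs10749408, rs11199874) and "carrier vs
non-carrier" are dominant (rs4775302, rs1994198, rs1571801, rs6497287).
Protective ORs (< 1) enter the product as published, uninverted. The
published description of this panel is internally inconsistent about
whether 5 or 10 SNPs enter; the panels are therefore data files, not code
(`panels/*.tsv`), and any subset can be supplied. The default uses all 10.

Risk-allele counts sum raw dosages (not remapped exponents), so the
attainable range over the 4-SNP panel with the KLK3 zero class absent is
1–8.

## Risk classification and eligibility

High risk: Gleason 7–10 **or** stage T2c; low risk: otherwise with Gleason
≤ 6. The high-risk rule is evaluated first, so Gleason ≤ 6 with T2c is high
risk. Men missing stage are classified on Gleason alone; men missing
Gleason with an uninformative stage (T1–T2b) cannot be classified and are
excluded, as are men missing both (an error when classified directly).
Stage T3–T4 is excluded by default — such men are biopsied regardless of
any genetic correction — and moved into the high-risk group under the
sensitivity-analysis toggle. Stage labels are parsed case-insensitively;
unknown labels become missing with a warning. The PSA eligibility window is
half-open, [3, 10): 3.0 ng/mL is eligible, 10.0 is not.

## Synthetic screened cohorts

The generator is first-class, tested code; its defaults *are* the study
conditions and are not tuned per analysis.

* **Genotypes**: `dosage ~ Binomial(2, f)` independently across SNPs and
  subjects (Hardy–Weinberg, no linkage disequilibrium). Default effect-
  allele frequencies are recovered from the published genotype counts of
  the 868-man study cohort, e.g. rs10788160: (317 + 2·53)/(2·868) ≈ 0.244.
* **PSA**: `log PSA = μ + Σ_s dosage_s·log(factor_s) + ε`,
  `ε ~ N(0, σ²)` — log-normal with multiplicative per-allele effects, the
  simplest model compatible with effects stated as percent increase per
  allele. Defaults μ = −0.10, σ = 0.80 were calibrated once so that inside
  the [3, 10) window the cohort reproduces the study's marginal moments
  (mean PSA ≈ 4.9 ng/mL, SD ≈ 1.7); they are frozen study conditions.
* **Screening selection** retains the half-open window and records the
  selected fraction (≈ 30% under defaults).
* **Risk labels**: `P(high) = logistic(a + b·log PSA)` with a = −3.0411,
  b = 1.0980, calibrated once to give 21.2% high-risk prevalence and
  stratum means ≈ 5.4 vs 4.8 ng/mL. Labels are drawn conditionally on PSA
  (the simplest generative direction consistent with the observed PSA
  difference); optional per-SNP log-odds terms and a mode in which risk
  depends only on the *non-genetic* component of log PSA support positive-
  control experiments. Gleason/stage are emitted consistently with the
  drawn label (7/T1 vs 6/T1) so the cohort round-trips the classifier.
* **KLK3 zero class**: subjects with rs17632542 dosage 0 (≈ 0.36% at
  f = 0.94) are removed during cohort assembly, emulating the screened data
  in which that genotype is absent and keeping the shifted-additive
  contrast well defined. The genotype-sampling primitive itself remains
  pure binomial; as a consequence the assembled cohort's rs17632542 counts
  sit slightly off exact Hardy–Weinberg proportions, which the per-cohort
  HWE table makes visible rather than hiding.
* **Demographics**: ages uniform on 50–69, centres uniform over nine UK
  city labels, optional standard-normal PC covariates independent of
  genotype. No claim of realism beyond the design margins.
* **Seeding**: one master seed spawns independent per-stage streams
  (genotypes, PSA noise, labels, demographics, PCs), so a stage can be
  re-run alone; identical config + seed gives bit-identical cohorts.

Under these defaults the four PSA-SNPs explain ≈ 0.5% of within-stratum
PSA variance in the population; fitted at the study's sample sizes
(≈ 184/684 with four predictors) the sample R² inflates to roughly the
1–2% the original small-sample fits report. What passing tests show is
that the *mechanism* holds — selection on the window attenuates SNP–PSA
slopes, and correction with so little genetic variance cannot move the
AUC — not that real cohorts share the generator's independence and
log-normality assumptions (no LD, no imputation dosage uncertainty, no
age–PSA trend, no benign-disease component of PSA).

## Regression stages

PSA-level fits are OLS of PSA (ng/mL) on additive dosage with age, study
centre as fixed-effect indicators (first level dropped) and any PC
covariates; variance-explained summaries (R², F) come from the unadjusted
single-predictor fit. Risk-group fits are ML logistic regressions with
Wald 95% CIs (the CI method was unstated upstream; Wald is the default
here). Separation is detected (diverging coefficients or standard errors)
and raised, never silently estimated. Per-SNP p-values are reported raw —
no multiplicity correction, matching the original analysis. Fractional
imputed dosages pass the regression pathway but are rejected by the score
pathway's exponent map with a clear error.

Hardy–Weinberg checks default to the 1-df chi-square goodness-of-fit test
against p², 2pq, q² with the allele frequency estimated from the counts;
a conditional exact test (summing heterozygote-count probabilities no
larger than the observed) is available for sparse counts. Monomorphic SNPs
are flagged, not tested.

Internal-coefficient models 1–4 refit high/low risk on measured PSA alone,
plus the 4 PSA-SNP dosages, plus the aggressive-SNP dosages, or all, and
score each by in-sample AUC of the fitted linear predictor. Because ML
maximises likelihood rather than rank statistics, the in-sample AUC of a
nested fit can decrease by a sliver when added predictors are pure noise;
tests allow 0.005 for this.

## Discrimination calculus

The empirical ROC groups tied scores at a single operating point, making
the trapezoidal AUC equal the Mann–Whitney statistic
`P(pos > neg) + ½P(tie)`; this equality is tested exhaustively on small
instances at 1e−12. AUC variance, CIs and the paired two-sided test use
DeLong's placement-value estimator (O(n log n) midrank form), verified to
~1e−10 against an independent reference implementation (pROC) on a frozen
instance; a paired-bootstrap comparison (normal approximation with the
bootstrap SE) is the opt-in alternative. The fixed-sensitivity operating
point uses the empirical step function — the largest threshold whose
achieved sensitivity still meets the target, so the achieved value sits
just above it (e.g. 90.2% for a 90% target); interpolation to the exact
target is opt-in. Scores are oriented so that higher means higher risk; a
negatively oriented score yields AUC < 0.5 with a warning, never an
automatic flip. `LR = sensitivity/(1 − specificity)` holds bit-exactly in
every emitted record; specificity 1 produces IEEE +inf rather than an
error. Posterior odds are exactly prior odds × LR; because the upstream
definition of "prior odds given measured PSA and age" is unspecified,
prior odds are an explicit input (the pipeline defaults to cohort
prevalence odds and labels that choice in provenance).

## Pipeline and determinism

`run_analysis` chains filtering → scoring → per-SNP associations →
allele-count summary → the four-score AUC/LR comparison (measured PSA,
PSA − g4, PSA − g10, PSA − g4·g10) → internal models → configured
sensitivity analyses, logging each stage with input/output digests.
Reports serialise with sorted keys and repr floats, so identical config +
seed produces byte-identical files. Sensitivity analyses are config
toggles running through the same code paths, including the deliberately
small extreme-grade contrast (Gleason ≥ 8 vs 5–6) and T3–T4 inclusion.
The per-allele-count table emits means of *both* measured PSA and the
corrected score per stratum, because a published per-count table of this
kind can be read either way; the package reports both and adjudicates
neither.

## Problem sizes

Default simulated cohorts use 12,000 men before screening (≈ 3,500
eligible) — large enough for stable AUC estimates while keeping the full
pipeline and the Monte-Carlo test suite (100-replicate null/positive-
control contrasts, 200-replicate attenuation checks, 1,000-replicate
DeLong calibration at n = 300, 50,000-subject parameter recovery) inside
interactive runtimes.

## Known limitations

* The generator omits LD, genotype uncertainty, age and benign-prostate
  effects on PSA; its point is mechanism, not demographic realism.
* Wald intervals can misbehave at small counts (the extreme-grade contrast
  has ~20 cases); profile-likelihood alternatives are not implemented.
* The deposited spreadsheet of the original cohort cannot be
  redistributed; the test that reproduces its AUC/operating point runs
  only when a user supplies that file locally.
* No partial AUC, time-dependent ROC, calibration analysis, genotype
  QC/imputation or PC computation — out of scope by design.
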