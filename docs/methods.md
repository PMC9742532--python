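# Methods

## Problem

Community diabetes screening is a two-stage process: an inexpensive
screen (a questionnaire risk score, a trained classifier, or a single
laboratory test) flags high-risk individuals, who are then sent for a
confirmatory oral glucose tolerance test (OGTT). The quality of the
screen determines three per-participant quantities: how many people need
the confirmatory test, what the average detection cost is, and how much
future complication cost is attributable to the diabetics the screen
misses. `dmscreen` implements this evaluation end to end on synthetic
cohorts, so that screening strategies can be compared at matched
sensitivity or matched cost with fully reproducible arithmetic.

## Diagnostic model

Diabetes is defined from plasma glucose: fasting plasma glucose (FPG)
≥ 7.0 mmol/L or 2-h post-load glucose (2hPG) ≥ 11.1 mmol/L. Diabetics
subdivide into isolated post-load (FPG normal), isolated fasting (2hPG
normal), and combined hyperglycemia. A single threshold per analyte
plays both the diagnostic and the "seemingly normal" role; the
alternative convention of a 11.0 mmol/L normality boundary for 2hPG
would leave an undefined band between 11.0 and 11.1, so the package
uses one configurable 11.1 threshold for both purposes. HbA1c is used
only as a screening lab, never as an outcome; its normality boundary
defaults to the standard 6.5%.

## Synthetic cohort generator

One standard-normal latent risk `z` per person drives all correlation
structure:

* **Continuous features** (age, resting pulse rate, blood pressures,
  anthropometry, sleep duration, years of cell-phone use) are
  `median + loading·z + noise`, with medians and IQRs set to values
  typical of a middle-aged, predominantly female Chinese community
  cohort, and the noise SD derived as IQR/1.349. Loadings are sized so
  the diabetic stratum is ~3 years older, ~6 bpm faster at rest, ~7 mmHg
  higher in systolic pressure, and modestly more centrally obese —
  shifts of the magnitude reported for such cohorts. Height carries no
  loading. BMI, waist-to-hip and waist-to-height ratios are *derived*
  row-wise from weight, height, waist and hip, so the anthropometric
  identities hold exactly.
* **Categorical features** (sex, smoking, drinking, physical activity,
  work status, education) threshold a unit-normal latent, partially
  loaded on `z`, at the quantiles of the category frequencies. Several
  of these are deliberately only weakly informative so that top-k
  feature selection faces a real ranking problem.
* **Glucose**: log FPG and log 2hPG are bivariate normal conditional on
  `z` — each log-analyte is loaded on `z` (correlation share 0.6) plus a
  correlated residual. Marginally the pair is bivariate lognormal, which
  is what makes calibration analytic (below). Lognormality gives the
  right-skewed tails glucose shows empirically.
* **HbA1c** is linear in the two glucose values plus Gaussian noise
  (SD 0.30%), truncated at 3.5%; its coefficients reproduce the typical
  non-diabetic median near 5.5% and diabetic median near 6.0%.
* **Diabetes status and subtype are derived** from the generated glucose
  pair through the diagnostic rule — never sampled directly — so status
  and labs can never disagree.

### Calibration

The generator is calibrated to three population facts: 12.4% diabetes
prevalence and 41% / 28% / 31% isolated post-load / isolated fasting /
combined subtypes among diabetics. Because the marginal log-glucose pair
is bivariate normal, these targets have a closed-form solution:

1. The probability of each analyte being below its diagnostic threshold
   is a margin fixed by the targets (e.g. P(FPG < 7) = 1 − prevalence ×
   (fasting + combined)); holding the log-median at its configured value,
   the probit quantile of that margin fixes the log-scale SD.
2. P(both below) = 1 − prevalence fixes the total log-scale correlation
   through a Brent root-find on the bivariate normal CDF.
3. The residual correlation after removing the shared-latent part
   follows algebraically; infeasible targets (residual correlation
   outside (−1, 1), or a margin below one half) raise a calibration
   error with diagnostics.

A sampling verification pass (default n = 50,000) then checks the
realized prevalence (±0.01) and subtype fractions (±0.03). At n = 50,000
the realized subtype percentages fall within a few tenths of a point of
the targets.

### What the generator does not emulate

Missingness is MCAR only (no informative missingness); there is no
measurement error model for the labs, no longitudinal follow-up, no
family history or medication features, and the ~150-feature breadth of a
real screening questionnaire is represented by a ~16-feature core plus
weak noise features. The latent structure is *linear* in one factor, so
a linear model is close to the Bayes-optimal screen here — on real data
nonlinear learners such as boosted trees typically win the bake-off, and
on this synthetic cohort logistic regression does (see
`results/model_bakeoff.csv`). Passing tests therefore demonstrate the
correctness of the machinery, not the superiority of any learner on
real data.

## Risk models

* **Score tables** follow the questionnaire pattern (binned integer
  points per item, positivity at a recommended cutoff). The published
  NCDRS and ADART point tables are not redistributed; the shipped JSON
  files are clearly marked synthetic placeholders with the same schema
  and the published cutoffs (≥25 and ≥5).
* **Classifiers**: logistic regression, calibrated SVM, random forest,
  k-NN, a centroid-displacement k-NN variant, a small multilayer
  perceptron, and LightGBM gradient boosting, all behind one
  `predict_risk` interface with fixed, sensible defaults and a seed
  (hyperparameter search is deliberately out of scope). Standardisation
  is applied for scale-sensitive learners; categoricals are one-hot
  encoded.
* **Cross-validation** uses a seeded random partition into k near-equal
  folds (default 5); pooled metrics are computed on out-of-fold
  predictions; 95% CIs by stratified percentile bootstrap.
* **Imputation** is a chained-equations iterative imputer fitted on the
  development set only and applied unchanged to the testing set;
  categoricals take the development-set mode; columns with ≥20% missing
  development values are dropped with a warning.
* **Streamlining** ranks features by mean absolute additive
  contribution, cross-validates models on the top 5/10/15/20/25, and
  selects the smallest k within a tolerance (default 0.005) of the best
  CV AUC — an explicit, testable version of "best predictive power with
  the fewest features".
* **Explanations** are exact additive decompositions of the log-odds:
  native tree-path contributions for LightGBM and the linear
  decomposition β·(x − x̄) for logistic regression, both grouped back
  from one-hot columns onto original features (additivity is preserved
  by grouping and asserted to 1e-6). Other learners fall back to seeded
  permutation importance for ranking only. A feature's contribution φ
  converts to a relative risk as sigmoid(base + φ) / sigmoid(base) —
  a declared convention, chosen because it compares the person-level
  predicted risk with and without the feature's contribution at the
  model's base rate.

## Screening cascades

Four designs are supported, differing in the screening lab performed
before the risk model: none (community setting), FPG-first, 2hPG-first,
and HbA1c-first (primary-care settings). A diagnostic screening-lab
result ends the trail immediately (detected, no confirmatory test).
Otherwise the risk model is applied to the screening-normal stratum;
positives receive the confirmatory test: a full OGTT where no glucose
analyte has been measured (no-lab and HbA1c designs), otherwise only
the missing analyte (2hPG after an FPG screen, FPG after a 2hPG
screen) — the analyte already measured is not repeated, and the cost
schedule prices the four tests separately.

Confusion outcomes compare the strategy's *flag* (screen-lab diagnostic
or model positive) against true diabetes status. A flagged non-diabetic
is a false positive even though the confirmatory test will clear them —
the cleared visit is precisely the avoidable cost — and for every true
diabetic the flag and the eventual detection coincide by construction of
the confirmatory-test contents.

## Economics

Costs are Chinese prices in CNY, medical + non-medical per test:
FPG 9.89 + 8.3, 2hPG 23.56 + 27.5, OGTT 33.45 + 27.5, HbA1c 84.16 + 8.3.
Per-participant detection cost is the itemised bill over every trail
divided by N. Potential complication costs per missed diabetic per year
are the published ranges 341–567 (5 y), 1302–2555 (10 y), 2802–5611
(15 y), 4428–8212 (20 y) and 5258–9132 (25 y); no discounting is
applied (no discount rate is published for these ranges). Costs are kept
at full precision internally and rounded to 2 decimals in reports.

## Statistical machinery

AUC is the Mann–Whitney pair statistic (ties one half); auPR uses
step-wise (non-interpolated) precision summation, whose random baseline
is the prevalence. Paired AUCs are compared with the DeLong
placement-value covariance estimator and a two-sided normal
approximation. CIs are stratified percentile bootstraps (B = 2000 by
default; the CI method is a package convention). Matched comparisons
invert step curves by grid search over observed score cutpoints: at
matched sensitivity, the qualifying operating point flagging the fewest
people; at matched cost, the most sensitive point within budget.
Relative reductions are (a − b)/a on unrounded values.

## Numerical conventions and problem sizes

All randomness flows from integer seeds through `numpy` Generators; the
same configuration reproduces byte-identical outputs. Positivity is
`score ≥ threshold` everywhere. Undefined metrics (zero denominators)
are returned as `None`, never silently as 0. The shipped analyses use
n = 8425 with a 60/40 split (5055/3370); generator calibration and the
population-fact checks use n = 50,000, where binomial error on a subtype
fraction is about ±0.4 points. Threshold sweeps cap the cutpoint grid at
201 quantile-spaced candidates plus a flag-nobody sentinel.

## Known limitations

The placeholder point tables are not the published scores, so
score-table operating points (e.g. sensitivity at the ≥25 cutoff) are
not comparable to published values. The single-latent linear generator
cannot express interactions or non-monotone feature effects, and its
feature set is far narrower than a real screening questionnaire. The
centroid-displacement k-NN is a simple local-centroid variant, not a
reimplementation of any specific published algorithm. Matched
comparisons assume both strategies are evaluated on the same testing
set; no transportability adjustment is attempted.
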