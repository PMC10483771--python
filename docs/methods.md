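# Methods

## Scoring model

The LGI score is a rank-based composite. For each of CRP, WBC, PLT and
NLR, every patient's value is converted to a cohort-internal decile via
mid-ranks — observation *i* with mid-rank *r_i* (average rank among ties)
in a cohort of *n* gets decile ⌈10·r_i/n⌉ — and the decile maps to a fixed
score (1→−4 … 4→−1, 5–6→0, 7→1 … 10→4). The total is the sum over the
four markers (−16…16). The mid-rank/ceiling formulation was chosen because
it is invariant to monotone transforms of the marker, handles ties
deterministically (tied values always share a decile), and is independent
of input order. All four markers are scored in the same direction: higher
level, higher score. Deciles are cohort-relative, computed from the
analyzed sample rather than external reference ranges, so scores are
comparable only within one cohort; `LGIScorer.fit` freezes the reference
distributions so that new observations can be ranked against a fitted
cohort. Records with a non-positive lymphocyte count have no defined NLR;
they are excluded from the reference distributions and reported, not
silently dropped. Quartile groups of the score use the same mid-rank rule
with 4 bins; because the score is integer-valued, tied scores straddling a
quartile boundary stay together and group sizes deviate from n/4 by the
size of the tied block. A fully degenerate score distribution collapses to
one group with a warning.

## Endpoints

Severity is NIHSS > 5 (assessed at baseline and day 7), END is a rise of
≥ 2 NIHSS points from baseline to day 7, and the 90-day outcome
dichotomizes mRS as excellent (0–1) vs poor (2–6). Threshold-derived risk
factors follow the usual clinical cutoffs (SBP ≥ 140 or DBP ≥ 90 mmHg or
antihypertensives; fasting glucose > 7.0 mmol/L or antidiabetics; total
cholesterol > 5.18 or triglycerides > 1.7 mmol/L). The diabetes rule is
applied to the single glucose value the schema carries, standing in for
the repeat-measurement clinical definition; recorded flags take precedence
when raw measurements are absent.

## Association models

Each endpoint is regressed on quartile indicators (reference: quartile 1)
by maximum-likelihood logistic regression at three adjustment tiers —
crude; model 1 (gender, age); model 2 (+ smoking, drinking, prior stroke,
AF, CHD, hypertension, diabetes, dyslipidemia, and baseline NIHSS for the
90-day outcome only, since NIHSS *is* the severity endpoints' own scale).
ORs carry Wald 95% intervals, exp(β ± 1.96·SE), matching the reporting
convention of clinical tables; profile-likelihood intervals were not used.
The p-for-trend refits the model with the quartile index (1–4) as a single
ordinal covariate and reports its Wald p — the dose–response test most
consistent with the regression framework. Analyses are complete-case, with
per-model n and dropped-row counts recorded. Separation and
non-convergence are flagged on the report (detected via the optimizer
status, statsmodels' separation warnings, and |β| > 15 as a
quasi-separation guard); no silent fallback is applied. Quartile levels
absent from an analysis subset drop out of the design matrix; an empty
reference quartile is an error, and in stratified analyses such strata are
skipped with a warning. Stratified analyses fit crude within-stratum
models on the cohort-level quartile labels (an adjustment tier can be
requested); effect modification is tested by a 1-df likelihood-ratio test
on the stratifier × ordinal-quartile product term in the pooled model,
matching the single-p-per-stratifier reporting style.

## Discrimination and added value

The AUC is the Mann–Whitney concordance probability with ties counted 1/2;
its variance comes from the DeLong structural components, giving a normal
95% CI clipped to [0, 1]. The continuous NRI sums the net proportion of
events whose predicted risk rose and nonevents whose risk fell (exact ties
count as no movement — an explicit, testable choice); the IDI is the
change in discrimination slope. Both use asymptotic (Pencina-style)
variance estimates for p-values; a seeded bootstrap percentile interval
(default 2,000 resamples) is available. `compare_models` fits the
conventional logistic model (age + baseline NIHSS) and the add-on model
(+ LGI score, continuous by default; quartile-coded behind a flag) and
compares their in-sample predicted risks — apparent performance, matching
standard clinical reporting; an optional stratified k-fold mode yields
out-of-fold risks for honest estimates. The LGI-only AUC is computed on
the raw score (equivalent to a univariable logistic fit up to the monotone
link).

## Descriptive table and sample size

Categorical variables are compared by the chi-square test without
continuity correction, switching to Fisher's exact when the table is 2×2
and any expected cell is below 5; larger sparse tables keep the chi-square
with a recorded note, as no exact r×c test is available in the stack.
Continuous variables pass a per-variable gate — Lilliefors-corrected
Kolmogorov–Smirnov normality on the pooled values plus Levene's
equal-variance test, both at α = 0.05 — selecting ANOVA/t-test with
mean ± SD, else Kruskal–Wallis/Mann–Whitney with median [IQR]. Gating per
variable (not per variable-per-group) keeps one summary format per row;
the gate's p-values are recorded on each row. The events-per-variable
utility returns n_factors · EPV / event_proportion unrounded (15 factors
at EPV 10 with events in 80% of subjects → 187.5).

## Synthetic cohort generator

The generator emulates the marginal structure of a single-centre acute
ischemic stroke registry cohort (n = 876): 58% male, age median 70
[60.5, 78], hypertension 69.2%, diabetes 24.2%, dyslipidemia 43.9%,
CHD 13%, AF 10.6%, smoking 29.2%, drinking 26.8%, prior stroke 11%, TOAST
subtype proportions 35.4 / 13.7 / 40.9 / 10%. Published tables report no
biomarker summaries, so CRP/WBC/neutrophil/lymphocyte/platelet medians and
spreads are population-plausible admission values, log-normally
distributed. A single standard-normal latent inflammation factor loads on
every log-biomarker (negatively on lymphocytes, so NLR rises with it), on
the NIHSS negative-binomial mean, on the END deterioration probability,
and on the poor-outcome logistic link (which also takes age, centred at 70
years, and baseline NIHSS). This is deliberately the *minimal* structure
that makes the LGI–outcome association tunable and recoverable: set the
loadings and link coefficients to zero and every association test must go
null; set them to a known value and the fitted models must recover it.
Severity (NIHSS > 5) is not given its own link — it follows from the NIHSS
count model. Day-7 NIHSS is baseline plus a deterioration jump (+2 +
Poisson(1)) with probability expit(−2.20 + 0.60·f), else an improvement
drawdown floored at 0, making END prevalence (~11%; unreported in the
emulated registry) directly tunable. Default link coefficients were
calibrated once by Monte Carlo so the default cohort reproduces the
registry's stated outcome marginals — poor 90-day outcome ≈ 26%, NIHSS
median 2 [1, 4], Spearman(LGI, NIHSS) ≈ 0.26 — and then frozen. All
randomness flows from one `numpy` Generator seeded in the config; no
global RNG state is touched.

What the generator does **not** emulate: real correlation among risk
factors (they are drawn independently), measurement error and
repeat-measure variability, missing data, treatment effects
(thrombolysis/endovascular patients are out of scope by design), or any
biomarker–subtype dependence (TOAST is independent multinomial by
default). Passing tests therefore demonstrate the *statistical machinery*
— scoring, model fitting, inference calibration — not clinical validity
on real registries.

## Numerical choices and problem sizes

Logistic fits use statsmodels' Newton MLE (maxiter 200). Wald z is
1.959963…, not 1.96 rounded. The calibration suites run 500 replicates at
n = 800 — large enough that Wald coverage sits in the 0.93–0.97 band and
null p-values are uniform to a Kolmogorov–Smirnov check at α = 0.01, small
enough to keep the full test run around a quarter of a minute. Bootstrap
and permutation routines take explicit seeds. Exact ties in risk changes
contribute zero to the NRI; swapping the two models negates NRI and IDI
exactly, which the property tests assert to 1e-12.

## Known limitations

Cohort-relative scoring means a patient's LGI score changes with the
cohort it is computed in; cross-cohort comparisons need a frozen reference
(`LGIScorer.fit` on the reference cohort, `transform` on the new one).
The stratified-analysis interaction test uses the ordinal quartile term
(1 df); it will miss non-monotone effect modification. Fisher's exact is
limited to 2×2 tables. In-sample NRI/IDI are optimistic; use the k-fold
option for honest estimates.
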