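# Methods

`score2pro` implements a subgroup-stratified proteomic risk-prediction
analysis for incident myocardial infarction (MI): per-protein proportional-
hazards screening, machine-learned panel selection, and clinical-subgroup-
specific model evaluation, driven by a synthetic cohort generator that
emulates the statistical structure of a large middle-aged population cohort
with Olink-style plasma proteomics. This note records the models, the
defaults and why they were chosen, and what the synthetic validation does
and does not establish.

## The synthetic cohort

Each participant carries clinical covariates, a vector of protein levels,
a follow-up time and an event indicator.

**Covariates.** Marginals emulate a UK-style population cohort aged 40–69:
age ~ truncated normal (57, 8) on [40, 69]; 54.9% female; smoking
never/previous/current = 0.55/0.345/0.105; SBP ~ N(138, 19) mmHg with DBP
correlated at ρ = 0.65 (blood pressures co-vary strongly in any real
cohort); HDL, LDL and triglycerides independent truncated normals with
total cholesterol closed by a Friedewald-style identity
(total = HDL + LDL + TG/2.2 + ε, ε ~ N(0, 0.15)); BMI, eGFR and education
truncated normals; CRP log-normal (it is heavily right-skewed in any
population sample); diabetes prevalence 5.3%. The lipid closure and the
SBP–DBP correlation are deliberate departures from fully independent
marginals: independence would make HDL > total cholesterol commonplace
(physically impossible, and an input-validation error downstream) and would
leave chained imputation with no signal to exploit.

**Proteins.** Standard normal (NPX values are log-scale and are analysed
standardized), optionally equicorrelated in blocks
(`protein_block_corr`, `protein_block_size`), optionally loaded on age/sex
(`protein_age_sex_loading`, off by default so that confounding is a test
scenario rather than the baseline).

**Events.** Weibull proportional hazards:
S₀(t) = exp(−(t/λ)^k) with λ = `weibull_scale`, k = `weibull_shape`
(k = 1, the default, is exponential). The linear predictor is the sum of
planted per-SD log hazard ratios times protein values; an effect may carry a
subgroup condition, in which case it applies only where the condition holds
— this is the heterogeneity the stratified models are designed to detect.
Event times invert the survival function in closed form:
T = λ(−log U / e^lp)^{1/k}. Censoring is min(administrative horizon,
exponential dropout); default horizon 15 y, dropout 0.01/y, and λ chosen so
that baseline cumulative incidence is ≈ 4% by year 15, matching the
emulated cohort's ~4% MI incidence over ~14 y median follow-up.

Optional clinical-covariate log hazard ratios (`clinical_log_hrs`, off by
default) let a configuration reproduce the real cohort's clinical risk
gradients (events older, more male, more smokers) and, through them, an
elevated ~7–9% incidence in the high-risk composite subgroup. They are
mean-centred so baseline incidence is preserved.

**Missingness.** MCAR masks at configurable rates on protein columns and on
the continuous clinical columns. Outcomes, sex, age, smoking and diabetes
are never masked: the first three by contract, the rest because the
imputation contract here covers continuous variables only.

## Preparation

Order: protein filter → clinical imputation → 70/30 split → derived
variables. Proteins with missing fraction > 25% are dropped. Clinical
missingness is imputed either by column medians or (default) by chained
iterative imputation with extra-trees regressors (a few rounds suffice for
MCAR at the simulated rates); observed values are never altered and both
methods are seed-deterministic. Proteins are *not* imputed — the boosted
trees handle missing values natively and the Cox screen drops missing rows
per protein. The derivation/validation split is a simple random 70/30 draw,
made once on the full cohort and inherited by every subgroup analysis.
Protein standardization (mean 0, SD 1) is computed on derivation rows only
and applied to all rows, the leakage-safe reading of an "untouched"
validation set; non-HDL cholesterol = total − HDL is recomputed after
imputation so subgroup membership is defined for every row.

## Per-protein Cox screening

Each protein is tested in a proportional-hazards model with one of two
adjustment sets: model 1 (age, sex, education years) or model 2 (model 1 +
diabetes, smoking as previous/current indicators vs never, BMI, SBP, DBP,
total cholesterol, triglycerides, HDL, LDL, CRP, eGFR). Significance is
Bonferroni-corrected at α/m where m is the number of proteins tested in
that screen (subgroup screens use their own m).

The partial-likelihood maximizer is implemented in numpy with Efron
handling of tied event times. Screening hundreds of proteins across
simulation replicates needs millisecond fits, so when no two events share a
time the score and observed information collapse to reverse cumulative sums
plus a single weighted Gram matrix per Newton iteration (rows sorted by
time with events before tied censored rows, so every risk set is a suffix);
with tied events a general Efron path iterates over tie groups. Nuisance
covariates are standardized internally for Newton stability — the exposure
column is left on its own scale so the log-HR keeps the per-SD convention.
Monotone likelihoods (|log HR| > 15) are flagged non-convergent and
excluded from significance, never fatal to a screen. Adjustment matrices
drop linearly dependent columns after centring via pivoted QR — inside the
ever-smoker subgroup, for example, previous + current = 1 is constant and
would otherwise make the no-intercept Cox information singular. The solver
is cross-checked in the tests against grid maximization of the explicitly
written partial likelihood on ≤ 8-subject fixtures (10⁻⁴ agreement) and
against lifelines on larger tied-data fixtures.

Descriptive survival analysis dichotomizes chosen proteins at the cutoff
maximizing |sensitivity + specificity − 1| over observed values (the
magnitude form covers protective markers, whose Youden J is negative in the
conventional direction; ties break toward the lower cutoff), caps follow-up
at 15 years, and reports Kaplan–Meier curves per group plus adjusted HRs
against a reference group; two proteins give the 2×2 cross of their
cutoffs.

## Panel selection

Bonferroni-significant proteins are ranked by total split-gain importance
of one deterministic LightGBM classifier trained on all candidates
(protein features only; ties broken by candidate order). Sequential forward
selection then adds proteins in rank order; after each addition the
cumulative AUC is computed from out-of-fold predictions (stratified 5-fold
CV inside the derivation set). In-sample evaluation is available as a
switch but is not the default: a boosted tree's in-sample AUC is near 1
almost immediately and cannot drive a stopping rule.

A step is an **improvement** only if its gain over the best-so-far AUC is
both ≥ 0.003 *and* significant by a paired DeLong test at α = 0.05;
selection stops after four consecutive non-improvements, and the panel is
the best-so-far prefix. Requiring both conditions is deliberate: with a few
hundred events the out-of-fold refit noise alone clears either single
condition often enough to drag several noise proteins into every panel,
while the conjunction keeps panels minimal without losing planted signal
(the disjunctive form recovered panels with 3–7 spurious members under the
same conditions). An ε = ∞ setting therefore degenerates to "stop after
`plateau_length` steps", which is the intended boundary behaviour. The
comparison baseline (best-so-far vs previous step) is configurable.

Boosted-tree defaults: 200 trees, depth ≤ 3 (8 leaves), learning rate
0.05, `min_child_samples` 200 — capped at n/20 (floor 20) on small training
sets so trees can still split. The large leaf floor matters: a
lightly-constrained booster given only one or two features memorizes
feature quantiles, which *depresses* small-panel out-of-fold AUC so much
that appending pure-noise features genuinely raises it (+0.02 observed),
destroying panel minimality. All runs fix `deterministic=true`,
single-threaded row-wise histograms, and a config seed: traces are
bit-reproducible.

## Evaluation statistics

* **AUC** — Mann–Whitney with midrank ties.
* **DeLong** — structural-component variance/covariance for paired AUCs;
  verified to 10 decimals against R's pROC on a frozen fixture, against a
  participant bootstrap (variance within 15%), and by type-I simulation.
  Comparing a score vector with itself is reported degenerate (Δ = 0,
  p = 1).
* **Dynamic AUC** — at horizon t, cases are events by t, controls are
  subjects still at risk at t; subjects censored early without an event are
  excluded at that horizon (no IPCW weighting; the simple exclusion rule is
  documented rather than hidden). Horizons run forward from baseline.
* **Categorical NRI** — two categories at a risk threshold;
  event NRI = (up − down)/n_events, non-event NRI = (down − up)/n_non-events,
  overall = their sum (an exact identity on the same sample). Inference is
  a percentile bootstrap over participants (default 1,000 resamples) with
  a normal-approximation p from the bootstrap SE. An optional "calibrated"
  variant first recalibrates each model's risks by logistic intercept+slope
  on the logit, fitted on derivation predictions; raw risks are the default
  output.
* **Optimism correction** — Harrell's procedure: refit on each bootstrap
  resample, optimism = AUC(resample-fit on resample) − AUC(resample-fit on
  original), corrected = apparent − mean optimism. Known limitation: for a
  model that interpolates its training data, ~63% of the "original" sample
  is memorized in-bag, so the detectable optimism is bounded and the
  corrected AUC of an unconstrained tree on pure noise settles near 0.7–0.8
  rather than 0.5. The procedure is validated on non-interpolating recipes;
  the tests document the interpolator case explicitly.
* **Geographic CV** — leave-one-region-out; folds whose test (or training)
  rows are single-class are skipped with a warning.
* **HR heterogeneity** — pairwise Z = (β₁ − β₂)/√(SE₁² + SE₂²) on subgroup
  log-HRs, two-sided normal p.

## Stratified framework

Ten subgroups from five binary SCORE2-style stratifications: sex, age
(< 60 vs ≥ 60 y), smoking (never vs ever), SBP (< 140 vs ≥ 140 mmHg,
the European hypertension boundary), non-HDL cholesterol (< 4 vs
≥ 4 mmol/L). Within each subgroup (derivation rows only): model-2 screen
with a subgroup-specific Bonferroni denominator → importance ranking →
forward selection → a subgroup-specific protein classifier. Comparators on
the *identical* subgroup validation rows (row-id audit retained): a
clinical model trained de novo on the SCORE2 covariate set (age, sex,
smoking, SBP, total and HDL cholesterol — published SCORE2 coefficients are
deliberately not used; the stratifying variable stays in the feature set
whenever it is not constant in the subgroup), a combined clinical+protein
model, and the general protein model — trained once on the full derivation
set and only *evaluated* inside the subgroup. ΔAUC uses the DeLong test;
reclassification uses categorical NRI at a 5% threshold. Subgroups with
fewer than 30 derivation events (configurable) are skipped with an
explicit report entry.

The high-risk composite (male ∧ ever-smoker ∧ SBP ≥ 140 ∧ non-HDL ≥ 4;
optionally extended by diabetes) is evaluated with a proteomic model built
from the union of the four matching one-variable panels, at a risk
threshold equal to the composite's own observed incidence rounded to the
nearest percent. Four reclassification bundles are reported: specific
alone, specific+clinical, general alone, general+clinical, each against
the clinical model, with 2×2 movement tables. The same machinery sweeps
all 2⁵ = 32 composite cells (per-cell panel = union of the five matching
one-sided panels, per-cell incidence threshold; under-powered cells are
reported as skipped). Panel intersections across the ten subgroups are
tabulated as a protein × subgroup membership matrix with exact
intersection-pattern counts.

## Problem sizes and what the validation shows

The bundled demonstration (`configs/demo.yaml`) uses 10,000 participants
and 200 proteins with ten planted effects (four subgroup-conditional) and
clinical hazard gradients; it runs end-to-end in about a minute. The
statistical test-bench sizes were chosen to keep the whole suite inside a
desktop run while leaving pass bands binomially consistent with the rates
they check: screening error control at n = 5,000 (15 replicates) and power
at n = 20,000; panel recovery at n = 10,000 with 50 candidates (12
replicates); subgroup specificity at n = 30,000 (10 replicates);
type-I-error simulations at 2,000 replicates.

Passing these simulations shows the machinery is correct and calibrated
under its own generative assumptions — proportional hazards, MCAR
missingness, Gaussian proteins, exchangeable regions. It does not show
robustness to what the generator does not emulate: batch/plate effects and
Olink QC artefacts, informative censoring, competing risks, non-proportional
hazards, or the real joint distribution of clinical covariates (only
partially mimicked). At the demonstration scale the high-risk composite
holds only a few hundred participants and a handful of validation events,
so its NRI estimates are honest but volatile across seeds; the full-size
analysis this emulates had several times more events in that cell.

## Known limitations

* The Youden cutoff is computed on the full cohort (the dichotomized
  survival analysis is descriptive, not part of the prediction pipeline).
* NRI p-values use the bootstrap-SE normal approximation, not an exact
  permutation.
* Optimism correction under-corrects interpolating models (above).
* The 32-cell sweep's per-cell panels are unions of one-variable panels;
  cells are not re-screened (too few events per cell at desk scale), and
  the union rule is recorded in the output metadata.
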