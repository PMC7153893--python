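# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limits of what the test suite demonstrates.

## Per-cell state classification

FISH scoring yields an integer signal count per probe per cell. The
package maps counts to a three-state classification relative to a disomic
reference of 2 signals per nucleus: count < 2 → loss, = 2 → normal,
> 2 → gain. The reference is configurable per probe
(`classify_cell_states(..., normal_counts=...)`) because centromeric and
locus probes can warrant different baselines in tetraploid or polysomic
material; the default follows the common FISH convention. Counts of 3 and
4 collapse to the same "gain" state — clones are defined on the
three-state profile, not on raw counts. This is a modeling choice: it
keeps clone counts stable under minor scoring noise at the cost of merging
high-level amplifications with single-copy gains.

## Diversity scores

For a patient and a marker subset (any of the 15 non-empty subsets of a
4-probe panel), cells sharing the same state profile over the subset form
a clone. With clone proportions p₁…p_R over N cells:

- Shannon S = −Σ pᵢ ln pᵢ (natural log). Note the sign: the index is
  sometimes written without the leading minus, which makes it non-positive;
  this package reports the conventional non-negative entropy.
- Simpson S′ = Σ pᵢ², inverse Sᵢ = 1/S′, complement S_c = 1 − S′.
- Normalized clone score NC = R/N.

All five are computed exactly (no bias correction, no rarefaction), which
matches how they are used here: as relative covariates within a cohort
scored with a common ≥50-cell protocol. NC in particular is
sample-size-dependent; the ≥50-cell inclusion rule is what makes it
comparable across patients.

## Inclusion filters

Patients are excluded for baseline dysplasia, for having fewer than 50
scored cells in a panel under analysis, or for progressing within 6 months
of the baseline brush (such early progressors plausibly harbored prevalent
dysplasia). Patients missing one panel remain eligible for analyses of
the other panel. The filter is idempotent and logs each exclusion.

## Cox modeling

Fits maximize the Efron-tie partial likelihood via lifelines
(Newton–Raphson, convergence tolerance 1e-9, up to 500 steps — the
tightened tolerance matters on flat likelihoods, where the default stops
~2e-4 from the maximizer). Reported per-coefficient statistics: hazard
ratio exp(β), 95% CI exp(β ± 1.96·SE), Wald p; per-model: overall Wald
test, likelihood-ratio test against the null model, and
AIC = −2·loglik + 2·k. Significance is declared at p ≤ 0.05 on both the
Wald and likelihood-ratio tests; univariate screens additionally flag
0.05 < p ≤ 0.10 as borderline (borderline covariates stay eligible for
multivariate models, since segment length behaves this way in real
cohorts).

Models carry at most 3 base covariates by default — about one per ten
events in a 32-event cohort — and the fitter warns whenever covariates
exceed events/10. Constant covariates are dropped; if nothing remains the
fit degenerates to the null model with lr_p = 1 rather than erroring, so
bootstrap loops survive degenerate resamples.

Spline expansion uses the truncated-power natural cubic basis
(N₁(x) = x, N_{k+1}(x) = d_k(x) − d_{K−1}(x), the standard constant-free
form) with df columns, boundary knots at the training range and interior
knots at equally spaced quantiles; df = 3 by default, minimum 2. A basis
containing the constant function would make the Cox information matrix
singular, which rules out off-the-shelf regression-spline bases that span
the intercept. Splines are applied in a fixed order (age first, then
C-length, then the third covariate) when enumerating candidate models, and
spline-vs-linear choices are made by the nested likelihood-ratio
(anova) chi-square at p ≤ 0.05.

## Integrated time-dependent AUC

Discrimination of a risk score on survival data is summarized by the
incident/dynamic time-dependent AUC: at each observed event time t ≤ τ,
cases are patients progressing exactly at t, controls those event-free
beyond t, and AUC(t) is the probability a case outranks a control (ties
count 1/2). The curve is integrated with weights w(t) ∝ 2·f̂(t)·Ŝ(t) from
the Kaplan–Meier estimate on the evaluation data, normalized to sum to 1.
τ defaults to the 95th percentile of follow-up, which stabilizes the tail
where few patients remain at risk. The estimator is rank-based, hence
invariant under strictly monotone transforms of the score; a constant
score gives exactly 0.5. Tests cross-check it against scikit-survival's
cumulative/dynamic Uno AUC — a different member of the same family that
reads systematically slightly higher under strong effects — for agreement
and shared ordering, never as the implementation.

## Bootstrap model selection

Each of B replicates draws n patients with replacement as a training set,
fits the candidate model, records its training AIC, and evaluates iAUC on
the out-of-bag patients. Replicates whose training or out-of-bag set
carries no usable event are redrawn and counted; replicate seeds derive
from (master seed, replicate counter), so results are reproducible and
independent of execution order. Models are ranked by median out-of-bag
iAUC descending, ties broken by lower median AIC, with a final
model-id tie-break for full determinism. B = 1000 is the default for real
analyses; the bundled analysis scripts and acceptance checks use B = 200,
which leaves the medians' ordering stable while keeping runs short.

## Leave-one-out stratification

The selected model is refit n times, each time leaving one patient out;
the held-out patient's risk score is exp(linear predictor) with covariates
centered at the training fold's means. The absolute scale of such scores
is an arbitrary (exponentiated, centered) quantity — only the induced
ranking and the chosen cut-off matter, and all reported stratification
statistics are functions of the resulting 2×2 table. High risk is
score ≥ cut-off; the helper `select_cutoff` returns the largest cut-off
whose sensitivity still reaches a target (default 0.90, the
surveillance-oriented operating point). Confidence intervals: Wilson score
for proportions (sensitivity, specificity, PPV, NPV), Simel's log-method
for likelihood ratios; these are reported for orientation and are not the
basis of any selection. Degenerate cells yield NaN statistics rather than
errors. Group comparison uses product-limit curves and the two-sample
log-rank test (NaN when no events occurred at all); annual progression
rates are 100 × events / person-years.

## Synthetic cohort generator

The generator emulates the marginal structure of a multi-center NDBE
surveillance cohort and ties outcomes to covariates through a known
hazard, giving every pipeline stage a ground truth.

Per patient: latent clone count K ~ 1 + Poisson(2) per panel, the first
clone being the diploid ancestor; each further clone aberrates each probe
with probability 0.15, direction biased per probe (losses favored for
CDKN2A/TP53, gains for the rest); clone proportions ~ Dirichlet with
α = 5 on the ancestor and 1 elsewhere, so the normal clone usually
dominates; 50–120 cells per panel drawn multinomially, clone signatures
mapping to counts (loss=1, normal=2, gain=3). Clinical margins: age
~ N(60, 10) truncated above 18 years, C-length a rounded
Gamma(1.1, 2.6) (median ≈ 2 cm), M-length = C + 1 + Poisson(1), BMI
~ N(27.2, 3.8), and binary covariates at the observed cohort frequencies
(81% male, 71% smokers, 99% PPI use, 66% community hospitals).

Survival: log-hazard β_age(age−60) + β_C(C−2) + β_NC(NC−0.04), where NC
is the normalized clone score measured on the generated set-2 cells over
all four probes — the same quantity the pipeline later computes, so
parameter-recovery tests face no errors-in-variables attenuation. Default
effects: β_age = ln 1.1 per year and β_C = ln 1.1 per cm (univariate-scale
hazard ratios typical of NDBE cohorts); β_NC = 120 per unit NC, chosen so
that the three-covariate model's median out-of-bag iAUC lands near
0.85–0.9 given the clone structure above (measured NC has sd ≈ 0.012, so
this corresponds to a ~1.4 log-hazard spread per NC standard deviation).
Censoring is Uniform(53, 120) months (median 86.5) under an
administrative cap of 120 months; the exponential baseline rate is solved
by Brent's method on the realized linear predictors and censoring times so
the expected progressor fraction equals 9.6%. Event times are exponential
given the linear predictor; progressors split evenly between HGD and EAC.

What the generator does **not** emulate: hybridization failure and scorer
disagreement, spatial clone structure along the Barrett segment,
non-proportional or time-varying hazards, correlation between clinical
covariates and clone structure, and informative censoring. Tests passing
on synthetic cohorts therefore demonstrate the pipeline's correctness and
calibration under its own assumptions, not the clinical performance of the
biomarkers on real patients.

## Numerical and reporting choices

- CSV dialect: comma-separated, UTF-8, header required, '.' decimals.
- Reported statistics are rounded to 2 decimals in reports; CSVs keep full
  precision.
- Clone signatures are tuples of state strings in subset order;
  proportions are sorted descending before index computation (order is
  immaterial to every index).
- Random streams: every stochastic routine takes an explicit seed;
  bootstrap replicate b uses `default_rng([seed, b])`.
- Problem sizes in the bundled runs: B = 200 bootstrap replicates,
  100 replicate cohorts for generator calibration, 400 for the null
  calibration of the Wald test, 20 repeated experiments for the
  informative-vs-null comparison — sizes at which the checked quantities'
  Monte-Carlo error is well inside the asserted bands.

## Known limitations

- The aneusomy surrogate uses the unweighted mean of three percentages;
  a cell-weighted pooling would differ for very unbalanced panels.
- The three-state clone definition merges amplification levels; analyses
  of high-level ERBB2 amplification would need a finer state map.
- The leave-one-out risk-score scale depends on training-fold centering;
  cut-offs are not transferable across cohorts without recalibration.
- No competing-risks treatment: death before progression is censored.
- The XLSX import path for legacy supplementary tables is out of scope;
  inputs are the documented CSV schemas.
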