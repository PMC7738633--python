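# Methods

## Growth model

Lesion volume is modeled with the Gompertz function
`X(t) = K·exp(ln(X0/K)·exp(−αt))`, a sigmoidal growth law whose specific
growth rate decays exponentially: growth is fastest early and decelerates
toward the carrying capacity `K`. Assumptions inherited by everything
downstream:

- the tumor is well approximated by a sphere whose diameter is the geometric
  mean of the long and short axes measured on contrast CT;
- the tumor originates from a single cell (10⁻⁶ mm³) and grows along one
  Gompertz trajectory (no dormancy, no multi-clonal origin);
- `K` is the same for all patients, fixed at 180,000 mm³ = 180 cm³, the
  volume of a 7-cm sphere — a host-level nutrient-limitation ceiling, not a
  fitted quantity;
- `X0` is the volume at the first scan and is taken from the data, so each
  patient contributes exactly one free parameter, α (month⁻¹).

α is estimated by Levenberg–Marquardt nonlinear least squares on the volume
scale (log-volume residuals are available via `fit_log_scale=True` but are
not the default, since the estimator is defined on tumor volume data).
Initialization is α₀ = 0.05 month⁻¹, between the two reported subtype means
(0.024 and 0.088 month⁻¹). The optimizer itself is unconstrained in the
single parameter; estimates outside the plausibility box (10⁻⁴, 2) month⁻¹
are clamped to the bound and flagged `converged=False`. This arises when the
measured volumes are non-increasing, which a Gompertz curve cannot
represent; such fits are reported, flagged, and excluded from nothing — the
flag is the signal. Observed volumes at or above `K` are a hard error
(`CarryingCapacityError`), and the pipeline excludes the patient with a
recorded reason.

Fit quality is the Pearson correlation between observed and fitted volumes,
pooled across all observations of a delta class (pooling, rather than
averaging per-patient correlations, weights patients by their number of
scans; with 2–6 scans per patient a per-patient correlation is too unstable
to average).

## Initiation time

The fitted curve is projected backward to the time needed to grow from a
single cell `Xs = 10⁻⁶ mm³` to a detectable mass `Xe = 10 mm³` (10⁷ cells):

```
T = |−(1/α)·ln(ln(Xs/K)/ln(X0/K))| − |−(1/α)·ln(ln(Xe/K)/ln(X0/K))|
```

Each term is the (signed) crossing time of the curve through `Xs` or `Xe`.
The absolute-value form is implemented literally; whenever `X0 > Xe` (always
true for radiologically visible lesions, which exceed 10 mm³) both crossings
lie in the past and the expression reduces to the `X0`-free closed form
`(1/α)·ln(ln(Xs/K)/ln(Xe/K))`, which the implementation evaluates as an
internal cross-check on every call. Note the algebraic cancellation requires
`X0 > Xe`, not merely `X0 < K`: below `Xe` the second absolute value flips
sign. `T` is exactly inversely proportional to α, so the cohort distribution
of `T` inherits the lognormal shape of α.

Cohort initiation times are summarized by a lognormal fit: μ and σ are the
mean and the maximum-likelihood (1/n) standard deviation of the log
initiation times (the unbiased 1/(n−1) variant is available via
`ddof=1`). The reported quantities are the mode `exp(μ − σ²)`, the median
`exp(μ)`, and quantiles/CDF values from `scipy.stats.lognorm`. A degenerate
sample (all values equal) yields σ = 0 with a flag instead of a density.

## Classification

The delta subtype is predicted from α alone. A univariate logistic
regression (unpenalized; perfect separation simply yields large
coefficients) provides the probabilistic model, but because the logistic
link is monotone in α, the ROC over predicted probabilities coincides with
the ROC over α: the implementation therefore builds the ROC staircase
directly on α. Candidate thresholds are the midpoints between consecutive
distinct sorted α values plus one sentinel below and above the observed
range (so "predict everything one class" is always a candidate). When two
adjacent floating-point values have a midpoint that rounds up to the upper
value, the lower value is used instead, preserving the strict `α > t`
prediction rule. AUC is the trapezoid area under the staircase and equals
the Mann–Whitney concordant-pair fraction (ties counted half), which the
tests verify by exhaustive pair counting.

The discrimination threshold maximizes classification accuracy over all
candidates; ties are broken by larger Youden's J (sensitivity + specificity
− 1), then by the smaller threshold. The positive class is high delta (the
faster-growing subtype). Confusion metrics include the Matthews correlation
coefficient, defined as 0 when any marginal count vanishes.

Leave-one-out cross-validation runs n folds: each drops one patient, refits
the classifier and threshold on the rest, and classifies the held-out
patient; the pooled held-out predictions form the cross-validated confusion
matrix. Per-fold AUCs (computed on the training fold) are summarized as
mean ± sd. A fold whose training set loses an entire class is excluded with
a warning — possible only when a class has a single member.

## Metabolic profile

Single-slice body-composition areas (cm², at L2–L3) convert to volumes as
area × slice thickness (cm³). The wasting rate per patient is the endpoint
estimator `100·(V_last − V_first)/(V_first·(t_last − t_first))` in % change
per month — one number per patient, scale-invariant in the volumes. An OLS
slope across all scans (as % of baseline per month) is available as
`method="regression"` for sensitivity analysis. Blood glucose is summarized
as the per-patient OLS slope of glucose on time restricted to the window
[−24, 0] months before diagnosis; patients with fewer than two in-window
readings are excluded with a warning. The choice of slope-then-compare for
the glucose "temporal profile" contrast is this package's design decision;
other summaries of a temporal profile are defensible.

Group contrasts use Welch's unequal-variance two-sample t-test (two-tailed).
A fully degenerate comparison (both groups constant) returns p = 1 when the
means agree and p = 0 with a `degenerate` flag otherwise.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with defaults set
to the study conditions:

- 26 low-delta and 29 high-delta patients;
- per-class lognormal α with arithmetic means 0.024 and 0.088 month⁻¹. The
  per-class log-sd is a free parameter (no cohort variance is published);
  the default 0.6 was chosen once so the two α distributions overlap
  (normal-theory AUC ≈ 0.94), exercising threshold selection and LOOCV away
  from the trivially separable regime;
- irregular scan schedules: 2–6 scans, inter-scan intervals ~N(7.5, 3²)
  months truncated at 1 month (the reported mean pre-diagnostic intervals
  are 7.3/8.3 months by subtype);
- `X0` uniform on 50–2,000 mm³; exact Gompertz volumes; multiplicative
  lognormal noise (CV 5%, mean 1) applied to each axis of the biaxial
  measurement, with the long/short axis ratio drawn uniformly on [1, 1.5].
  Noise is applied to diameters, where measurement error physically arises,
  not to volumes. Noisy measurements whose implied volume would reach `K`
  are truncated just below it with a warning;
- tissue series (SAF/VAF/muscle): linear relative decline at a per-patient
  rate ~N(class mean, 2.5²) %/month, class means (−1.1, −8.7) SAF,
  (−1.5, −10.2) VAF, (−0.4, −8.8) muscle (low, high), over 3–5 scans in the
  24 pre-diagnostic months, with 5% multiplicative noise. A linear decline
  at −8.7%/month exhausts the compartment before 24 months, so each
  patient's tissue window is capped so the final value stays ≥10% of
  baseline — the same truncation logic as the volume ceiling;
- blood glucose: per-patient slope ~N(0.1, 0.2²) (low) or N(1.5, 0.5²)
  (high) mg/dL/month on a ~100 mg/dL baseline with 5 mg/dL reading noise,
  4–8 readings in [−24, 0] months.

Ground truth (α, X0, tissue rates, BG slope per patient) is stored in
`cohort.metadata["truth"]` for loop-back tests. `null_cohort` draws both
classes' α from one pooled lognormal so labels are uninformative, for null
calibration of the classifier.

What the generator does **not** emulate: rater measurement disagreement,
non-Gompertz growth (dormancy, regression), missing or censored scans,
correlated noise between axes of the same scan, age/sex structure, and any
survival outcome. Passing tests therefore validate the estimators under the
stated model, not the clinical claims on real patients.

## Numerical choices and degenerate inputs

- Internal lesion volumes are mm³ (the initiation thresholds are stated in
  mm³); report-facing volumes cm³; time in months, dates converted at
  30.4375 days/month; per-patient time origin is the first scan.
- Duplicate rows sharing a scan timestamp are averaged (axes) with a logged
  warning.
- Pearson R of a constant-vs-constant exact fit is reported as 1.0 (perfect
  agreement) rather than NaN.
- CSV round-trips preserve full float precision (`repr` on write,
  `float_precision="round_trip"` on read).
- LOOCV is n-fold (one fold per patient), the standard construction.
- The pipeline report is deterministic: identical cohort and config give
  bit-identical JSON.

## Problem sizes used in validation

The test-suite simulations use 55–400 patients per scenario, 200–500
Monte-Carlo replicates for estimator-recovery checks, 10⁴ replicates for
the Welch type-I calibration, and 400 replicates for the power check at the
study's group sizes (26/29); the full pipeline on the default 55-patient
cohort completes in about a second on one CPU.

## Known limitations

- With 2-point trajectories α is exactly identified, so measurement noise
  propagates directly into the estimate; the per-patient fit flag and
  Pearson R do not protect against this at n_obs = 2.
- The endpoint wasting-rate estimator uses only two scans per patient by
  design; it is unbiased under linear decline but noisier than the
  regression variant when more scans exist.
- The α log-sd default is a modeling choice, not an estimate; conclusions
  about classifier accuracy on synthetic cohorts scale with it.
- Qualitative delta scoring, CT segmentation, inter-rater agreement, and
  survival analyses are out of scope.
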