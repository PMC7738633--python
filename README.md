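# pdac-growth

Growth-kinetics and metabolic-profile analysis of pancreatic ductal
adenocarcinoma (PDAC) in the pre-diagnostic period, for researchers studying
imaging-based PDAC subtypes on serial CT.

Patients who develop PDAC as a second primary cancer often have serial
follow-up CT scans that happen to capture the pancreatic lesion before it is
diagnosed. This package turns those serial biaxial lesion measurements into
per-patient growth-rate estimates, projects tumor initiation times backward
from the fitted curves, classifies the imaging subtype (high vs low "delta",
i.e. conspicuous vs inconspicuous tumor border) from growth rate alone, and
contrasts soft-tissue wasting and blood-glucose trends between subtypes.
Because no patient-level data are publicly deposited, a synthetic cohort
generator reproduces the statistical structure of such a cohort so that
every stage is testable end to end.

## Model

Tumor volume follows a Gompertz law

```
X(t) = K · exp( ln(X0/K) · exp(−α t) )
```

- `K` — carrying capacity, fixed at 180 cm³ (the volume of a 7-cm sphere):
  the maximum tumor volume the host can support;
- `X0` — volume at the first observation (anchored to the data, t = 0);
- `α` — growth-rate constant (month⁻¹), the single fitted parameter,
  estimated per patient by Levenberg–Marquardt nonlinear least squares on
  volumes derived from biaxial measurements (volume of a sphere with
  diameter √(long·short)).

The fitted curve is projected backward to the **initiation time** `T`: the
modeled time to grow from a single cell (10⁻⁶ mm³) to a detectable 10 mm³
mass (10⁷ cells),

```
T = |−(1/α) ln( ln(Xs/K) / ln(X0/K) )| − |−(1/α) ln( ln(Xe/K) / ln(X0/K) )|
```

with `Xs = 10⁻⁶ mm³`, `Xe = 10 mm³`. The interval is independent of `X0`
and equals `(1/α) · ln( ln(Xs/K) / ln(Xe/K) )`. Cohort initiation times are
characterized by a maximum-likelihood lognormal (μ, σ), with mode
`exp(μ − σ²)` and cumulative initiation probabilities from its CDF.

Classification of the subtype from α uses a univariate logistic regression;
since the link is monotone in α, the ROC, AUC, and accuracy-maximizing
discrimination threshold are computed directly on α and validated by
leave-one-out cross-validation. Soft-tissue wasting (subcutaneous fat,
visceral fat, muscle, from single-slice CT areas × slice thickness) is
summarized per patient as % change/month and compared between subtypes with
Welch's t-test, as are per-patient blood-glucose slopes over the 24 months
before diagnosis.

## Worked example

```python
from pdacgrowth import GeneratorConfig, generate_cohort, run_pipeline

cohort = generate_cohort(GeneratorConfig(seed=1))   # 26 low / 29 high delta
report = run_pipeline(cohort)

per = report.summary["per_class"]
clf = report.summary["classifier"]
print(f"low delta:  mean alpha {per['low']['mean_alpha']:.4f}/mo, "
      f"initiation mode {per['low']['mode_months']:.1f} mo")
print(f"high delta: mean alpha {per['high']['mean_alpha']:.4f}/mo, "
      f"initiation mode {per['high']['mode_months']:.1f} mo")
print(f"AUC {clf['auc']:.3f}, threshold {clf['threshold']:.4f}/mo, "
      f"LOOCV accuracy {clf['loocv']['pooled']['accuracy']:.2f}")
```

prints

```
low delta:  mean alpha 0.0228/mo, initiation mode 32.5 mo
high delta: mean alpha 0.0978/mo, initiation mode 7.7 mo
AUC 0.958, threshold 0.0373/mo, LOOCV accuracy 0.91
```

Low-delta tumors grow about four times more slowly than high-delta tumors
(characteristic times 1/α of ~44 vs ~10 months for this draw), so their most
probable initiation time lies years rather than months before the first
scan, and the growth-rate constant alone separates the two subtypes with an
AUC near 0.96 — the threshold of ~0.037 month⁻¹ plays the role of the
clinical discrimination cut-off.

The same analysis is available from the shell:

```
pdac-growth simulate --seed 1 --out-dir cohort/
pdac-growth run-all --in-dir cohort/ --out-dir results/ --plots
```

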