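# lrfusion

Likelihood-ratio evidence evaluation for two-class biomarker problems,
with logistic-regression methods that keep working when the classes are
**perfectly separated** — the regime where good markers break ordinary
maximum likelihood.

The package is aimed at forensic and clinical statisticians who need to
turn a panel of continuous measurements (think hair EtG/FAEEs plus blood
markers for chronic-alcohol assessment) into a calibrated likelihood
ratio `LR = P(E|H1)/P(E|H2)`, a verbal strength-of-support statement, and
an honest cross-validated comparison of candidate methods.

## What it implements

- **Exact separation diagnosis** (`detect_separation`): a linear program
  decides complete/quasi-separation and returns a witness direction —
  no reliance on the "huge standard errors" symptom, though that ratio is
  reported too.
- **Separation-robust fitters** (`fit_firth`, `fit_elastic_net` +
  `select_lambda_cv`, `fit_bayes_glm`): Jeffreys-prior (Firth)
  bias-reduced logistic regression; elastic-net penalized likelihood
  `max (1/N) l(β) − λ Σ[(1−α)βj²/2 + α|βj|]` by cyclical coordinate
  descent with soft-thresholding and cross-validated λ; Student-t
  (Cauchy) prior posterior modes via prior-augmented IWLS.  All three
  return finite coefficients on separated data.
- **Density-based LR scores** (`fit_density`, `score_log_lr`):
  per-variable scores `s = log f(x|H1)/f(x|H2)` from Gaussian fits or
  Gaussian-kernel KDE with Silverman's bandwidth
  `h = 0.9·min(σ̂, IQR/1.34)·n^(−1/5)`.
- **Score fusion** (`fit_fusion`, `predict_fusion`): the two-stage
  calibration `logit(p) = β*0 + Σ β*j s_j`, densities fitted on a training
  set, fusion weights on a disjoint validation set (leakage is an error,
  not a guideline).
- **Baselines and metrics**: LDA/QDA with density-ratio LR output;
  confusion-matrix measures; the log-likelihood-ratio cost
  `Cllr = ½[mean log2(1+1/LR₁) + mean log2(1+LR₂)]`; the ENFSI decade
  verbal scale.
- **A comparison harness** (`run_comparison`): repeated stratified
  50/40/10 train/validation/test splits (default 50 replicates) over a
  10-method grid, with per-method failure bookkeeping and bit-reproducible
  seeding.
- **A synthetic generator** (`generate_biomarker_like`): correlated,
  positively skewed lognormal marker panels with *controllable perfect
  separation*, so the whole pipeline is testable without any external
  dataset.

## Worked example

```python
import numpy as np
from lrfusion import (GeneratorConfig, generate_biomarker_like, detect_separation,
                      fit_logistic_mle, fit_firth, fit_fusion, predict_fusion)

panel = generate_biomarker_like(GeneratorConfig(seed=7))   # n=125, k=8
print(f"panel: n={panel.n}, k={panel.k}, positives={panel.n_positive}")

rep = detect_separation(panel)
print(f"separated: {rep.separated}  (witness variables: {rep.witness['variables']})")

mle = fit_logistic_mle(panel)
print(f"MLE converged: {mle.converged}, max SE/|coef| ratio: {np.nanmax(mle.se_coef_ratios()):.1e}")

firth = fit_firth(panel)
print(f"Firth converged: {firth.converged}, slope for marker1: "
      f"{firth.coefficients[1]:.3f} (SE {firth.std_errors[1]:.3f})")

idx = np.arange(panel.n)
train, val, test = panel.subset(idx[:62]), panel.subset(idx[62:112]), panel.subset(idx[112:])
model = fit_fusion(train, val, density_method="kde", fusion_method="elastic_net", seed=0)
for r, y in list(zip(predict_fusion(model, test.features), test.labels))[:3]:
    print(f"true={'positive' if y else 'negative':8s} log10(LR)={r.log10_lr:+7.2f}  {r.verbal}")
```

prints

```
panel: n=125, k=8, positives=58
separated: True  (witness variables: ['marker1', 'marker2'])
MLE converged: False, max SE/|coef| ratio: 6.9e+04
Firth converged: True, slope for marker1: 0.919 (SE 0.616)
true=positive log10(LR)=  +1.86  moderate support for H1
true=negative log10(LR)=  -3.33  strong support for H2
true=positive log10(LR)=  +2.77  moderately strong support for H1
```

Reading it: the two designated markers perfectly separate the classes, so
plain maximum likelihood cannot converge and its standard errors dwarf the
coefficients by four orders of magnitude — while the Firth fit lands on a
finite, interpretable slope.  The fused KDE scores then give each test
individual a calibrated LR: the first positive is about 70 times more
likely under H1 ("chronic") than H2, and the negative's measurements are
about 2000 times more likely under H2.

## Command line

Every stage is also a subcommand of the `lrfusion` console script:

```bash
lrfusion generate --out panel.csv --n 125 --seed 7
lrfusion classify panel.csv --method firth --out pred.csv
lrfusion scores panel.csv panel.csv --out scores.csv --density kde
lrfusion fuse train.csv val.csv --out fused.csv --fusion glmnet --density kde
lrfusion evaluate pred_with_truth.csv
lrfusion compare panel.csv --out summary.csv --n-cv 50 --seed 1
```

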