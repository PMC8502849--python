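# Methods

## Model

One record per administered sample: Cronbach's alpha αᵢ, respondent
count nᵢ, item count J of the form scored (a study reporting only
subscale alphas is coded as separate rows with distinct ids and the
subscale's J), and optional moderators. Alphas are carried through all
inference on the cube-root transformed scale Tᵢ = (1 − αᵢ)^(1/3), which
improves normality and stabilizes variance for internal-consistency
coefficients; the transform is strictly decreasing, so every report
states directions on both scales. Its large-sample sampling variance is

    vᵢ = 18 J (nᵢ − 1) (1 − αᵢ)^(2/3) / ((J − 1)(9 nᵢ − 11)²).

The working model is Tᵢ ~ N(xᵢ'β, vᵢ + τ²): an intercept-only design for
pooling, intercept plus one centered covariate for continuous-moderator
meta-regression, and intercept plus reference-cell dummies for
categorical subgroup models. The model assumes the vᵢ are known, the
random effects are normal, and the per-study alphas are independent.

## Estimation and inference

**τ² (REML).** The profiled restricted log-likelihood
−½[Σ ln(vᵢ+τ²) + ln det(X'WX) + Σ wᵢ rᵢ²], with W = diag(1/(vᵢ+τ²)) and
rᵢ the weighted-least-squares residuals at that τ², is maximized by
bounded scalar search on [0, 10·(max vᵢ + var T)] with relative
tolerance 1e−10 and an iteration cap of 200; the boundary τ² = 0 is
compared explicitly so homogeneous data return exactly zero. The search
is one-dimensional, deterministic, and directly checkable against a
grid + golden-section oracle (the test suite and acceptance script do
exactly that; agreement is ~1e−10, far inside the 1e−6 requirement).

**Pooling.** wᵢ = 1/(vᵢ + τ̂²), T₊ = Σwᵢ Tᵢ/Σwᵢ. The confidence interval
uses the unmodified Knapp–Hartung variance [Σwᵢ(Tᵢ−T₊)²/(k−1)]/Σwᵢ with
a t(k−1) reference; no truncation of the adjustment factor is applied.
With τ² = 0 and equal variances this collapses to the fixed-effect
inverse-variance mean, and with zero residuals the interval degenerates
to a point — both are asserted in tests. Alpha-scale intervals
back-transform the swapped T endpoints. Default level 95%, two-sided,
configurable.

**Heterogeneity.** Cochran's Q uses fixed-effect weights 1/vᵢ with
df = k − 1 and a chi-square upper tail. Two I² flavors are always
computed: the Q-based 100·max(0, (Q−df)/Q) and the τ²-based
100·τ̂²/(τ̂² + s²) with the Higgins–Thompson typical variance
s² = (k−1)Σw/((Σw)² − Σw²). They can differ by many points in small
heterogeneous collections (e.g. Q = 204.64 on 24 df gives 88.3% by the
Q formula while the τ²-based value can sit near 86%), so the headline
flavor is an explicit config choice; the τ²-based index — the one REML
software conventionally reports — is the default, and both always
appear in the report.

**Publication bias.** The classical Egger formulation: unweighted OLS
of the standardized effect Tᵢ/√vᵢ on precision 1/√vᵢ, testing the
intercept on k − 2 df. The classical version (rather than a weighted
variant) is used because its df bookkeeping matches the convention of
RG reports and it is exactly the "regtest(model='lm')" test of metafor,
against which the implementation is cross-checked. It requires variance
spread; equal variances raise a named error.

**Moderators.** Each moderator is analyzed in isolation on the studies
that report it (listwise deletion); τ² is re-estimated by REML within
every subset and never inherited from the full-set fit. Knapp–Hartung
scaling s²_KH = Σwᵢrᵢ²/(k−p) multiplies (X'WX)⁻¹; per-term t tests and
the omnibus F over the non-intercept terms use k − p denominator df
(so (1, k−2) for a simple regression, (m−1, k−m) for m groups).
Residual heterogeneity Q_E is the fixed-effect-weighted residual sum of
squares on k − p df. Explained variance is
R² = 100·max(0, (τ²₀ − τ²_res)/τ²₀), defined as 0 when τ²₀ = 0; REML can
legitimately estimate a *larger* τ² after adding a useless moderator,
and the truncation branch is exercised in tests. Categorical models use
reference-cell coding (largest group as reference, alphabetical
tie-break); because the printed per-level coefficients in published RG
tables are ambiguous between codings, each level's model-implied mean
(back-transformed, with CI) is reported alongside the contrasts. A
two-level factor reproduces the 0/1 meta-regression exactly. Singleton
levels and subsets below k = 8 proceed with logged warnings rather than
refusal; no multiple-testing correction is applied across moderators,
and the report footnotes the number of tests run. The Pearson follow-up
deliberately correlates *raw* alpha with the moderator, so its sign is
directly interpretable (and opposite to the T-scale slope).

## Synthetic data

The study-level generator draws Nᵢ uniformly over a configurable range,
moderators from fixed distributions chosen to resemble caregiver
samples (predominantly female staff, mean ages near 44 ± 8, publication
years 2007–2021, mostly validated translations in geriatric settings),
true effects θᵢ = T(μ_α) + Σβ_m(x_im − x̄_m) + uᵢ with uᵢ ~ N(0, τ²), and
observed Tᵢ ~ N(θᵢ, vᵢ) with vᵢ evaluated at the back-transformed θᵢ.
It simulates on the T scale directly — the same model the estimators
assume — which makes it a *calibration* instrument, not evidence about
real data: passing calibration shows the estimators are correct under
their own assumptions, not that real alphas follow the model. Observed
alphas leaving (0, 1) are clipped to (0.001, 0.999) with a logged
count; shipped test configurations keep clipping far below 1% of draws.
Configurations whose *true* effects leave the domain (alpha ≥ 1, where
the variance formula is undefined) raise instead.

The item-level generator exists to break that circularity at the one
point where it can be broken cheaply: it draws n × J response matrices
from a compound-symmetric latent normal (common inter-item correlation
ρ, population alpha Jρ/(1 + (J−1)ρ)), optionally discretized to a 1–5
Likert scale at equal-probability thresholds (which biases alpha
slightly downward; the continuous path is the default for calibration
claims). The empirical variance of transformed sample alphas from 5000
such datasets at n = 500, J = 13, α = 0.8125 agrees with the
Hakstian–Whalen formula to ~2%, against a 15% acceptance bound, and a
grid over J ∈ {5, 13}, n ∈ {100, 500}, α ≈ 0.56–0.91 stays inside 15%.

**The 25-sample fixture** is a deterministic construction, not a draw:
25 planted effects are scaled normal quantiles on the T scale, study
sizes are one dominant sample (12,500) plus a geometric tail summing to
15,149, and the residual scale is solved by Brent's method through the
actual pipeline so the τ²-based I² equals 86%. The effect-to-study
assignment uses restricted randomization (re-drawn until planted
effects are uncorrelated with precision and with size rank), and
category labels are spread evenly across the effect distribution, so
the only association built in is a positive T-scale age slope (negative
age–reliability correlation, Pearson r ≈ −0.6 on the 21 studies
reporting age). Per-moderator availability is fixed at
25/22/22/21/17/5/4 (year, women, men, age mean, age SD, score mean,
score SD). The dominant-plus-tail size profile is an assumption — it is
what makes a wide pooled interval coexist with a large total N — and is
declared, with everything else, in the fixture's provenance note; the
fixture demonstrates that the pipeline can express a published result
pattern, not that it reproduces any study's data.

## Numerical and design notes

* Q's degrees of freedom are k − 1 throughout; published tables that
  index Q by the number of samples are read as such.
* The dependent variable of every model fit is T, even where narrative
  conventions speak of "alpha as the dependent variable"; mixing scales
  within one analysis would invalidate the weights.
* Back-transformation clamps T at 0 (alpha = 1) before cubing, so
  extreme lower interval endpoints cannot leave the alpha scale.
* `alpha ≤ 0` inputs are rejected at ingest: theoretically possible,
  but outside the variance formula's domain.
* CSV dialect: UTF-8, comma-separated, header row, empty cell =
  missing; category labels trimmed and matched case-insensitively.
* Monte-Carlo problem sizes (2000 replicates for calibration and
  coverage, 5000 item-level datasets for the variance check, 500/300
  replicates for recovery) were chosen so binomial/MC standard errors
  are several times smaller than the acceptance bands they feed.

## Limitations

* The Hakstian–Whalen variance assumes essentially tau-equivalent,
  normal items; for short scales at small n it is only approximate
  (still inside 15% on the tested grid, but coverage of per-study
  intervals dips toward 94%).
* The Egger test is calibrated under homogeneity; under strong
  heterogeneity the classical version is known to be conservative or
  liberal depending on the variance-size relation. No selection-model
  or trim-and-fill follow-up is provided.
* Moderator analyses are simple (one moderator at a time, no
  interactions, no multivariable models), matching standard RG reports.
* The generators do not simulate the literature-selection process,
  publication-bias mechanisms, or multidimensional subscale structure.
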