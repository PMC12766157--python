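# Methods

`mrisk` estimates the long-term risk of metastatic recurrence (MR) for
women diagnosed with early-stage (I–III) breast cancer, using only the
survival information that population cancer registries routinely hold —
no recurrence registration is required. This note documents the model, the
numerical choices, the synthetic-data generator that stands in for
confidential registry listings, and what the tests do and do not show.

## The model

The method treats the disease course as a diagnosis → metastasis → cancer
death pathway and combines three ingredients.

**1. Relative survival.** For each stratum (stage, optionally stage ×
molecular profile, with age group and diagnosis period as covariates) a
grouped actuarial life table is built on annual intervals: with `n_i`
at risk, `d_i` deaths and `w_i` withdrawals in interval `i`, the effective
denominator is `n'_i = n_i − w_i/2` and observed interval survival
`p_i = 1 − d_i/n'_i`. Expected interval survival `p*_i` is the Ederer II
estimator: the mean, over the subjects still at risk at the interval
start, of each subject's own probability of surviving the interval under
general-population mortality, taken from a rate table of annual death
probabilities `q(age, sex, year)` converted to monthly probabilities
`1 − (1−q)^{1/12}` with age and calendar year advanced month by month.
Interval relative survival is `r_i = p_i / p*_i` and cumulative relative
survival `RS_k = Π r_i`; it estimates net (cancer-only) survival and may
exceed 1. Standard errors are Greenwood-type, on the observed component
only, with the expected survival treated as fixed — the registry
convention.

**2. Mixture cure model.** Relative survival is modelled as

    RS(t) = c + (1 − c) · S_u(t)

with cure fraction `c` (no excess mortality) and non-cured survival `S_u`,
Weibull `exp(−(λt)^γ)` or log-logistic `1/(1 + (λt)^γ)`. `S_u` is the
survival of `T*`, the time from diagnosis to cancer death of the
non-cured. The model is fitted at life-table resolution by a grouped
binomial likelihood: interval deaths `d_i ~ Binomial(n'_i, 1 − p*_i ·
RS(t_i)/RS(t_{i−1}))`. Covariates (age group, period) enter `c` through a
logit link and `λ` through a log link; the shape `γ` is shared within a
stratum, which keeps the model identifiable from 15 annual intervals.
Log-logistic is preferred when it converges in every stratum of a table;
one non-convergent stratum triggers a table-wide Weibull fall-back, and
exact ties break toward Weibull.

**3. Recurrence extraction.** For the non-cured, `T* = T₁ + T₂`: time to
metastatic recurrence plus time from recurrence to cancer death, assumed
independent. Post-recurrence survival is tied to de-novo stage-IV net
survival through a cause-specific mortality hazard ratio `r`:

    S₂(t) = S_IV(t)^r ,   r = 1/0.75 = 1.33 by default,

reflecting the poorer prognosis of metachronous recurrence relative to a
de-novo metastatic diagnosis. `S_IV` is the cure-model-smoothed stage-IV
relative-survival curve (the smoothing is what allows evaluation out to
15 years), and `r` is applied to the whole curve, including any fitted
plateau. Given `S*` (= fitted `S_u`) and `S₂`, the recurrence-free
survival `S₁` of the non-cured solves the renewal identity

    S*(t_k) = S₁(t_k) + Σ_{j≤k} [S₁(t_{j−1}) − S₁(t_j)] · S₂(t_k − t_{j−½})

on a monthly grid, with `S₂` evaluated at interval midpoints. The outputs
are, per stratum:

* cumulative MR risk `P(t) = (1 − c)(1 − S₁(t))`, reported at 5/10/15 years,
* recurrence-free probability `c + (1 − c)·S₁(t)`,
* conditional MR risk `q(a,b) = [P(b) − P(a)] / [1 − P(a)]` on the
  contiguous intervals 0–5, 5–10, 10–15 years, whose inverse is
  `P = 1 − Π(1 − q_j)`,
* a sensitivity table over `r ∈ {1.00, 1.33, 1.50, 1.70}`.

All risks are *net* quantities: competing (other-cause) mortality is
removed, which overstates absolute risk, increasingly so at older ages.
Larger `r` shortens `T₂`, hence lengthens the implied `T₁` and lowers the
early cumulative risk; the spread across `r` shrinks as the horizon grows.

## Numerical choices

* **Deconvolution.** Writing `d_j ≥ 0` for the `T₁` probability mass in
  interval `j`, the renewal identity is the lower-triangular system
  `Σ_{j≤k} d_j [1 − S₂(t_k − t_{j−½})] = 1 − S*(t_k)`. Naive forward
  substitution is catastrophically unstable here: the diagonal
  `1 − S₂(h/2)` can be ~10⁻⁴ when `S₂` is flat near zero (log-logistic
  shapes ≳ 1.2), and roundoff is amplified exponentially. The system is
  therefore solved by nonnegative least squares (`scipy.optimize.nnls`);
  the sign constraint regularises the solution and makes
  `S₁ = 1 − cumsum(d)` monotone by construction. Quality is measured by
  the sup-norm of the re-convolution residual; a residual above 0.02
  flags the stratum as unstable. Against independent fine-grid
  convolution oracles the solver recovers `S₁` within ~3·10⁻³, and the
  closed-form hypoexponential case to machine precision.
* **Grids.** Monthly grid to 180 months for all T-domain work; the
  stage-IV curve is evaluated on a half-month grid so midpoint values of
  `S₂` are exact rather than interpolated.
* **Optimisation.** Cure likelihoods are multimodal, so fitting restarts
  from 10 stratified initial values over logit c ∈ [−2, 3], median T* ∈
  [6, 120] months, γ ∈ [0.5, 2] (Nelder–Mead polish then BFGS);
  convergence tolerance 10⁻⁸ on the objective. Fits with |logit ĉ| > 6
  are flagged as boundary (e.g. stage IV, where ĉ → 0, or a stratum with
  no excess mortality, ĉ → 1).
* **Dates.** Month resolution throughout; survival is completed months,
  which makes the "zero months of survival" exclusion exact. Attained age
  advances at an unobserved birthday placed 6 months after diagnosis by
  default (`birthday_offset`); the simulator uses the identical
  convention, so expected survival cancels exactly in null checks.
* **Eligibility order.** Age bound (> 74 at diagnosis) → missing stage →
  death-certificate-only/autopsy registration → zero-month survival, each
  record tallied under the first rule it violates, so tallies are
  reproducible and the filter is idempotent.
* **Rate-table gaps** are filled by nearest-year carry-forward (logged),
  and ages beyond the table use the terminal row — deliberately simple
  and conservative.
* **Reporting.** Probabilities are fractions internally; percentages are
  rendered only at the reporting boundary, rounded half-up to one
  decimal.

## The synthetic registry

Registry case listings of this kind are confidential, so the generator in
`mrisk.synthetic_registry` emulates one with known ground truth. Defaults
mirror the study conditions: accrual 1997–2017 with administrative
censoring in December 2018; stage mix 51.1 / 34.0 / 11.5 / 3.4 % (I–IV);
four age bands (15–44, 45–54, 55–64, 65–74) with mix 14.0 / 26.3 / 28.8 /
30.9 %; profile mix 76.1 / 15.7 / 8.2 % (HR+/HER2−, HER2+, TN); stage-IV
net survival Weibull with median 30 months (metastatic breast cancer
median survival is 2–3 years); `r = 1.33`; per-stage cure fractions 0.95 /
0.82 / 0.55 and recurrence-time medians 60 / 48 / 36 months, chosen so
15-year risks land near the reported 3 / 16 / 43 % by stage. Other-cause
death is drawn month by month from a Gompertz rate table (log q linear in
age, ≈ 8·10⁻⁴ at age 40, ≈ 10⁻² at 70 — roughly Western-European female
levels). `T₂` is drawn from `S_IV^r` by inverse transform on a monthly
grid with within-interval uniform refinement; mass beyond the grid (under
a survival plateau) is returned as "beyond horizon" rather than
truncated. A degenerate instant-death `T₂` law lets tests build cohorts
whose `T*` is exactly Weibull.

What the generator does **not** emulate: local/regional recurrence,
treatment effects, screening dynamics, frailty linking `T₁` and `T₂`
(independence is the model's own assumption), registry data-quality
artefacts (late registrations, stage migration, profile missingness
patterns). Passing tests therefore show that the estimator chain recovers
the truth *under the model's assumptions* at registry-scale n — not that
those assumptions hold in any particular real registry.

## Problem sizes used in the checks

The self-checks run at sizes where Monte-Carlo noise is well below the
tolerances while keeping runs in minutes on one CPU: cure-fraction
recovery at n = 50,000 per stratum (ĉ within ±0.02 over 10 replicates),
end-to-end risk recovery at n = 200,000 (P(5/10/15y) within ±1.5
percentage points of the generating `(1−c)F₁(t)`), the Ederer II null at
n = 50,000 (15-year RS confidence interval covering 1), and deconvolution
oracles on 181-point monthly grids.

## Known limitations

* The end-to-end estimate carries a small systematic bias (≈ 1 pp at 15
  years in the checks) because the convolution `T₁ + T₂` is not exactly
  Weibull or log-logistic; the parametric smoothing of `S*` is the price
  of extrapolating beyond the data.
* No confidence intervals are produced for `P(t)`; the uncertainty of the
  deconvolution step is summarised only by the re-convolution residual.
* Conditional risks live in the net world (no competing mortality); they
  are not real-world probabilities for an individual woman, particularly
  at ages where other-cause mortality is substantial.
* De-novo stage-IV survival may or may not contain a cured fraction; the
  simulator exposes this as a configurable plateau rather than asserting
  either way, and `r` is applied to whatever the stage-IV fit produces.
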