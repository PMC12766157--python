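# mrisk

Long-term **metastatic recurrence (MR) risk** for women with early-stage
breast cancer, estimated from the survival data that population cancer
registries already collect. Registries rarely register recurrences —
following up intermediate outcomes is resource-intensive — yet clinicians,
patients and advocacy groups need to know the probability of progressing
to metastatic disease 5, 10 or 15 years after diagnosis, and how that
probability falls for women who are still recurrence-free years later.

`mrisk` implements the three-step registry method end to end:

1. **Relative survival** — grouped actuarial life tables per stratum with
   Ederer II expected survival from a population rate table:
   `RS_k = Π p_i / p*_i`.
2. **Mixture cure model** — fitted to relative survival,
   `RS(t) = c + (1−c)·S_u(t)` (Weibull or log-logistic `S_u`), giving the
   cured fraction `c` and the survival `S_u` of `T*`, the time to cancer
   death of the non-cured, with age group and period as covariates and
   stage as the stratification variable.
3. **Recurrence extraction** — `T* = T₁ + T₂` with `T₁` the time to MR and
   `T₂` the time from MR to cancer death. Post-recurrence survival is
   stage-IV net survival powered by a mortality hazard ratio,
   `S₂(t) = S_IV(t)^r` (default `r = 1/0.75 = 1.33`); a numerical
   deconvolution then recovers `S₁` from `S*` and `S₂`, yielding the
   cumulative risk `P(t) = (1−c)(1−S₁(t))` and conditional risks
   `[P(b)−P(a)]/[1−P(a)]` for 5-year intervals, plus a sensitivity
   analysis over `r ∈ {1.00, 1.33, 1.50, 1.70}`.

Because real case listings are confidential, the package ships a
**synthetic registry generator** (`mrisk.synthetic_registry`) that draws
cohorts from the diagnosis–metastasis–death process with known ground
truth — cure fractions, `T₁` law, `S_IV` and `r` — so the whole chain is
testable. All risks are *net* of competing mortality: they answer "what
would the recurrence risk be in the absence of death from other causes".

## Worked example

A YAML config drives both the simulator and the estimation run:

```yaml
# config.yaml
seed: 3
case_listing: cohort.csv
rate_table: rate_table.csv
cure_family: auto          # prefer log-logistic, fall back to Weibull
r_default: 1.33
covariates: [age_group]
age_bands: [[15, 54], [55, 74]]
periods: [[2003, 2012]]
stages: [I, II, III]
simulate:
  n_subjects: 60000
  seed: 3
  accrual_years: [2003, 2012]
  strata:
    - {stage: I,   proportion: 0.511, cure_fraction: 0.95, t1_law: {family: weibull, median: 60, shape: 1.2}}
    - {stage: II,  proportion: 0.340, cure_fraction: 0.82, t1_law: {family: weibull, median: 48, shape: 1.2}}
    - {stage: III, proportion: 0.115, cure_fraction: 0.55, t1_law: {family: weibull, median: 36, shape: 1.2}}
    - {stage: IV,  proportion: 0.034}
  s4_law: {family: weibull, median: 30, shape: 1.1}
  r: 1.33
```

```sh
mrisk simulate --config config.yaml --outdir .
mrisk run --config config.yaml --outdir out
cat out/report.txt
```

which prints (abridged):

```
Metastatic recurrence risk (net of other-cause mortality)
============================================================

stratum                                5y    10y    15y   q0-5  q5-10  q10-15
I|age_group=15-54                     2.4    4.0    4.7    2.4    1.6     0.8
I|age_group=55-74                     1.8    3.5    4.6    1.8    1.8     1.1
II|age_group=15-54                   11.7   16.2   17.8   11.7    5.1     1.9
II|age_group=55-74                   10.1   15.4   17.5   10.1    5.9     2.6
III|age_group=15-54                  32.5   43.5   47.2   32.5   16.3     6.5
III|age_group=55-74                  32.3   43.7   47.5   32.3   16.8     6.8
```

Reading row three: of women diagnosed with stage II cancer at ages 15–54,
11.7 % are predicted to develop a metastatic recurrence within 5 years and
17.8 % within 15 years (in the absence of other-cause death); a woman
still recurrence-free at 10 years faces only a 1.9 % risk in the next five
— close to the generating truth ((1−0.82)·F₁(t) with median 48 months).
Conditional risks compose back to the cumulative:
`1 − (1−0.117)(1−0.051)(1−0.019) = 0.178`. The full run also writes life
tables, the fit summary, monthly risk curves, the r-sensitivity table and
a `manifest.json` recording warnings (non-convergence, boundary cure
fractions, deconvolution residuals); `mrisk run` exits 0 only when every
stratum is ok. The same algebra is available programmatically:

```python
>>> from mrisk import compose_cumulative
>>> round(100 * compose_cumulative([0.070, 0.040, 0.018]), 1)  # 0–5, 5–10, 10–15y
12.3
```

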