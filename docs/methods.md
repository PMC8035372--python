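# Methods

## Rates and conventions

All tables live on 1×1 age–period Lexis squares with ages as completed
years, matching the conventions of the Human Fertility Database family of
resources. Female reproductive ages are 15–49; male ages are 15–59 (male
fertility above 59 is negligible in high-income register data, and male
rates above 45 already decline to very low levels). An age-specific
fertility rate is births attributed to a sex/age/year divided by that
group's person-years of exposure; births with zero matching exposure are an
error, zero births with zero exposure yield rate 0.

* **TFR** sums a year's single-age rates over the sex's full support.
* **CFR** sums rates along the cohort diagonal — rate at age *x* taken from
  the period schedule of year *cohort + x* — over ages 15–50 inclusive.
  Cohorts missing any required year are refused with the list of missing
  years rather than silently truncated.
* **MAC** is the rate-weighted mean of *age + ½*. The midpoint convention
  is the standard choice for rates on Lexis squares; in male-minus-female
  MAC *differences*, the headline tempo measure here, the half-year offsets
  cancel, so the choice is immaterial for the comparisons.

## Conditional imputation of missing paternal ages

Within one calendar year, let `K(m, p)` be births with maternal age *m* and
known paternal age *p*, and `U(m)` the unknown-father births at *m*. The
conditional approach allocates `U(m) · K(m, p) / Σ_p K(m, p)` to cell
`(m, p)`. Allocation is deterministic and fractional — the expected-count
allocation, not a stochastic single-birth assignment — and conserves yearly
totals exactly. Imputation never borrows across years; the mother's age is
an excellent predictor of the father's age, which is exactly the
information the marginal (unconditional) comparator throws away.

Design choices where the procedure is underdetermined:

* **Sparse cells.** A maternal age with unknown-father births but no
  known-father births borrows from a symmetric widening window over
  maternal ages (±1, ±2, … up to ±5); the first non-empty window wins, and
  the final fallback is the year's marginal father distribution. Widening
  preserves the conditional logic as closely as the data allow.
* **Unknown maternal age.** Births with both ages unknown are spread over
  the year's known joint (m, p) distribution, conserving both margins;
  births with an unknown mother but a known father are kept as-is — they
  still carry valid information for male rates.
* A year with no known-father births at all is a hard error: no conditional
  or marginal distribution exists.

Under missingness that depends only on the maternal age (MAR), the
known-father conditional distribution is unbiased for the true one, so in
expectation mode conditional imputation reproduces the complete-data male
schedule to machine precision; the unconditional comparator is biased
whenever the father distribution varies with the mother's age and
missingness is non-uniform.

## PCLM ungrouping

Grouped counts (5-year or open-ended intervals) are ungrouped with the
penalized composite link model: observed interval counts are Poisson with
mean `C γ`, where `C` is the 0/1 composition matrix and `γ = exp(β)` the
latent single-age counts; the penalty `λ‖D₂β‖²` (squared second differences
of `log γ`) enforces smoothness. Estimation is penalized IRLS (Fisher
scoring with step-halving), converged when the penalized score's largest
component falls below 1e-8 relative to the total count, capped at 200
iterations. `λ = "auto"` minimizes `AIC = deviance + 2·ED` over a 25-point
log grid on [1e-2, 1e5], with `ED = tr[(XᵀWX + λP)⁻¹ XᵀWX]` the effective
dimension. An open-ended final interval is extended internally to the top
of the requested grid. Fitted counts are non-negative by construction and
match the observed total within 0.1%.

**Accuracy in practice.** With few intervals (e.g. seven covering ages
15–49) the model can reproduce the interval counts exactly for any small
λ, so the AIC selects, in effect, the smoothest near-exact interpolant.
On a noiseless round trip of the built-in gamma-shaped schedule grouped to
5-year + open-ended intervals, that interpolant's mean absolute error is
about 5% of the mean cell (concentrated on the steep left flank, ages
18–25); the error-minimizing λ on that example reaches ~1.8% but no
information criterion computed from the grouped data selects it. Users
should treat single-age detail reconstructed from 5-year groups as smooth
interpolation, reliable for totals and broad shape, not for cell-level
precision. Round-trip error decreases with narrower intervals.

## Other data-preparation steps

* **Youngest-age bins** ("age ≤ 17"): allocated over the constituent single
  ages proportionally to an externally supplied reference distribution
  (e.g. pooled shares of other populations); exact conservation.
* **End-of-year age classification**: a count at age-attained *x* is split
  between age-at-birth *x* (weight *w*) and *x−1* (weight *1−w*). With
  birthdays and within-year birth timing both uniform, the correct weight
  is ½, the default; *w* is exposed as a parameter because registers with
  seasonal birth patterns may warrant other splits.

## Same-age counterfactual

Paternal ages are erased and every father is assigned the mother's age;
counterfactual male rates divide those births by observed male exposures at
ages 15–49 (no counterfactual father can be 50+, so the male schedule is
zero there). The counterfactual ratio divides the counterfactual male TFR
by the observed female TFR, and is invariant to any permutation of paternal
ages in the input. The departure of the observed ratio from 1 splits
additively and exactly into: observed − counterfactual (parental age gaps
interacting with cohort-size variation, plus differential timing),
counterfactual − reference (labelled *mortality/migration + residual*,
since sex-selective survival and migration can offset each other and the
attribution is exact only in their absence), and reference − 1 with
reference = 100/SRB.

## Synthetic scenario generator

The generator is female-dominant: female rates drive births and fathers are
assigned through an age-gap distribution, mirroring how male rates are
derived from registers in practice and keeping ground truth analytic.

* **Female schedule**: gamma-shaped density on ages 15–49 matched by
  moments to a mean age (default 29, drifting by a configurable
  postponement rate in years/year) and spread (default 4.5 years), scaled
  to a target TFR (default 1.8) — values typical of recent high-income
  populations.
* **Age gap**: Gaussian discretized on integers −10..+25, truncated to keep
  paternal ages in 15–59 and renormalized; default mean 3, sd 2 years
  (fathers in high-income countries average 2–4 years older than mothers).
  The mean may drift per calendar year and may depend linearly on the
  mother's age (anchored at age 30), which makes the father-age
  distribution genuinely conditional on maternal age.
* **Exposures**: cohort size × sex share (women 1, men SRB/100, default
  SRB 105) × optional per-sex survival factor; cohort-size maps express
  boom/bust transitions.
* **Missingness**: MCAR (constant), MAR (logistic in maternal age) or MNAR
  (logistic in paternal age), parameterized by the rate at parental age 30
  and a log-odds slope per year of age.
* **Noise**: expectation mode (cell counts are exact expectations) is the
  default and is what deterministic recovery statements refer to; Poisson
  mode draws cell counts and applies binomial thinning for missingness so
  pre-imputation counts remain integers. One scenario seed feeds every
  stochastic stage through per-stage spawn keys, so identical seeds give
  bit-identical tables.

What the generator does **not** emulate: correlation between parental ages
beyond the additive (possibly age-trending) gap, parity, multiple births,
within-year timing, migration flows as events (only net exposure factors),
or register-specific recording artefacts. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated mechanisms, not
robustness to every real-register pathology.

Problem sizes in the shipped tests are chosen for fast, deterministic
arithmetic: expectation-mode scenarios of one to three years for recovery
checks, a 52-year stationary scenario for cohort/period comparisons, and a
200,000-birth schedule for ungrouping round trips.

The stationarity check (CFR ratio = TFR ratio) is run on a scenario with a
degenerate +2-year gap and a schedule putting <1e-9 of its mass above
maternal age 48, because the identity only holds when no male fertility
falls above the CFR truncation age of 50; with wider gaps the male TFR
(ages to 59) genuinely exceeds the male CFR (ages to 50).

## Known limitations

* The PCLM is 1-D (age); no age × year smoothing.
* No tempo-adjusted (Bongaarts–Feeney) rates, no parity-specific measures,
  and no variance of the parental age gap — none of these are derivable
  from the ASFR outputs alone.
* The end-of-year conversion weight of ½ is a neutral stand-in for
  register-specific interpolation protocols, not a claim about any
  particular country's data.
* No structural two-sex model: the counterfactual reassigns ages, it does
  not model partner matching.
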