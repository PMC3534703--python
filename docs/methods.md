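# Methods

## The attributable-fraction model

For a population cell (race × age band × sex) and a cause of death, the
alcohol-attributable fraction (AAF) is the share of deaths that would not
occur under a counterfactual of universal lifetime abstention.  Exposure in
a cell is described by three mutually exclusive drinking statuses —
lifetime abstainer, former drinker, current drinker — and, among current
drinkers, by a continuous distribution of average daily ethanol intake
x (g/day).  With a dose–response relative risk RR(x) normalized to
RR(0) = 1, a former-drinker relative risk RR_f, and drinker density f(x):

    N   = P_former·(RR_f − 1) + P_current·∫₀ᶜ f(x)·(RR(x) − 1) dx
    AAF = N / (N + 1)

N is a signed excess-risk mass, so the AAF is signed: where RR < 1 over the
bulk of the density (moderate drinking and ischemic disease, diabetes) the
cell's AAF is negative and subtracts deaths from the net burden.  AAF ≤ 1
always; AAF = 1 only for causes whose ICD definitions name alcohol
(`wholly_attributable`).

Four method variants handle causes where the plain chronic integral is
wrong:

* **ihd** — current drinkers are split by binge status (any 5+-drink
  occasions).  Non-binge drinkers follow the protective dose–response;
  binge drinkers follow a detrimental curve floored at RR ≥ 1, encoding the
  finding that heavy episodic drinking abolishes cardioprotection.  The
  floor (rather than the raw detrimental curve) is a deliberate guard: a
  misconfigured curve can never re-introduce protection for bingers.
* **injury** — a finite-cell categorical approximation: drinkers are
  partitioned into (volume category × binge status) cells using the gamma
  category masses and the binge split, each cell carries a configured RR,
  and AAF = Σpᵢ(RRᵢ−1) / (Σpᵢ(RRᵢ−1) + 1).  A continuous occasion-level
  formulation (per-occasion risk integrated over the blood-alcohol time
  course) could replace this without interface changes; the cells are
  config-driven.
* **hiv** — only the pathway through antiretroviral-therapy nonadherence is
  modelled: drinkers above a daily-volume threshold (default 48 g/day)
  carry a single nonadherence RR; everyone else RR = 1.
* **wholly_attributable** — AAF ≡ 1; a zero-exposure profile with such a
  cause logs a warning (inconsistent inputs) but still returns 1.

## Exposure model and undercoverage correction

Drinker intake is gamma with mean μ and SD σ = k·μ; k defaults to 1.171
(men) and 1.258 (women), the values used in the triangulation literature
for linking survey means to consumption distributions.  Equivalently,
shape = 1/k² (≈ 0.73 for men: strongly right-skewed) and scale = μ·k².  The
density is truncated and renormalized on (0, C] with C = 150 g/day by
default; the cap bounds the influence of the gamma tail on risk integrals
and is configurable.  Renormalizing (rather than lumping the tail mass at
C) was a deliberate choice: it keeps the density proper and the category
masses additive; the alternative is a one-line change in `interval_mass`.

Surveys under-capture consumption relative to sales-based per-capita data.
The survey-implied adult per-capita consumption is the population-weighted
mean of P_current·μ over strata, converted with 789.24 g ethanol/L and 365
days/year; its ratio to the recorded+unrecorded reference (liters/year) is
the coverage rate.  The correction multiplies every stratum's drinker mean
by the single factor target·reference/implied (target 0.80 by default,
`None` disables it for sensitivity analysis) and refits the gamma.  A
uniform factor preserves relative differences between strata; nothing in
the inputs identifies stratum-specific undercoverage, so a uniform shift is
the parsimonious choice.  Binge quantities are not upshifted by default —
the correction targets average volume, and occasion counts are not volume —
though the profiles carry the binge fields unchanged so a caller can shift
them explicitly.  The untruncated mean enters the per-capita accounting
(volume bookkeeping against sales data), while the truncated density enters
risk integration.

## Burden arithmetic

Attributable deaths per (stratum, cause) cell are AAF × deaths, kept signed
and unrounded internally.  PYLL per death uses the remaining life
expectancy L of the (sex, age band) cell discounted at a continuous
r = 3%/year: (1 − e^(−rL))/r, which is < L for r > 0 and → L as r → 0.  A
discrete-annual variant ((1 − (1+r)^(−L))/r) is available by flag.  Life
expectancy is looked up per band; the synthetic life table evaluates its
linear decline at the band midpoint.  Aggregation sums cells and recomputes
percentages from summed numerators and denominators — percentages are never
averaged.  Published-style rounding (deaths to integers, PYLL to the
nearest 10) is applied only at the rendering step.  Directly standardized
rates weight stratum-specific rates (counts/population by age × sex) by a
fixed standard population's structure, per 100,000.

## Numerical choices

Risk integrals are computed in probability space: substituting u = F(x)/F(C)
turns ∫₀ᶜ f(x)(RR(x)−1) dx into ∫₀¹ (RR(Q(u·F(C))) − 1) du with Q the gamma
quantile function.  The integrand is bounded even though the gamma density
diverges at 0 for shape < 1.  Adaptive quadrature runs at absolute
tolerance 1e−8; every result is cross-checked against a 10⁴-point
midpoint rule, and disagreement beyond 1e−4 raises a diagnostic error
rather than returning silently.  Quantile grids are cached per density.
Constant-form RR functions return their value for x > 0 and 1 at x = 0,
reconciling the RR(0) = 1 anchor with closed-form constant-RR tests (the
drinker density has no mass at 0, so the anchor never enters an integral).

## The synthetic-data generator

The generator emulates: stratified trinomial drinking status, gamma intake
with the σ = k·μ rule, Bernoulli binge status among drinkers with
zero-truncated Poisson occasions/year (zero-truncated because the microdata
schema identifies bingers by occasions > 0; an untruncated Poisson would
bias the recoverable binge prevalence downward), unit survey weights by
default with an optional lognormal-weight switch to exercise the weighted
estimators, and mortality counts with planted AAFs via
count = baseline/(1 − AAF).

Default conditions: all 40 strata (4 races × 5 ten-year age bands 15–64 ×
2 sexes); lifetime-abstainer and former-drinker prevalences per stratum
taken from the packaged published consumption-indicator table; drinker
means of 18–26 g/day for men and 8–13 g/day for women declining with age
(chosen so that, with ~55–70% current drinkers, the survey-implied
per-capita lands near the ~50–60% coverage regime typical of consumption
surveys against a 9.5 L/year reference); binge prevalence 0.35 (men) /
0.15 (women) with 26 / 12 occasions/year; populations proportioned
roughly like the 2005 US race structure.  The synthetic life table declines
linearly from 76 (men) / 81 (women) years at age ~0 by 0.9 years per year
of age — monotone and sex-ordered, not an official life table.

What the generator does **not** emulate: multistage/oversampled survey
designs and design-consistent variance, item nonresponse, beverage-specific
quantity–frequency instruments, within-person longitudinal drinking
history, and any real correlation between consumption and cause-specific
baseline mortality.  Passing recovery tests therefore demonstrates that the
estimators and the attribution arithmetic are correct under the model's own
assumptions — not that the gamma/k model is adequate for any particular
real survey.

## Validation layers

Because the original survey microdata is restricted and the meta-analytic
risk coefficients live outside this package, validation has two layers:
(1) the consistency audit rebuilds every margin, cause-group sum, race-block
sum, and percentage of the published mortality and PYLL tables from their
printed cells (fixtures transcribed into `data/table{1,2,3}.csv`), with
zero tolerance on counts and print-precision matching on percentages; and
(2) simulation-backed tests — quadrature vs 10⁶-draw Monte-Carlo oracles
(0.002 absolute), end-to-end recovery of planted AAFs at 50,000 survey rows
per stratum (0.01 absolute), gamma-mean recovery (2%, pooled across seeds
because a single drinker subsample with CV > 1 carries ~1% standard error),
coverage-correction conservation (1e−6 relative), discounting closed forms
(1e−9), and the ordering of the unadjusted vs 80%-coverage sensitivity
branches under risk-increasing configurations.

## Problem sizes

Acceptance and test runs use 4 recovery strata at 50,000 rows each for the
end-to-end check and 40 strata at 400–2,000 rows for pipeline-level
orderings; these sizes put Monte-Carlo noise well inside the stated
tolerances while keeping a full run in tens of seconds.

## Known limitations

* Shipped risk coefficients are illustrative; all validation targets are
  independent of them.
* Cross-sectional exposure: no lag between consumption and chronic-disease
  mortality (relevant for cancers).
* No harms-to-others pathways, no morbidity (YLD/DALY), no uncertainty
  intervals — point estimates only.
* The 65+ age range is accepted structurally (extra bands flow through) but
  carries no validation targets.
* The injury method is a categorical approximation of occasion-level risk.
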