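# Methods

This note documents the models, defaults, numerical choices and known
limitations of `heatsmoke`, in the spirit of a statistical package's methods
appendix. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Study design

The package implements a **time-stratified case-crossover** analysis of the
joint effect of extreme heat and wildfire-smoke PM2.5 on hospital
admissions. Each admission day ("case day") is compared with every other
same-day-of-week day in the same calendar month and year (3 or 4 referent
days). Because each person serves as their own control, all time-invariant
individual characteristics are conditioned out; matching on month-year and
weekday removes slow seasonal trends and day-of-week utilization patterns.
The referent scheme is symmetric (any referent's own referent set contains
the original case day), which makes the time-stratified design unbiased for
short-term exposure effects under the usual case-crossover assumptions
(exposure not affected by the outcome; no trend within month).

### Exposure construction

- **Wildfire-influenced PM2.5.** For each grid cell and calendar day
  (month, day), the expected smoke-free concentration is the mean of total
  PM2.5 over all study years on that calendar day with no plume overhead.
  Feb 29 pools with Feb 28. If every same-calendar-day observation is
  plume-covered, the window widens symmetrically ±w days (circularly across
  the year boundary), w = 1…15, until at least one smoke-free observation is
  pooled; a cell with a fully plume-covered ±15-day window is a hard error.
  The estimator is a raw mean rather than a seasonal smoother — the simplest
  faithful choice; a harmonic fit would differ only where smoke-free
  observations are very sparse.
  Attribution requires *both* plume overlap and exceedance:
  `wf = max(total − expected, 0) · 1{plume}`; hence `0 ≤ wf ≤ total`
  everywhere and `wf = 0` on all non-plume days.
- **Population weighting.** Gridded hazards are aggregated to ZCTAs with
  weights `pop(cell)/pop(ZCTA)`; the result is a convex combination of the
  cell values (verified property). Nearest-neighbor block replication
  (`regrid_nearest`) reproduces the resampling of coarse products onto a
  finer grid; synthetic grids are built to nest exactly, so no CRS handling
  is needed or attempted.
- **Extreme heat.** Month- and ZCTA-specific empirical quantiles (linear
  interpolation between order statistics, the common default in scientific
  software) of daily Tmax pooled across study years, at the 90th/95th/99th
  percentiles; a heat day is `tmax > threshold` — *strictly* greater,
  matching the "days above the cutoff" reading. All temperatures are °F.
  At least 28 observations per (ZCTA, month) pool are required.

### The interaction model

Per matched stratum *i* with one case and m referents:

    logit Pr(Y=1|X) = β0i + βH·X_HEAT + βS·X_SMOKE + βHS·X_HEAT·X_SMOKE

The exact conditional likelihood eliminates β0i:

    ℓ(β) = Σ_i [ η_case − log Σ_rows exp(η_row) ]

with analytic gradient `x_case − E_w[x]` and Hessian `−Σ_i Cov_w(x)` (w the
within-stratum softmax). Strata whose rows share identical exposures
contribute a constant `log(1/m)` and are dropped and counted.

Smoke enters either continuously (µg/m³) or as indicators `>0` or `>12`
µg/m³ (the heavy-plume-density cutoff; strict inequality). Heat may be
lagged X days and smoke Y days (0–3), modeled separately for each of the 16
combinations; lag look-backs may cross month boundaries backwards.

### Interaction measures

At a smoke increment δ (default 1 µg/m³, configurable — additive measures
require a defined exposure contrast):

    OR01 = e^βH,  OR10 = e^(βS·δ),  OR11 = e^(βH + βS·δ + βHS·δ)
    multiplicative = e^(βHS·δ)
    RERI = OR11 − OR10 − OR01 + 1
    AP   = RERI / OR11

RERI > 0 ⟺ AP > 0 ⟺ OR11 > OR01 + OR10 − 1 (super-additivity), exactly, for
every fit. CIs: Wald on the log scale for the ORs and the multiplicative
measure; the delta method for RERI and AP, each propagated through the fit
covariance on its own gradient (AP is *not* back-transformed from RERI).
P-values are two-sided normal; the one-sided (synergy > 0) value is also
emitted and the convention is labeled in the output.

## Numerical choices

- **Optimizer**: full Newton–Raphson from β = 0 with step-halving on any
  likelihood decrease; convergence at max|∇ℓ| < 1e-8 or relative ℓ change
  < 1e-10; covariance is the inverse negative Hessian at the optimum.
- **Degenerate designs**: a term with no within-stratum variation anywhere
  is structurally collinear with the stratum intercepts and raises an error
  naming the term; a design with *no* informative stratum raises a
  degenerate-design error.
- **Separation**: monotone likelihoods (complete or quasi-complete
  separation) are flagged as non-converged with a diagnostic, never allowed
  to diverge silently. Detection: a Hessian that loses rank along the ascent
  path after the first step, or a "converged" coefficient with |β| > 10
  (odds ratio > 2×10⁴ — the gradient tolerance can be met while the softmax
  saturates). Interaction measures refuse non-converged fits.
- **Quantiles**: linear interpolation between order statistics; any
  consistent convention shifts thresholds by less than one daily
  observation.

## The synthetic world

`SimulationConfig` defaults state one synthetic world; they are not tuned to
test outcomes:

| parameter | default | rationale |
|---|---|---|
| grid | 6×6 cells, 9 contiguous ZCTA blocks | smallest grid exercising aggregation |
| period | 2011-01-01 – 2012-12-31 | ≥ 2 full years so month/day baselines and monthly thresholds are estimable |
| mean Tmax / seasonal amplitude / noise SD | 75 / 20 / 7 °F | mid-latitude climate; July-peaked sinusoid |
| background PM2.5 | lognormal, mean 8, SD 4 µg/m³ | typical non-fire ambient levels |
| plume events | Poisson(6)/cell·season, geometric runs (mean 3 d), May–Nov | episodic multi-day smoke in the fire season |
| plume boost | +20 µg/m³ | clearly separates plume days from background |
| cell population | Poisson(1000)+1 persons | positive ZCTA totals guaranteed |
| truth (βH, βS, βHS) | (0.3, 0.05, 0.08) at lags (0, 3) | moderate effects per heat day / µg/m³ |
| demographics / community rates | printed all-natural case mix (e.g. 57.6% female, 40.2% aged 65+, 85.2% English; 18.8% higher-poverty, 31.8% lower-education, 2.8% rural ZCTAs) | realistic stratified-analysis fixtures |

Case generation draws a ZCTA and a (year, month, weekday) stratum uniformly,
then picks the admission day within the stratum with probability
∝ exp(βH·xH + βS·xS + βHS·xH·xS) at the truth lags — the *same* stratum
definition the analysis conditions on, so parameter recovery is exact in
expectation. Admissions start at day 4 of the study period so every case
has full 3-day lag history. Diagnosis codes are drawn from representative
categories inside the printed outcome ranges; the ICD-9→ICD-10 switch is at
admission year 2016.

What the generator does **not** emulate: spatial correlation of weather and
smoke between cells (cells are independent draws), real fire calendars or
plume geometry, monitor-based PM2.5 surfacing, exposure measurement error,
within-person admission dependence (repeat admissions are independent
strata), and marginal compound-day frequencies matched to any particular
region. A green test therefore establishes correctness of the *estimators
and design machinery*, not realism of any specific epidemiologic effect
size. The marginal rate of compound exposure days is governed by free knobs
(`plume_rate`, heat climatology), not calibrated to published frequencies.

`simulate_strata` generates matched strata directly at the design level
(i.i.d. exposures within stratum, case sampled by the same softmax); it is
the fast path for parameter-recovery, coverage and bootstrap studies where
the raster stage is irrelevant.

## Design choices where the design was open

- **RERI sign convention**: the standard `OR11 − OR10 − OR01 + 1`
  (VanderWeele & Knol), the convention of the InteractionR package.
- **All-natural classification**: ICD-10 chapters A–R count as natural;
  S–Z (injury, poisoning, external causes, special-purpose and status
  codes) are excluded, as are ICD-9 800–999 and E/V codes. Range membership
  is decided on the 3-character category, so subcodes inherit their
  category's classification; ICD-10 ranges compare lexicographically within
  a letter (I30–I5A contains I5A).
- **Suppression counting**: "cases exposed" counts case rows with
  lag-assigned heat = 1 *and* smoke > 0 (joint exposure, the binding
  constraint for interaction cells); configurable to `either`. Default
  minimum is 10 exposed cases.
- **Month restriction** (May–November) is decided on the case date;
  referents share the month by construction.
- **Multiple qualifying diagnoses** enter each outcome-specific analysis
  once; outcomes are analyzed separately.
- **Multiple testing**: raw p-values across all 16 cells × outcomes ×
  strata, with the cell count emitted so users can adjust post hoc.
- **Community flags** are time-invariant attributes of the record (one
  ACS-style vintage), not year-varying covariates.

## Limitations

- The conditional-likelihood implementation targets the 3-parameter
  interaction model; it is not a general conditional-logistic regression
  with arbitrary covariates (the case-crossover design absorbs individual
  covariates by matching).
- Delta-method intervals for RERI and AP are first-order asymptotics; with
  very few informative strata they can disagree with resampling intervals
  (the acceptance suite checks agreement with a parametric bootstrap at
  realistic stratum counts).
- Distributed-lag nonlinear models, pooling across lag cells, and exact
  permutation inference are out of scope.
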