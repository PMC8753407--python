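# Methods

## Model

The unit of analysis is a city × cause-of-death × demographic-subgroup cell.
For each cell the observed annual death probability `m_c` is modelled as a
coverage-weighted blend of enrolled and unenrolled risk,

    m_b · HR · p + m_b · (1 − p) = m_c,

where `p` is the city's observed FHS enrolment share (2016), `HR` the hazard
ratio of death for FHS users vs non-users for that cause and subgroup, and
`m_b` the base probability of an unenrolled person. Calibration solves this
algebraically, `m_b = m_c / (HR·p + 1 − p)` — no iterative solver, so the
identity `project(calibrate(m_c)) = m_c` holds to machine precision and the
reference column of any ratio matrix is exactly 1. Projection re-evaluates
the blend at `p′ = clamp(p + Δ/100, 0, 1)`; the ±Δ grid runs from −20 to
+40 percentage points. Because the blend is affine in coverage, per-city
no-clamp ratios are linear in Δ (`ratio(−Δ) + ratio(+Δ) = 2`); clamping at
100% attenuates high-coverage cities (e.g. Belo Horizonte at 76.5% clamps
above +23.5 pp), pulling the pooled +40 ratio toward 1.

Rates are stored exactly as published (deaths per 1,000 person-years; child
outcomes per 1,000 live births) and converted to annual probabilities by
dividing by 1,000. This rate→probability shortcut (rather than
`1 − exp(−rate)`) follows the model's framing of annual mortality
probabilities; at these magnitudes (≤ ~0.008) the two differ by < 0.5%.

Calibration is infeasible when the implied `m_b` or `m_b·HR` reaches 1; the
engine raises a named error identifying city and cause rather than clipping.

## Execution modes

**Analytic** (`apply_scenario`): exact expected rates per cell, pooled
across cities by population weight (a config switch gives unweighted means;
the published pooling weights are not stated, so population weighting is
this package's choice). City populations are not part of the published city
table and come from a synthetic defaults file.

**Stochastic** (`run_microsim`): each individual carries age band, sex,
race, Bolsa Família status and enrolment; each simulated year one draw from
a multinomial over causes (probability `m_b·HR` per cause if enrolled,
`m_b` otherwise, optionally scaled by an age-band factor with
population-weighted mean 1) plus a survival residual. A single multinomial
guarantees at most one death per person-year and conserves total
probability exactly, unlike independent per-cause Bernoulli draws. Coverage
changes re-assign enrolment monotonically: expansion never disenrols an
existing enrolee; contraction disenrols uniformly at random. The analytic
mode is the exact expectation of the stochastic mode and serves as its test
oracle (agreement within 3 binomial SE at n = 500,000). Multi-year runs
iterate the same annual probabilities on survivors — a closed, static
population with no ageing, births or migration, because the source material
specifies none.

## Hazard-ratio uncertainty

Each Monte Carlo replicate redraws every (cause × subgroup) HR
independently from a normal distribution built from its mean and 95% CI:
linear scale by default — `Normal(mean, (hi − lo)/3.92)` truncated below at
10⁻⁶, truncation events counted and logged — with a log-scale option
(`exp(Normal(log mean, (log hi − log lo)/3.92))`) since HR intervals are
conventionally log-symmetric; which scale the source analysis used is not
stated, so both are provided and linear is the documented default, matching
the literal "random normal distributions" description. Intervals are
percentile (2.5/97.5 by default) over replicates; the point estimate is
always computed at the HR means and never uses draws, so it is invariant to
replicate count and seed. No cross-cause correlation is imposed (none is
stated) and no bootstrap of an empirical HR set is performed. The reference
analysis used 10,000 replicates per city; examples and tests here use
1,000, which resolves the 2.5/97.5 percentiles with interval-endpoint Monte
Carlo error well under the display precision. Baseline-rate and demographic
sampling error is deliberately not propagated — only HR uncertainty is.

## Synthetic inputs

The published material prints city-level aggregates only; cause- and
subgroup-specific HRs and all microdata are unprinted. The generator
emulates their structure:

- **HR table** — cause-level log HRs `Normal(−0.6, 0.25)`, CI half-width
  0.15 on the log scale. These defaults were fixed by inverting the
  published pooled ratio rows (all-cause 1.11 at −20 pp / 0.78 at +40 pp at
  mean coverage ≈ 0.42 implies HR ≈ 0.55; cause rows span ≈ 0.40–0.95).
  Subgroup cells add per-level modifiers: deterministic tilts (Bolsa
  Família −0.08, Black −0.06, Pardo −0.03 on the log scale, mirroring the
  reported 1.3×/1.2×/1.1× absolute-response gradients) plus
  `Normal(0, 0.1)` noise. The maternal cause's log HR is shrunk by 0.05 to
  reproduce its flat row; infant/under-5 get literature-style `any`-only
  entries around log HR −0.16.
- **Cause splits** — Dirichlet around a packaged plausible urban-Brazil mix
  (cardiovascular-dominant), concentration 200 (≈ ±2% absolute wobble on
  the largest shares); `∞` returns the mix exactly. Cause-specific rates
  conserve the all-cause rate by construction.
- **Individuals** — attributes drawn independently from city marginals
  (no published joint distribution; a known limitation — real attribute
  correlation, e.g. poverty × race, would sharpen subgroup contrasts), with
  a three-macro-band age structure (<15, 15–64, 65+) spread uniformly
  within bands.
- **Age schedule** — `rate ∝ exp(0.085 · (age − 60))` per band, rescaled so
  the band-mass-weighted mean equals the city's crude rate to 1e-9 relative
  error. The slope gives an 80+/young-adult rate ratio of order 100–300,
  typical of all-cause schedules.
- **Subgroup baselines** — no subgroup-specific observed rates are
  published, so by default every cell calibrates to the city cause rate
  (zero within-city baseline gap); `build_schedule` accepts subgroup rate
  multipliers (renormalised to conserve the city rate) to emulate baseline
  disparities, as the inequality-gap example does.

Passing tests on these inputs demonstrate the machinery — calibration,
projection, propagation, aggregation — not the true Brazilian magnitudes:
real HRs, joint demographics and cause mixes would shift levels, though the
structural identities (linearity, calibration, oracle equivalence) are
input-independent.

## Age bands and standardisation

Bands: 0–4, 5–14, then 15–24 … 55–64, 65–69, 70–79, 80+ — chosen so 15 and
65 (the published macro-band edges) and 70 (the premature-mortality cutoff)
all fall on boundaries; `premature_ncd` rejects any cutoff off a boundary.
Direct standardisation uses the pooled 15-city age structure as the default
standard — **the published analysis never names its standard population** —
with the WHO World Standard selectable. Display rounding is half-up, 2 dp
for ratios and 1 dp for per-1,000 rates; machine-readable outputs keep full
precision and are byte-deterministic at fixed config.

## Inequality and SDG metrics

Gaps are absolute differences of all-cause rates per 1,000: between-city
(max − min city crude rate) and pooled group differences (Black−White,
Pardo−White, Bolsa Família−not), where group rates marginalise cells within
city and pool across cities by population × group share — so baseline group
gaps include between-city composition, as published gap figures do. The SDG
scorecard evaluates, at the largest swept shift: premature (<70) NCD
reduction vs the one-third target; communicable-disease reduction vs a
100% ("ending deaths") target; and each city's projected under-5 rate vs
25 per 1,000 live births. Child outcomes are projected at the rate level
with literature-style HRs (no individual children are simulated), using
live births = population × crude birth rate/1,000 as the denominator scale.

## Problem sizes and numerical choices

Default study conditions: the 15 packaged cities, 17 adult cause groups,
16 fully-specified subgroup cells (4,080 calibrated cells); stochastic
checks use 150,000–500,000 individuals per city; Monte Carlo examples use
1,000 replicates. Tolerances: machine-precision identities at 1e-12
relative; stochastic agreement at 3 SE; interval coverage checked at
95% ± 3 pp. Ties/degeneracies: equal coverage levels make `recover_hr`
ill-posed (a named error); zero-width CIs collapse intervals to points by
construction.

## Data-fidelity note

One cell of the packaged city table is adjusted: the published Pardo share
for Curitiba (58.5%) is internally inconsistent (White+Black+Pardo =
136.6%, vs 96.6–99.6% for every other city) and is stored as 18.5%, in line
with its peers. All other cells are verbatim. Population, Bolsa Família
share and birth rate are synthetic defaults, labelled as such in
`data/city_defaults.csv`.
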