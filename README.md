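# fhsim

Microsimulation of primary-care coverage change and cause-specific mortality
in the 15 largest Brazilian cities.

Brazil's Estratégia de Saúde da Família (Family Health Strategy, FHS)
delivers community-based primary care through multidisciplinary teams;
enrolment multiplies a person's hazard of death from each cause by a hazard
ratio HR (HR < 1 = protective). `fhsim` asks the policy question: **what
happens to mortality — overall, by cause, by demographic group — if a city's
FHS coverage rises or falls?**

## The model

A city's observed mortality probability `m_c` for a cause blends enrolled
and unenrolled risk at the observed coverage `p`:

```
m_b · HR · p + m_b · (1 − p) = m_c
```

Step 1 (calibration) inverts this for the base probability of an unenrolled
person, `m_b = m_c / (HR·p + 1 − p)`. Step 2 (projection) re-applies the
blend at a counterfactual coverage `p′ = clamp(p + Δ/100, 0, 1)` for shifts
Δ from −20 to +40 percentage points. The relation is affine in coverage, so
per-city no-clamp mortality ratios are linear in Δ — a property the test
suite verifies symbolically and numerically.

Around this kernel the package provides:

- **`fhsim.io`** — validated readers/writers; a packaged 15-city table
  (2016 demographics, FHS coverage, crude/age-standardised/infant/under-5
  mortality) plus clearly-labelled synthetic defaults for population
  weights, Bolsa Família shares and birth rates.
- **`fhsim.synth`** — synthetic hazard-ratio tables (log-normal, asymmetric
  CIs, subgroup modifiers by sex, race and Bolsa Família receipt), Dirichlet
  cause-of-death splits, individual population tables, and exponential
  age-mortality schedules calibrated to each city's crude rate.
- **`fhsim.engine`** — analytic expected-value projection
  (`apply_scenario`, `scenario_sweep`) and a stochastic individual-level
  engine (`run_microsim`) drawing one multinomial death per person-year;
  `recover_hr` inverts published-style ratio tables back to hazard ratios.
- **`fhsim.uncertainty`** — Monte Carlo propagation: each replicate redraws
  every HR from a normal built on its 95% CI; percentile intervals.
- **`fhsim.metrics`** — age standardisation, infant/under-5 projection,
  premature (<70) non-communicable-disease mortality, absolute inequality
  gaps (between cities, Black vs White, Pardo vs White, Bolsa Família vs
  not), and an SDG scorecard (targets 3.4, 3.2, "ending" communicable
  deaths).

## Worked example

```python
import fhsim

cities = fhsim.load_packaged_cities()
cfg = fhsim.SynthConfig(seed=1)
hr_table = fhsim.gen_hr_table(cfg)
splits = {c.name: fhsim.gen_cause_split(c, cfg) for c in cities}
schedule = fhsim.build_schedule(cities, hr_table, splits)
sweep = fhsim.scenario_sweep(schedule, cities)   # Δ = −20 … +40 pp

r0, r40 = sweep[2], sweep[-1]
print(r0.city_crude["Rio de Janeiro"])   # 8.14   (observed rate recovered)
print(r40.pooled_all_cause_ratio)        # 0.8177…
card = fhsim.sdg_assessment(sweep, cities, hr_table)
print(card["premature_ncd"]["achieved_reduction"])  # 0.1975…
```

At unchanged coverage the projection returns the observed crude rate of
8.14 deaths per 1,000 exactly (calibration identity). At +40 percentage
points, pooled all-cause mortality falls to 0.82 of baseline, and premature
non-communicable-disease mortality drops ~20% — short of the SDG 3.4 target
of one-third. `examples/` contains runnable scripts for the coverage sweep,
uncertainty intervals, inequality gaps, the SDG scorecard and the
stochastic-vs-analytic cross-check, each printing the numbers above with a
note on what they mean.

## Limitations

Cause-specific and subgroup-specific hazard ratios and baseline splits are
synthetic emulations (their magnitudes anchored to published pooled ratio
tables), not re-estimates from individual data; demographic attributes are
sampled independently; the population is closed and static. See
`docs/methods.md` for the full accounting.
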