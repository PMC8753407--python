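"""Project cause-specific mortality over a grid of FHS coverage shifts.

Loads the packaged 15-city table, generates a synthetic hazard-ratio table,
calibrates base mortality and sweeps coverage from -20 to +40 percentage
points, printing the pooled published-style ratio matrix.
"""

import fhsim

cities = fhsim.load_packaged_cities()
cfg = fhsim.SynthConfig(seed=1)
hr_table = fhsim.gen_hr_table(cfg)
splits = {c.name: fhsim.gen_cause_split(c, cfg) for c in cities}
schedule = fhsim.build_schedule(cities, hr_table, splits)
sweep = fhsim.scenario_sweep(schedule, cities)

print("Pooled mortality ratio vs current coverage (rows: cause, cols: pp shift)")
print(f"{'cause':<24}" + "".join(f"{int(r.delta_pp):>7}%" for r in sweep))
row = "All causes"
print(f"{row:<24}" + "".join(f"{r.pooled_all_cause_ratio:8.2f}" for r in sweep))
for code in sweep[0].pooled_cause.index:
    label = fhsim.CAUSE_REGISTRY[code].label[:23]
    print(f"{label:<24}" + "".join(f"{float(r.pooled_cause.loc[code, 'ratio']):8.2f}" for r in sweep))

r0 = next(r for r in sweep if r.delta_pp == 0)
print("\nThe 0% column is exactly 1.00: re-projecting at the observed coverage")
print("returns the observed rates (calibration identity). Ratios below 1 at")
print("positive shifts quantify deaths averted by expanding primary care;")
print(f"e.g. Rio de Janeiro crude mortality {r0.city_crude['Rio de Janeiro']:.2f} -> "
      f"{sweep[-1].city_crude['Rio de Janeiro']:.2f} per 1,000 at +40 pp.")
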