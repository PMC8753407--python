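"""Cross-check the individual-level simulator against the closed form.

Simulates 200,000 Rio de Janeiro residents with a multinomial death draw per
person-year and compares the crude rate with the analytic expectation.
"""

import numpy as np

import fhsim

cities = fhsim.load_packaged_cities()
rio = next(c for c in cities if c.name == "Rio de Janeiro")
cfg = fhsim.SynthConfig(seed=1)
hr_table = fhsim.gen_hr_table(cfg)
schedule = fhsim.build_schedule([rio], hr_table, {rio.name: fhsim.gen_cause_split(rio, cfg)})

n = 200_000
pop = fhsim.gen_population(rio, n, seed=2)
sim = fhsim.run_microsim({rio.name: pop}, schedule, 20,
                         fhsim.EngineConfig(mode="stochastic", seed=3),
                         age_factors={rio.name: fhsim.age_factors(rio, cfg)})
analytic = fhsim.apply_scenario(schedule, [rio], 20)

obs = sim.crude_rate(rio.name)
exp = float(analytic.city_crude[rio.name])
se = np.sqrt(exp / 1000.0 / n) * 1000.0
print(f"Rio de Janeiro, +20 pp coverage, n={n:,} simulated residents:")
print(f"  stochastic crude rate: {obs:.3f} per 1,000")
print(f"  analytic expectation:  {exp:.3f} per 1,000 (binomial SE {se:.3f})")
print(f"  deviation: {abs(obs-exp)/se:.2f} SE")
print("\nThe analytic mode is the exact expectation of the stochastic engine;")
print("agreement within a few SE validates the individual-level sampler.")
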