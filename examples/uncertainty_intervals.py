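"""Propagate hazard-ratio uncertainty into the pooled coverage response.

Each replicate redraws every hazard ratio from a normal distribution built
from its 95% CI and re-runs the analytic projection; the 2.5/97.5 replicate
percentiles form the uncertainty interval.
"""

import fhsim

cities = fhsim.load_packaged_cities()
cfg = fhsim.SynthConfig(seed=1)
hr_table = fhsim.gen_hr_table(cfg)
splits = {c.name: fhsim.gen_cause_split(c, cfg) for c in cities}


def pooled_all_cause_ratio_at_plus40(table):
    schedule = fhsim.build_schedule(cities, table, splits)
    return fhsim.apply_scenario(schedule, cities, 40).pooled_all_cause_ratio


res = fhsim.monte_carlo(
    pooled_all_cause_ratio_at_plus40, hr_table, fhsim.MCConfig(n_reps=1000, seed=5)
)
print(f"Pooled all-cause mortality ratio at +40 pp coverage: "
      f"{res.point:.3f} (95% interval {res.lo:.3f} to {res.hi:.3f}, "
      f"{res.n_reps} replicates)")
print("A ratio of 0.90 means a 10% mortality reduction; the interval reflects")
print("only hazard-ratio estimation uncertainty, not baseline-rate error.")
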