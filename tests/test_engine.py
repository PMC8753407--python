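"""Calibration/projection kernel, analytic scenarios and the stochastic engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fhsim
from fhsim.engine import _reassign_enrolment
from fhsim.types import FULL_SUBGROUPS, Subgroup, ValidationError


def _flat_hr_table(hr=1.0, causes=("heart_disease", "stroke")):
    entries = [
        fhsim.HazardRatioEntry(c, Subgroup(), hr, hr, hr) for c in causes
    ]
    return fhsim.HazardRatioTable(entries)


class TestCalibrateProject:
    def test_unit_hazard_ratio_is_the_identity(self):
        assert fhsim.calibrate_base(0.005, 1.0, 0.7) == pytest.approx(0.005, rel=1e-15)

    def test_zero_coverage_is_the_identity(self):
        assert fhsim.calibrate_base(0.005, 0.8, 0.0) == pytest.approx(0.005, rel=1e-15)

    def test_direct_inversion_value(self):
        # mc/(hr*p + 1 - p) = 0.005/0.9; substituting back must close Eq. balance
        mb = fhsim.calibrate_base(0.005, 0.8, 0.5)
        assert mb == pytest.approx(0.005 / 0.9, rel=1e-15)
        assert mb * 0.8 * 0.5 + mb * 0.5 == pytest.approx(0.005, rel=1e-15)

    def test_projection_at_new_coverage(self):
        mb = fhsim.calibrate_base(0.005, 0.8, 0.5)
        # direct evaluation: mb * (0.8*0.7 + 0.3) = 0.005 * 0.86 / 0.9
        assert fhsim.project_rate(mb, 0.8, 0.7) == pytest.approx(0.005 * 0.86 / 0.9, rel=1e-15)

    def test_protective_hr_means_higher_base_rate(self):
        assert fhsim.calibrate_base(0.005, 0.8, 0.5) > 0.005
        assert fhsim.calibrate_base(0.005, 1.25, 0.5) < 0.005

    def test_rate_decreases_as_protective_coverage_rises(self):
        mb = fhsim.calibrate_base(0.005, 0.8, 0.5)
        rates = [fhsim.project_rate(mb, 0.8, p) for p in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    @pytest.mark.parametrize("mc", [0.0, 1.0, -0.1])
    def test_observed_probability_domain_enforced(self, mc):
        with pytest.raises(ValidationError):
            fhsim.calibrate_base(mc, 0.8, 0.5)

    def test_infeasible_calibration_raises(self):
        # hr*p + 1 - p = 0.505 -> mb = 0.99; enrolled probability fine, but
        # a tiny blend with large mc pushes mb past 1
        with pytest.raises(ValidationError, match="infeasible"):
            fhsim.calibrate_base(0.6, 0.01, 1.0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        mc=st.floats(1e-6, 0.5),
        hr=st.floats(0.05, 3.0),
        p=st.floats(0.0, 1.0),
    )
    def test_round_trip_is_machine_exact(self, mc, hr, p):
        try:
            mb = fhsim.calibrate_base(mc, hr, p)
        except ValidationError:
            return  # infeasible corner of the domain
        assert fhsim.project_rate(mb, hr, p) == pytest.approx(mc, rel=1e-13)


class TestRecoverHr:
    def test_unit_ratio_recovers_unit_hr(self):
        assert fhsim.recover_hr(5.0, 5.0, 0.3, 0.7) == pytest.approx(1.0)

    @pytest.mark.parametrize("hr", [0.5, 0.75, 1.0, 1.25])
    @pytest.mark.parametrize("p", [0.2, 0.5, 0.8])
    def test_forward_simulation_round_trip(self, hr, p):
        mb = 0.006
        delta = 0.2 if p <= 0.8 else -0.2
        p2 = p + delta
        r1 = fhsim.project_rate(mb, hr, p)
        r2 = fhsim.project_rate(mb, hr, p2)
        assert fhsim.recover_hr(r1, r2, p, p2) == pytest.approx(hr, rel=1e-10)

    def test_published_style_inversion_is_unique(self):
        # a -20pp ratio of 1.12 at coverage 0.629 pins a single hr in (0, 1);
        # brute-force grid scan is the independent check on uniqueness
        p, ratio = 0.629, 1.12
        hr = fhsim.recover_hr(1.0, ratio, p, p - 0.2)
        assert 0.0 < hr < 1.0

        def implied_ratio(h):
            return (h * (p - 0.2) + 1 - (p - 0.2)) / (h * p + 1 - p)

        grid = np.linspace(1e-3, 3.0, 30_000)
        sign = np.sign(implied_ratio(grid) - ratio)
        crossings = np.flatnonzero(np.diff(sign))
        assert crossings.size == 1
        assert grid[crossings[0]] == pytest.approx(hr, abs=2e-4)

    def test_equal_coverages_carry_no_information(self):
        with pytest.raises(ValidationError, match="no information"):
            fhsim.recover_hr(5.0, 4.0, 0.5, 0.5)


class TestApplyScenario:
    def test_zero_delta_reproduces_observed_rates_exactly(self, sweep):
        r0 = next(r for r in sweep if r.delta_pp == 0)
        assert np.allclose(r0.rates["ratio"], 1.0, rtol=1e-12, atol=0)
        assert r0.pooled_all_cause_ratio == pytest.approx(1.0, rel=1e-12)

    def test_unit_hazard_ratios_are_scenario_invariant(self, cities):
        mix = {"heart_disease": 0.6, "stroke": 0.4}
        sched = fhsim.build_schedule(
            cities[:3], _flat_hr_table(1.0), {c.name: mix for c in cities[:3]}
        )
        for delta in (-20, 15, 40):
            r = fhsim.apply_scenario(sched, cities[:3], delta)
            assert np.allclose(r.rates["ratio"], 1.0, rtol=1e-12)

    def test_single_city_ratio_symmetry_without_clamping(self, schedule, cities):
        # coverage 0.445 keeps +/-20 pp inside [0, 1], so the affine response
        # must satisfy ratio(-20) + ratio(+20) = 2
        campinas = [c for c in cities if c.name == "Campinas"]
        sched = schedule[schedule.city == "Campinas"]
        plus = fhsim.apply_scenario(sched, campinas, 20)
        minus = fhsim.apply_scenario(sched, campinas, -20)
        total = plus.rates["ratio"].to_numpy() + minus.rates["ratio"].to_numpy()
        assert np.allclose(total, 2.0, rtol=1e-12, atol=1e-12)

    def test_symbolic_oracle_confirms_affine_response(self):
        import sympy as sp

        mb, hr, p, d = sp.symbols("mb hr p d", positive=True)
        ratio = (hr * (p + d) + 1 - (p + d)) / (hr * p + 1 - p)
        ratio_m = ratio.subs(d, -d)
        assert sp.simplify(ratio + ratio_m - 2) == 0

    def test_monotone_in_delta_under_protective_hr(self, sweep):
        ratios = [r.pooled_all_cause_ratio for r in sweep]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))

    def test_clamped_cities_attenuate_the_pooled_response(self, cities, hr_table):
        # Belo Horizonte (76.5% coverage) clamps at +40; the pooled ratio must
        # sit strictly closer to 1 than the no-clamp affine prediction
        sched = fhsim.build_schedule(cities, hr_table)
        r10 = fhsim.apply_scenario(sched, cities, 10)  # no city clamps at +10
        r40 = fhsim.apply_scenario(sched, cities, 40)
        no_clamp_prediction = 1.0 + 4.0 * (r10.pooled_all_cause_ratio - 1.0)
        assert no_clamp_prediction < r40.pooled_all_cause_ratio < 1.0

    def test_missing_cause_hr_is_an_error(self, cities):
        with pytest.raises(KeyError):
            fhsim.build_schedule(cities[:1], _flat_hr_table(0.8, causes=("hiv",)),
                                 {cities[0].name: {"heart_disease": 1.0}})

    def test_city_crude_baseline_matches_fixture(self, sweep, cities):
        r0 = next(r for r in sweep if r.delta_pp == 0)
        for c in cities:
            assert r0.city_crude[c.name] == pytest.approx(c.crude_mortality, rel=1e-12)

    def test_pooled_rate_is_population_weighted_city_mean(self, sweep, cities):
        r = sweep[-1]
        pops = {c.name: c.population for c in cities}
        total = sum(pops.values())
        expected = sum(r.city_crude[n] * w / total for n, w in pops.items())
        assert r.pooled_all_cause_rate == pytest.approx(expected, rel=1e-12)

    def test_subgroup_multipliers_conserve_the_city_rate(self, cities, hr_table):
        mult = {sg.key: (1.4 if sg.race == "black" else 0.9) for sg in FULL_SUBGROUPS}
        sched = fhsim.build_schedule(cities[:2], hr_table, subgroup_rate_multipliers=mult)
        r0 = fhsim.apply_scenario(sched, cities[:2], 0)
        for c in cities[:2]:
            assert r0.city_crude[c.name] == pytest.approx(c.crude_mortality, rel=1e-9)


class TestMicrosim:
    def test_zero_hazard_produces_zero_deaths(self, rio):
        rows = []
        for sg in FULL_SUBGROUPS:
            rows.append(
                {"city": rio.name, "cause": "heart_disease", "sex": sg.sex,
                 "race": sg.race, "bolsa_familia": sg.bolsa_familia,
                 "weight": rio.subgroup_weight(sg), "p": rio.fhs_coverage,
                 "hr": 1.0, "mc": 0.0, "mb": 0.0}
            )
        sched = pd.DataFrame(rows)
        pop = fhsim.gen_population(rio, 2_000, seed=1)
        res = fhsim.run_microsim({rio.name: pop}, sched, 0,
                                 fhsim.EngineConfig(mode="stochastic", seed=2))
        assert res.deaths.empty and res.crude_rate(rio.name) == 0.0

    def test_fixed_seed_reproduces_the_death_table(self, rio, schedule):
        sched = schedule[schedule.city == rio.name]
        pop = fhsim.gen_population(rio, 20_000, seed=3)
        cfg = fhsim.EngineConfig(mode="stochastic", seed=4)
        a = fhsim.run_microsim({rio.name: pop}, sched, 20, cfg)
        b = fhsim.run_microsim({rio.name: pop}, sched, 20, cfg)
        assert a.deaths.equals(b.deaths)

    def test_crude_rate_matches_analytic_oracle(self, rio, schedule):
        n = 150_000
        sched = schedule[schedule.city == rio.name]
        pop = fhsim.gen_population(rio, n, seed=5)
        ms = fhsim.run_microsim({rio.name: pop}, sched, 20,
                                fhsim.EngineConfig(mode="stochastic", seed=6))
        an = fhsim.apply_scenario(sched, [rio], 20)
        expected = float(an.city_crude[rio.name])
        se = np.sqrt(expected / 1000.0 / n) * 1000.0
        assert abs(ms.crude_rate(rio.name) - expected) < 3 * se

    def test_multi_year_exposure_counts_survivors_only(self, rio, schedule):
        sched = schedule[schedule.city == rio.name]
        pop = fhsim.gen_population(rio, 30_000, seed=7)
        res = fhsim.run_microsim({rio.name: pop}, sched, 0,
                                 fhsim.EngineConfig(mode="stochastic", seed=8, years=5))
        deaths = res.deaths["deaths"].sum()
        assert 30_000 * 5 - 4 * deaths <= res.exposure[rio.name] < 30_000 * 5

    def test_enrolment_change_is_monotone(self):
        rng = np.random.default_rng(0)
        enrolled = rng.random(50_000) < 0.5
        up = _reassign_enrolment(enrolled, 0.5, 0.8, np.random.default_rng(1))
        down = _reassign_enrolment(enrolled, 0.5, 0.2, np.random.default_rng(1))
        assert (up | enrolled).sum() == up.sum()      # no one disenrolled
        assert (down & enrolled).sum() == down.sum()  # no one newly enrolled
        assert abs(up.mean() - 0.8) < 0.01 and abs(down.mean() - 0.2) < 0.01

    def test_certain_death_inputs_rejected(self, rio):
        rows = [
            {"city": rio.name, "cause": "heart_disease", "sex": sg.sex,
             "race": sg.race, "bolsa_familia": sg.bolsa_familia,
             "weight": rio.subgroup_weight(sg), "p": 0.5, "hr": 1.0,
             "mc": 0.9, "mb": 1.2}
            for sg in FULL_SUBGROUPS
        ]
        pop = fhsim.gen_population(rio, 100, seed=1)
        with pytest.raises(ValidationError, match="reaches 1"):
            fhsim.run_microsim({rio.name: pop}, pd.DataFrame(rows), 0,
                               fhsim.EngineConfig(mode="stochastic", seed=2))
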