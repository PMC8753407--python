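"""Calibration and projection of mortality under coverage counterfactuals.

The model's balance condition ties a city's observed cause-specific mortality
probability ``mc`` to the (unobserved) base probability ``mb`` of an
FHS-unenrolled person, the enrolment hazard ratio ``hr`` and the enrolled
population share ``p``::

    mb * hr * p + mb * (1 - p) = mc

Calibration inverts this algebraically (``mb = mc / (hr*p + 1 - p)``);
projection re-applies it at a counterfactual coverage ``p_eff``. Because the
relation is affine in coverage, per-city no-clamp mortality ratios are linear
in the percentage-point shift — a property the tests exploit.

Two execution modes share this arithmetic: an analytic expected-value mode
(`apply_scenario`) and a stochastic individual-level mode (`run_microsim`)
that draws each person's cause of death from a multinomial per simulated
year. The analytic mode is the exact expectation of the stochastic one and
serves as its oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    ADULT_CAUSES,
    AGE_BAND_LABELS,
    FULL_SUBGROUPS,
    CityProfile,
    CoverageScenario,
    HazardRatioTable,
    Subgroup,
    ValidationError,
)

__all__ = [
    "EngineConfig",
    "calibrate_base",
    "project_rate",
    "recover_hr",
    "build_schedule",
    "apply_scenario",
    "scenario_sweep",
    "ScenarioResult",
    "run_microsim",
    "MicrosimResult",
]


@dataclass(frozen=True)
class EngineConfig:
    """Run-mode configuration.

    ``mode`` selects the analytic expected-value engine or the stochastic
    individual-level engine; ``n_individuals`` is the simulated population
    per city in stochastic mode; ``years`` iterates the annual probabilities
    on the surviving population (default one steady-state year). Coverage is
    always clamped to [0, 1].
    """

    mode: str = "analytic"
    n_individuals: int = 100_000
    years: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("analytic", "stochastic"):
            raise ValidationError(f"unknown mode {self.mode!r}", field_name="mode")
        if self.mode == "stochastic" and self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1", field_name="n_individuals")
        if self.years < 1:
            raise ValidationError("years must be >= 1", field_name="years")


# --------------------------------------------------------------------------
# Scalar kernel
# --------------------------------------------------------------------------


def calibrate_base(mc, hr, p):
    """Base (unenrolled) annual death probability implied by the observed one.

    Solves ``mb*hr*p + mb*(1-p) = mc`` for ``mb``. With a protective hazard
    ratio (hr < 1) the base probability exceeds the observed blend; hr = 1
    leaves it unchanged. Accepts scalars or numpy arrays.
    """
    mc = np.asarray(mc, dtype=float)
    hr = np.asarray(hr, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(mc <= 0) or np.any(mc >= 1):
        raise ValidationError("observed probability mc must lie in (0, 1)")
    if np.any(hr <= 0):
        raise ValidationError("hazard ratio must be > 0")
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("coverage p must lie in [0, 1]")
    denom = hr * p + 1.0 - p
    if np.any(denom <= 0):
        raise ValidationError("blend hr*p + 1 - p must be > 0")
    mb = mc / denom
    if np.any(mb >= 1) or np.any(mb * hr > 1):
        raise ValidationError(
            "infeasible calibration: base probability or enrolled probability reaches 1"
        )
    return mb if mb.ndim else float(mb)


def project_rate(mb, hr, p_eff):
    """Observed-blend probability at counterfactual coverage ``p_eff``.

    Exact inverse of :func:`calibrate_base`: projecting at the calibration
    coverage returns the observed probability to machine precision.
    """
    mb = np.asarray(mb, dtype=float)
    hr = np.asarray(hr, dtype=float)
    p_eff = np.asarray(p_eff, dtype=float)
    if np.any(p_eff < 0) or np.any(p_eff > 1):
        raise ValidationError("coverage p_eff must lie in [0, 1]")
    out = mb * (hr * p_eff + 1.0 - p_eff)
    return out if out.ndim else float(out)


def recover_hr(rate_a: float, rate_b: float, p_a: float, p_b: float) -> float:
    """Hazard ratio implied by rates at two distinct effective coverages.

    Given rates ``rate_a`` at coverage ``p_a`` and ``rate_b`` at ``p_b``
    (same city and cause, any common scale), the balance condition fixes a
    unique hr from the ratio ``r = rate_b / rate_a``::

        hr = (r*(1 - p_a) - (1 - p_b)) / (p_b - r*p_a)

    Used to validate forward simulations and to back out the hr a published
    ratio table implies.
    """
    if rate_a <= 0 or rate_b <= 0:
        raise ValidationError("rates must be > 0")
    if not (0 <= p_a <= 1 and 0 <= p_b <= 1):
        raise ValidationError("coverages must lie in [0, 1]")
    if p_a == p_b:
        raise ValidationError("coverage levels are equal: the ratio carries no information on hr")
    r = rate_b / rate_a
    denom = p_b - r * p_a
    if denom == 0:
        raise ValidationError("degenerate ratio: hr is unbounded for these inputs")
    hr = (r * (1.0 - p_a) - (1.0 - p_b)) / denom
    if hr <= 0:
        raise ValidationError(f"recovered hr {hr!r} is non-positive: inputs inconsistent with the model")
    return hr


# --------------------------------------------------------------------------
# Schedules
# --------------------------------------------------------------------------


def build_schedule(
    cities: Sequence[CityProfile],
    hr_table: HazardRatioTable,
    cause_fractions: Mapping[str, Mapping[str, float]] | None = None,
    subgroup_rate_multipliers: Mapping[tuple[str, str, str], float] | None = None,
) -> pd.DataFrame:
    """Calibrated mortality schedule per city x cause x subgroup cell.

    ``cause_fractions`` maps city name -> cause code -> share of all-cause
    mortality (defaults to the packaged mix for every city). Each fully
    specified subgroup cell is calibrated to the city's cause-level observed
    probability; ``subgroup_rate_multipliers`` optionally tilts baseline
    rates across cells (keyed by ``(sex, race, bolsa_familia)``) and is
    renormalised within each city so the weighted cell mean still equals the
    city rate. Missing subgroup-specific hazard ratios fall back to the
    cause's ``any`` entry.

    Returns a DataFrame with columns city, cause, sex, race, bolsa_familia,
    weight, p, hr, mc, mb — mc/mb as annual probabilities.
    """
    if cause_fractions is None:
        from .io import load_default_cause_mix

        mix = load_default_cause_mix()
        cause_fractions = {c.name: mix for c in cities}

    rows = []
    for city in cities:
        fractions = cause_fractions[city.name]
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"cause fractions sum to {total}, expected 1", entity=city.name
            )
        cells = [(sg, city.subgroup_weight(sg)) for sg in FULL_SUBGROUPS]
        wsum = sum(w for _, w in cells)
        if subgroup_rate_multipliers:
            raw = {sg.key: subgroup_rate_multipliers.get(sg.key, 1.0) for sg, _ in cells}
            norm = sum(w * raw[sg.key] for sg, w in cells) / wsum
            mult = {k: v / norm for k, v in raw.items()}
        else:
            mult = {sg.key: 1.0 for sg, _ in cells}
        for cause, frac in fractions.items():
            mc_cause = city.crude_mortality / 1000.0 * frac
            for sg, w in cells:
                entry = hr_table.lookup(cause, sg)
                mc_cell = mc_cause * mult[sg.key]
                try:
                    mb = calibrate_base(mc_cell, entry.hr_mean, city.fhs_coverage)
                except ValidationError as exc:
                    raise ValidationError(
                        str(exc), entity=f"{city.name}/{cause}", field_name="mb"
                    ) from exc
                rows.append(
                    {
                        "city": city.name,
                        "cause": cause,
                        "sex": sg.sex,
                        "race": sg.race,
                        "bolsa_familia": sg.bolsa_familia,
                        "weight": w / wsum,
                        "p": city.fhs_coverage,
                        "hr": entry.hr_mean,
                        "mc": mc_cell,
                        "mb": mb,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Analytic scenario engine
# --------------------------------------------------------------------------


@dataclass
class ScenarioResult:
    """Projected mortality under one coverage shift.

    ``rates`` holds one row per city x cause x subgroup cell with the
    projected rate, the calibration baseline and their ratio (per-1,000
    units). Pooled quantities are population-weighted across cities unless
    the scenario was run with equal weights. ``intervals`` is filled by the
    uncertainty module.
    """

    delta_pp: float
    rates: pd.DataFrame
    city_crude: pd.Series
    city_crude_baseline: pd.Series
    pooled_cause: pd.DataFrame
    pooled_all_cause_rate: float
    pooled_all_cause_baseline: float
    weights: pd.Series
    intervals: pd.DataFrame | None = None

    @property
    def pooled_all_cause_ratio(self) -> float:
        return self.pooled_all_cause_rate / self.pooled_all_cause_baseline

    def group_rate(self, axis: str, level: str, baseline: bool = False) -> float:
        """Pooled all-cause rate per 1,000 for one marginal demographic group.

        ``axis`` is one of ``sex``/``race``/``bolsa_familia``. Within each
        city the group rate averages its cells by cell weight; cities pool by
        scenario weight times the group's within-city share.
        """
        col = "baseline_per_1000" if baseline else "rate_per_1000"
        sub = self.rates[self.rates[axis] == level]
        if sub.empty:
            raise ValidationError(f"grouping {axis}={level!r} absent from results")
        num, den = 0.0, 0.0
        for city, g in sub.groupby("city"):
            share = g[g.cause == g.cause.iloc[0]]["weight"].sum()
            cw = float(self.weights[city]) * share
            city_rate = (g[col] * g["weight"]).sum() / share
            num += cw * city_rate
            den += cw
        return num / den


def apply_scenario(
    schedule: pd.DataFrame,
    cities: Sequence[CityProfile],
    delta_pp: float,
    weighting: str = "population",
) -> ScenarioResult:
    """Analytic projection of the whole schedule at one coverage shift.

    Effective coverage is clamped into [0, 1] per city. ``weighting`` pools
    cities by population (default) or equally.
    """
    if weighting not in ("population", "equal"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    scenario = CoverageScenario(delta_pp)
    city_map = {c.name: c for c in cities}
    missing = set(schedule["city"]) - set(city_map)
    if missing:
        raise ValidationError(f"schedule cities {sorted(missing)} missing from city list")

    df = schedule.copy()
    df["p_eff"] = [scenario.effective_coverage(p) for p in df["p"]]
    df["rate"] = project_rate(df["mb"].to_numpy(), df["hr"].to_numpy(), df["p_eff"].to_numpy())
    df["rate_per_1000"] = df["rate"] * 1000.0
    df["baseline_per_1000"] = df["mc"] * 1000.0
    df["ratio"] = df["rate"] / df["mc"]

    weights = pd.Series(
        {
            name: (float(city_map[name].population) if weighting == "population" else 1.0)
            for name in sorted(set(schedule["city"]))
        }
    )
    weights = weights / weights.sum()

    cell = df.assign(wrate=df["weight"] * df["rate_per_1000"], wbase=df["weight"] * df["baseline_per_1000"])
    by_city_cause = cell.groupby(["city", "cause"])[["wrate", "wbase"]].sum()
    city_crude = by_city_cause.groupby("city")["wrate"].sum()
    city_crude_baseline = by_city_cause.groupby("city")["wbase"].sum()

    w = weights.reindex(by_city_cause.index.get_level_values("city")).to_numpy()
    pooled = (
        by_city_cause.assign(pw_rate=by_city_cause["wrate"] * w, pw_base=by_city_cause["wbase"] * w)
        .groupby("cause")[["pw_rate", "pw_base"]]
        .sum()
        .rename(columns={"pw_rate": "rate_per_1000", "pw_base": "baseline_per_1000"})
    )
    pooled["ratio"] = pooled["rate_per_1000"] / pooled["baseline_per_1000"]
    order = [c.code for c in ADULT_CAUSES if c.code in pooled.index]
    pooled = pooled.reindex(order)

    keep = ["city", "cause", "sex", "race", "bolsa_familia", "weight",
            "rate_per_1000", "baseline_per_1000", "ratio"]
    return ScenarioResult(
        delta_pp=delta_pp,
        rates=df[keep].reset_index(drop=True),
        city_crude=city_crude,
        city_crude_baseline=city_crude_baseline,
        pooled_cause=pooled,
        pooled_all_cause_rate=float(pooled["rate_per_1000"].sum()),
        pooled_all_cause_baseline=float(pooled["baseline_per_1000"].sum()),
        weights=weights,
    )


def scenario_sweep(
    schedule: pd.DataFrame,
    cities: Sequence[CityProfile],
    deltas: Iterable[float] = (-20, -10, 0, 10, 20, 30, 40),
    weighting: str = "population",
) -> list[ScenarioResult]:
    """Run `apply_scenario` over a grid of percentage-point shifts."""
    return [apply_scenario(schedule, cities, d, weighting) for d in deltas]


# --------------------------------------------------------------------------
# Stochastic individual-level engine
# --------------------------------------------------------------------------


@dataclass
class MicrosimResult:
    """Death counts from the stochastic engine.

    ``deaths`` has one row per city x cause x subgroup cell x age band with
    the simulated death count; ``exposure`` holds person-years per city.
    """

    delta_pp: float
    deaths: pd.DataFrame
    exposure: dict[str, float]

    def cause_rates(self, city: str) -> pd.Series:
        """Deaths per 1,000 person-years by cause for one city."""
        d = self.deaths[self.deaths.city == city].groupby("cause")["deaths"].sum()
        return d / self.exposure[city] * 1000.0

    def crude_rate(self, city: str) -> float:
        d = self.deaths[self.deaths.city == city]["deaths"].sum()
        return float(d) / self.exposure[city] * 1000.0


def _reassign_enrolment(enrolled: np.ndarray, p: float, p_eff: float, rng: np.random.Generator) -> np.ndarray:
    """Monotone re-enrolment: rising coverage keeps every current enrolee,
    falling coverage disenrols uniformly at random."""
    out = enrolled.copy()
    if p_eff > p and p < 1.0:
        gain = (p_eff - p) / (1.0 - p)
        newly = ~enrolled & (rng.random(enrolled.size) < gain)
        out |= newly
    elif p_eff < p and p > 0.0:
        keep = p_eff / p
        out &= rng.random(enrolled.size) < keep
    return out


def run_microsim(
    populations: Mapping[str, pd.DataFrame],
    schedule: pd.DataFrame,
    delta_pp: float,
    cfg: EngineConfig,
    age_factors: Mapping[str, Mapping[str, float]] | None = None,
) -> MicrosimResult:
    """Stochastic projection: one multinomial death draw per individual-year.

    ``populations`` maps city name to an individual table from
    :func:`fhsim.synth.gen_population`. Each individual's per-cause annual
    probability is the cell's base probability times the cause hazard ratio
    if enrolled, optionally scaled by a city age-band factor (population
    weighted mean 1) so deaths carry an age gradient. A single multinomial
    with a survival residual guarantees at most one death per individual per
    year; in multi-year mode survivors are re-exposed with unchanged
    probabilities (closed population, no ageing).
    """
    scenario = CoverageScenario(delta_pp)
    rng = np.random.default_rng(cfg.seed)
    cell_index = {sg.key: i for i, sg in enumerate(FULL_SUBGROUPS)}
    causes = sorted(set(schedule["cause"]))
    records: list[dict] = []
    exposure: dict[str, float] = {}

    for city in sorted(populations):
        pop = populations[city]
        sched = schedule[schedule.city == city]
        if sched.empty:
            raise ValidationError(f"no schedule rows for city {city!r}")
        p = float(sched["p"].iloc[0])
        p_eff = scenario.effective_coverage(p)

        mb_mat = np.zeros((len(cell_index), len(causes)))
        hr_mat = np.ones_like(mb_mat)
        for r in sched.itertuples():
            i = cell_index[(r.sex, r.race, r.bolsa_familia)]
            j = causes.index(r.cause)
            mb_mat[i, j] = r.mb
            hr_mat[i, j] = r.hr

        sub_idx = np.array(
            [cell_index[k] for k in zip(pop["sex"], pop["race"], pop["bolsa_familia"])]
        )
        enrolled = _reassign_enrolment(pop["enrolled"].to_numpy(bool), p, p_eff, rng)

        probs = mb_mat[sub_idx] * np.where(enrolled[:, None], hr_mat[sub_idx], 1.0)
        if age_factors is not None:
            fac = pd.Series(age_factors[city]).reindex(AGE_BAND_LABELS)
            probs = probs * fac.to_numpy()[
                pd.Categorical(pop["age_band"], categories=AGE_BAND_LABELS).codes, None
            ]
        total = probs.sum(axis=1)
        if np.any(total >= 1.0):
            raise ValidationError(
                f"total annual death probability reaches 1 for some individual in {city!r}"
            )
        cum = np.cumsum(probs, axis=1)

        alive = np.ones(len(pop), dtype=bool)
        person_years = 0.0
        death_cause = np.full(len(pop), -1)
        for _ in range(cfg.years):
            idx = np.flatnonzero(alive)
            person_years += idx.size
            u = rng.random(idx.size)
            died = u < total[idx]
            hit = idx[died]
            death_cause[hit] = (u[died, None] < cum[hit]).argmax(axis=1)
            alive[hit] = False

        dead = death_cause >= 0
        if dead.any():
            tally = (
                pd.DataFrame(
                    {
                        "cause": [causes[c] for c in death_cause[dead]],
                        "sex": pop["sex"].to_numpy()[dead],
                        "race": pop["race"].to_numpy()[dead],
                        "bolsa_familia": pop["bolsa_familia"].to_numpy()[dead],
                        "age_band": pop["age_band"].to_numpy()[dead],
                    }
                )
                .value_counts()
                .rename("deaths")
                .reset_index()
            )
            tally.insert(0, "city", city)
            records.append(tally)
        exposure[city] = person_years

    deaths = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["city", "cause", "sex", "race", "bolsa_familia", "age_band", "deaths"])
    )
    return MicrosimResult(delta_pp=delta_pp, deaths=deaths, exposure=exposure)
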