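"""Outcome surfaces: age-standardised rates, child mortality, premature NCD
mortality, inequality gaps and SDG-target assessment.

Gap metrics are absolute differences of all-cause rates (per 1,000) between
named groups; the between-city gap is the spread between the highest- and
lowest-mortality city. The SDG scorecard operationalises target 3.4 as a
one-third reduction of premature (<70) non-communicable-disease mortality,
"ending" communicable-disease deaths as a 100% reduction target, and target
3.2 as under-5 mortality below 25 per 1,000 live births in every city.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import ScenarioResult, calibrate_base, project_rate
from .synth import SynthConfig, age_factors
from .types import (
    AGE_BANDS,
    CAUSE_REGISTRY,
    CityProfile,
    CoverageScenario,
    HazardRatioTable,
    ValidationError,
    band_masses,
)

__all__ = [
    "age_standardise",
    "pooled_standard_weights",
    "WHO_STANDARD_WEIGHTS",
    "child_mortality",
    "premature_ncd",
    "GapReport",
    "inequality_gaps",
    "sdg_assessment",
    "GAP_GROUPINGS",
]


# --------------------------------------------------------------------------
# Age standardisation
# --------------------------------------------------------------------------


def age_standardise(
    band_rates: Mapping[str, float], standard_weights: Mapping[str, float]
) -> float:
    """Directly standardised rate: weighted sum of band rates.

    Bands must match exactly and weights sum to 1; a flat schedule is
    invariant under any standard.
    """
    if set(band_rates) != set(standard_weights):
        raise ValidationError(
            f"band mismatch: rates {sorted(band_rates)} vs weights {sorted(standard_weights)}"
        )
    total = sum(standard_weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"standard weights sum to {total}, expected 1")
    return sum(band_rates[b] * standard_weights[b] for b in band_rates)


def pooled_standard_weights(cities: Sequence[CityProfile]) -> dict[str, float]:
    """Default standard population: the pooled age structure of the cities."""
    acc = {b[0]: 0.0 for b in AGE_BANDS}
    total_pop = sum(c.population for c in cities)
    for c in cities:
        masses = band_masses(c)
        for b, m in masses.items():
            acc[b] += m * c.population / total_pop
    return acc


#: WHO World Standard population collapsed onto the package's age bands.
_WHO_RAW = {
    "0-4": 8.86, "5-14": 17.29, "15-24": 16.69, "25-34": 15.54, "35-44": 13.74,
    "45-54": 11.41, "55-64": 8.27, "65-69": 2.96, "70-79": 3.73, "80+": 1.54,
}
WHO_STANDARD_WEIGHTS: dict[str, float] = {
    b: v / sum(_WHO_RAW.values()) for b, v in _WHO_RAW.items()
}


# --------------------------------------------------------------------------
# Child outcomes
# --------------------------------------------------------------------------


def child_mortality(
    city: CityProfile, hr_table: HazardRatioTable, delta_pp: float
) -> tuple[float, float]:
    """Projected infant and under-5 mortality per 1,000 live births.

    Applied at the rate level (no individual children are simulated): the
    observed rate is calibrated to a base rate with the literature-style
    child hazard ratio, then re-projected at the shifted coverage.
    """
    p = city.fhs_coverage
    p_eff = CoverageScenario(delta_pp).effective_coverage(p)
    out = []
    for cause, rate in (("infant", city.infant_mortality), ("under5", city.under5_mortality)):
        try:
            entry = hr_table.lookup(cause)
        except KeyError as exc:
            raise ValidationError(
                f"missing child hazard ratio for {cause!r}", entity=city.name
            ) from exc
        mb = calibrate_base(rate / 1000.0, entry.hr_mean, p)
        out.append(project_rate(mb, entry.hr_mean, p_eff) * 1000.0)
    return out[0], out[1]


# --------------------------------------------------------------------------
# Premature NCD mortality
# --------------------------------------------------------------------------


def _premature_share(city: CityProfile, cfg: SynthConfig, cutoff: int) -> float:
    """Share of a city's deaths occurring below the age cutoff, per the
    exponential age schedule."""
    boundaries = {b[1] for b in AGE_BANDS} | {AGE_BANDS[-1][2]}
    if cutoff not in boundaries:
        raise ValidationError(
            f"age cutoff {cutoff} is not on a band boundary {sorted(boundaries)}"
        )
    fac = age_factors(city, cfg)
    masses = band_masses(city)
    return sum(masses[b] * fac[b] for b, lo, hi in AGE_BANDS if hi <= cutoff)


def premature_ncd(
    result: ScenarioResult,
    baseline: ScenarioResult,
    cities: Sequence[CityProfile],
    cfg: SynthConfig | None = None,
    age_cutoff: int = 70,
) -> dict[str, float]:
    """Pooled premature (<cutoff) non-communicable-disease mortality.

    Deaths below the cutoff are apportioned by the city's age schedule; the
    coverage response scales all bands proportionally, so the premature-NCD
    ratio equals the pooled NCD ratio whenever hazard ratios do not vary by
    age (the model's assumption).
    """
    if cfg is None:
        cfg = SynthConfig()
    city_map = {c.name: c for c in cities}
    ncd = [c for c in result.pooled_cause.index if CAUSE_REGISTRY[c].cause_class == "non-communicable"]
    if not ncd:
        raise ValidationError("no non-communicable causes in results")

    def _pooled(res: ScenarioResult, col: str) -> float:
        by_city = (
            res.rates[res.rates.cause.isin(ncd)]
            .assign(w=lambda d: d["weight"] * d[col])
            .groupby("city")["w"]
            .sum()
        )
        total = 0.0
        for city, rate in by_city.items():
            share = _premature_share(city_map[city], cfg, age_cutoff)
            total += float(res.weights[city]) * rate * share
        return total

    rate = _pooled(result, "rate_per_1000")
    base = _pooled(baseline, "baseline_per_1000")
    return {"rate_per_1000": rate, "baseline_per_1000": base, "ratio": rate / base}


# --------------------------------------------------------------------------
# Inequality gaps
# --------------------------------------------------------------------------

GAP_GROUPINGS = ("between-city", "black-vs-white", "pardo-vs-white", "bf-vs-nonbf")


@dataclass
class GapReport:
    """Absolute all-cause mortality gap (per 1,000) between two groups.

    ``gaps`` is indexed by percentage-point coverage shift; ``baseline_gap``
    is the gap at an unchanged coverage. ``lo``/``hi`` are Monte Carlo
    interval bounds when uncertainty was propagated.
    """

    grouping: str
    baseline_gap: float
    gaps: pd.Series
    lo: pd.Series | None = None
    hi: pd.Series | None = None


def _gap(result: ScenarioResult, grouping: str) -> float:
    if grouping == "between-city":
        return float(result.city_crude.max() - result.city_crude.min())
    pairs = {
        "black-vs-white": ("race", "black", "white"),
        "pardo-vs-white": ("race", "pardo", "white"),
        "bf-vs-nonbf": ("bolsa_familia", "yes", "no"),
    }
    if grouping not in pairs:
        raise ValidationError(f"unknown grouping {grouping!r}; expected one of {GAP_GROUPINGS}")
    axis, a, b = pairs[grouping]
    return result.group_rate(axis, a) - result.group_rate(axis, b)


def inequality_gaps(results: Sequence[ScenarioResult], grouping: str) -> GapReport:
    """Gap trajectory across a scenario sweep.

    Requires a ``delta_pp = 0`` member to define the baseline gap. When the
    disadvantaged group's hazard-ratio benefit is at least as large and its
    baseline rate at least as high, the gap is non-increasing in the
    coverage shift.
    """
    if not results:
        raise ValidationError("results must be non-empty")
    gaps = pd.Series({r.delta_pp: _gap(r, grouping) for r in results}).sort_index()
    if 0 not in gaps.index:
        raise ValidationError("sweep must include delta_pp = 0 to define the baseline gap")
    return GapReport(grouping=grouping, baseline_gap=float(gaps.loc[0]), gaps=gaps)


# --------------------------------------------------------------------------
# SDG scorecard
# --------------------------------------------------------------------------


def sdg_assessment(
    results: Sequence[ScenarioResult],
    cities: Sequence[CityProfile],
    hr_table: HazardRatioTable,
    cfg: SynthConfig | None = None,
) -> dict:
    """Scorecard for SDG targets 3.4, 3.2 and 'ending' communicable deaths.

    Evaluated at the maximum coverage shift in the sweep, against the
    unchanged-coverage baseline: achieved relative reduction vs the one-third
    premature-NCD target, vs the 100% communicable-disease target, and each
    city's projected under-5 rate vs the 25 per-1,000-live-births threshold.
    """
    by_delta = {r.delta_pp: r for r in results}
    if 0 not in by_delta:
        raise ValidationError("sweep must include delta_pp = 0")
    baseline = by_delta[0]
    top = by_delta[max(by_delta)]

    prem = premature_ncd(top, baseline, cities, cfg)
    ncd_reduction = 1.0 - prem["ratio"]

    comm = [c for c in top.pooled_cause.index if CAUSE_REGISTRY[c].cause_class == "communicable"]
    comm_rate = float(top.pooled_cause.loc[comm, "rate_per_1000"].sum())
    comm_base = float(baseline.pooled_cause.loc[comm, "baseline_per_1000"].sum())
    comm_reduction = 1.0 - comm_rate / comm_base

    under5 = {}
    for city in cities:
        _, u5 = child_mortality(city, hr_table, top.delta_pp)
        under5[city.name] = {"rate_per_1000_births": u5, "met": bool(u5 < 25.0)}

    return {
        "delta_pp": top.delta_pp,
        "premature_ncd": {
            "achieved_reduction": ncd_reduction,
            "target_reduction": 1.0 / 3.0,
            "met": bool(ncd_reduction >= 1.0 / 3.0),
        },
        "communicable": {
            "achieved_reduction": comm_reduction,
            "target_reduction": 1.0,
            "met": bool(comm_reduction >= 1.0),
        },
        "under5": under5,
        "under5_met_all_cities": all(v["met"] for v in under5.values()),
    }
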