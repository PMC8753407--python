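"""Core domain types for the FHS coverage microsimulation.

The package models the fifteen largest Brazilian cities and the effect of
Brazil's Family Health Strategy (Estratégia de Saúde da Família, FHS) primary
care programme on cause-specific mortality. Enrolment in the FHS multiplies a
person's hazard of death from each cause by a hazard ratio (HR); a city's
observed mortality is the coverage-weighted mix of enrolled and unenrolled
risk. The types here carry city profiles, the cause-of-death registry,
demographic subgroups, and HR entries with their 95% confidence intervals.

Units convention: city tables store rates exactly as published — deaths per
1,000 person-years (or per 1,000 live births for child outcomes) and
percentages as proportions in [0, 1]. Conversion to annual probabilities
(rate / 1,000) happens only inside the simulation engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ValidationError",
    "CityProfile",
    "CauseGroup",
    "Subgroup",
    "HazardRatioEntry",
    "HazardRatioTable",
    "CoverageScenario",
    "ADULT_CAUSES",
    "CHILD_CAUSES",
    "CAUSE_REGISTRY",
    "CAUSE_CLASSES",
    "SEXES",
    "RACES",
    "BF_STATUSES",
    "AGE_BANDS",
    "band_masses",
]


class ValidationError(ValueError):
    """Raised when a domain object violates an invariant.

    Carries the offending entity (e.g. a city name) and field so callers can
    report exactly which cell of an input table is bad.
    """

    def __init__(self, message: str, *, entity: str | None = None, field_name: str | None = None):
        self.entity = entity
        self.field_name = field_name
        prefix = ""
        if entity is not None:
            prefix += f"[{entity}] "
        if field_name is not None:
            prefix += f"field '{field_name}': "
        super().__init__(prefix + message)


# --------------------------------------------------------------------------
# Cause-of-death registry
# --------------------------------------------------------------------------

CAUSE_CLASSES = ("communicable", "non-communicable", "injury", "maternal", "child-outcome")


@dataclass(frozen=True)
class CauseGroup:
    """One cause-of-death group (ICD-10 chapter aggregate) with its class."""

    code: str
    label: str
    cause_class: str

    def __post_init__(self) -> None:
        if self.cause_class not in CAUSE_CLASSES:
            raise ValidationError(
                f"unknown cause class {self.cause_class!r}", entity=self.code, field_name="cause_class"
            )


# The 17 adult cause groups, in the display order of the published ratio
# matrix, plus the two child outcomes handled at the rate level.
ADULT_CAUSES: tuple[CauseGroup, ...] = (
    CauseGroup("infections_other", "Infections (excluding HIV, TB, malaria, NTDs)", "communicable"),
    CauseGroup("hiv", "HIV", "communicable"),
    CauseGroup("tb_malaria_ntd", "TB, malaria, NTDs", "communicable"),
    CauseGroup("respiratory", "Respiratory", "non-communicable"),
    CauseGroup("nutrition", "Nutrition", "non-communicable"),
    CauseGroup("neoplasms", "Neoplasms", "non-communicable"),
    CauseGroup("nervous_system", "Nervous system", "non-communicable"),
    CauseGroup("endocrine", "Endocrine", "non-communicable"),
    CauseGroup("mental_substance", "Mental/substance use", "non-communicable"),
    CauseGroup("stroke", "Stroke", "non-communicable"),
    CauseGroup("heart_disease", "Heart disease", "non-communicable"),
    CauseGroup("other_cvd", "Other cardiovascular", "non-communicable"),
    CauseGroup("digestive", "Digestive", "non-communicable"),
    CauseGroup("genitourinary", "Genitourinary", "non-communicable"),
    CauseGroup("unintentional_injury", "Unintentional injuries", "injury"),
    CauseGroup("intentional_injury", "Intentional injuries", "injury"),
    CauseGroup("maternal", "Maternal", "maternal"),
)

CHILD_CAUSES: tuple[CauseGroup, ...] = (
    CauseGroup("infant", "Infant mortality", "child-outcome"),
    CauseGroup("under5", "Under-5 mortality", "child-outcome"),
)

CAUSE_REGISTRY: Mapping[str, CauseGroup] = {c.code: c for c in ADULT_CAUSES + CHILD_CAUSES}


# --------------------------------------------------------------------------
# Demographic subgroups
# --------------------------------------------------------------------------

SEXES = ("female", "male")
RACES = ("white", "black", "pardo", "other")
BF_STATUSES = ("yes", "no")  # Bolsa Família (conditional cash transfer) receipt


@dataclass(frozen=True)
class Subgroup:
    """A demographic cell; ``"any"`` on an axis marginalises over it."""

    sex: str = "any"
    race: str = "any"
    bolsa_familia: str = "any"

    def __post_init__(self) -> None:
        if self.sex not in SEXES + ("any",):
            raise ValidationError(f"unknown sex {self.sex!r}", field_name="sex")
        if self.race not in RACES + ("any",):
            raise ValidationError(f"unknown race {self.race!r}", field_name="race")
        if self.bolsa_familia not in BF_STATUSES + ("any",):
            raise ValidationError(
                f"unknown bolsa_familia status {self.bolsa_familia!r}", field_name="bolsa_familia"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.sex, self.race, self.bolsa_familia)

    @property
    def is_marginal(self) -> bool:
        return "any" in self.key


ANY_SUBGROUP = Subgroup()

#: All fully-specified subgroup cells (2 sexes x 4 races x 2 BF statuses).
FULL_SUBGROUPS: tuple[Subgroup, ...] = tuple(
    Subgroup(s, r, b) for s in SEXES for r in RACES for b in BF_STATUSES
)


# --------------------------------------------------------------------------
# City profiles
# --------------------------------------------------------------------------

_PROPORTION_FIELDS = (
    "frac_under15",
    "frac_over64",
    "frac_female",
    "frac_white",
    "frac_black",
    "frac_pardo",
    "frac_poverty",
    "frac_secondary_edu",
    "frac_bolsa_familia",
    "fhs_coverage",
)

_POSITIVE_RATE_FIELDS = (
    "crude_mortality",
    "age_std_mortality",
    "infant_mortality",
    "under5_mortality",
    "crude_birth_rate",
)


@dataclass(frozen=True)
class CityProfile:
    """One city's demographics, FHS coverage and observed mortality.

    ``fhs_coverage`` is the observed proportion of the population enrolled in
    the FHS (2016); mortality rates are per 1,000 person-years, child
    mortality per 1,000 live births. ``population``, ``frac_bolsa_familia``
    and ``crude_birth_rate`` are not part of the published city table and come
    from a companion defaults file or the synthetic generator.
    """

    name: str
    population: int
    frac_under15: float
    frac_over64: float
    frac_female: float
    frac_white: float
    frac_black: float
    frac_pardo: float
    frac_poverty: float
    frac_secondary_edu: float
    frac_bolsa_familia: float
    fhs_coverage: float
    crude_mortality: float
    age_std_mortality: float
    infant_mortality: float
    under5_mortality: float
    crude_birth_rate: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("city name must be non-empty", field_name="name")
        if self.population <= 0:
            raise ValidationError("population must be > 0", entity=self.name, field_name="population")
        for f in _PROPORTION_FIELDS:
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"proportion {v!r} outside [0, 1]", entity=self.name, field_name=f
                )
        for f in _POSITIVE_RATE_FIELDS:
            v = getattr(self, f)
            if not v > 0.0:
                raise ValidationError(f"rate {v!r} must be > 0", entity=self.name, field_name=f)
        race_sum = self.frac_white + self.frac_black + self.frac_pardo
        if race_sum > 1.0 + 1e-9:
            raise ValidationError(
                f"race fractions sum to {race_sum:.3f} > 1", entity=self.name, field_name="frac_white"
            )
        if self.frac_under15 + self.frac_over64 >= 1.0:
            raise ValidationError(
                "under-15 and over-64 fractions must leave a working-age remainder",
                entity=self.name,
                field_name="frac_under15",
            )

    @property
    def frac_other_race(self) -> float:
        return max(0.0, 1.0 - self.frac_white - self.frac_black - self.frac_pardo)

    def race_fraction(self, race: str) -> float:
        if race == "other":
            return self.frac_other_race
        return {"white": self.frac_white, "black": self.frac_black, "pardo": self.frac_pardo}[race]

    def sex_fraction(self, sex: str) -> float:
        return self.frac_female if sex == "female" else 1.0 - self.frac_female

    def bf_fraction(self, status: str) -> float:
        return self.frac_bolsa_familia if status == "yes" else 1.0 - self.frac_bolsa_familia

    def subgroup_weight(self, sg: Subgroup) -> float:
        """Population share of a subgroup cell under independent marginals."""
        w = 1.0
        if sg.sex != "any":
            w *= self.sex_fraction(sg.sex)
        if sg.race != "any":
            w *= self.race_fraction(sg.race)
        if sg.bolsa_familia != "any":
            w *= self.bf_fraction(sg.bolsa_familia)
        return w

    @property
    def live_births(self) -> float:
        """Annual live births implied by the crude birth rate."""
        return self.population * self.crude_birth_rate / 1000.0


# --------------------------------------------------------------------------
# Hazard ratios
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HazardRatioEntry:
    """Effect of FHS enrolment on one cause of death for one subgroup.

    HR < 1 means enrolment is protective. The CI bounds are the published
    2.5%/97.5% limits and need not be symmetric around the mean.
    """

    cause: str
    subgroup: Subgroup
    hr_mean: float
    hr_lo: float
    hr_hi: float

    def __post_init__(self) -> None:
        if self.cause not in CAUSE_REGISTRY:
            raise ValidationError(f"unknown cause {self.cause!r}", entity=self.cause, field_name="cause")
        if not self.hr_lo > 0:
            raise ValidationError(
                f"hr_lo {self.hr_lo!r} must be > 0", entity=self.cause, field_name="hr_lo"
            )
        if not (self.hr_lo <= self.hr_mean <= self.hr_hi):
            raise ValidationError(
                f"require hr_lo <= hr_mean <= hr_hi, got ({self.hr_lo}, {self.hr_mean}, {self.hr_hi})",
                entity=self.cause,
                field_name="hr_mean",
            )

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.cause, *self.subgroup.key)


class HazardRatioTable:
    """Keyed collection of HR entries with ``any``-subgroup fallback lookup."""

    def __init__(self, entries: Iterable[HazardRatioEntry]):
        self._entries: dict[tuple[str, str, str, str], HazardRatioEntry] = {}
        for e in entries:
            if e.key in self._entries:
                raise ValidationError(
                    f"duplicate hazard-ratio key {e.key}", entity=e.cause, field_name="key"
                )
            self._entries[e.key] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[HazardRatioEntry]:
        return iter(self._entries.values())

    def lookup(self, cause: str, subgroup: Subgroup = ANY_SUBGROUP) -> HazardRatioEntry:
        """Exact (cause, subgroup) match, else the cause's ``any`` entry."""
        e = self._entries.get((cause, *subgroup.key))
        if e is not None:
            return e
        e = self._entries.get((cause, "any", "any", "any"))
        if e is not None:
            return e
        raise KeyError(
            f"no hazard ratio for cause {cause!r}, subgroup {subgroup.key} (and no 'any' fallback)"
        )

    def causes(self) -> set[str]:
        return {e.cause for e in self}

    def with_means(self, means: Mapping[tuple[str, str, str, str], float]) -> "HazardRatioTable":
        """Copy of the table with hr_mean replaced (used by Monte Carlo draws).

        CI bounds are widened where needed so entries stay valid; downstream
        projection only reads hr_mean.
        """
        new = []
        for e in self:
            m = means.get(e.key, e.hr_mean)
            new.append(
                HazardRatioEntry(
                    e.cause, e.subgroup, m, min(e.hr_lo, m), max(e.hr_hi, m)
                )
            )
        return HazardRatioTable(new)


# --------------------------------------------------------------------------
# Coverage scenarios
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CoverageScenario:
    """A percentage-point shift of FHS coverage, clamped into [0, 1].

    A city at 76.5% coverage under ``delta_pp=+40`` reaches 100%, not 116.5%.
    """

    delta_pp: float

    def effective_coverage(self, p: float) -> float:
        return min(1.0, max(0.0, p + self.delta_pp / 100.0))


# --------------------------------------------------------------------------
# Age bands
# --------------------------------------------------------------------------

#: (label, lower age, upper age) — upper bound exclusive; the open band is
#: closed at 95 for midpoint/width arithmetic. Boundaries include 15 and 65
#: (the published demographic split) and 70 (the premature-mortality cutoff).
AGE_BANDS: tuple[tuple[str, int, int], ...] = (
    ("0-4", 0, 5),
    ("5-14", 5, 15),
    ("15-24", 15, 25),
    ("25-34", 25, 35),
    ("35-44", 35, 45),
    ("45-54", 45, 55),
    ("55-64", 55, 65),
    ("65-69", 65, 70),
    ("70-79", 70, 80),
    ("80+", 80, 95),
)

AGE_BAND_LABELS: tuple[str, ...] = tuple(b[0] for b in AGE_BANDS)


def band_masses(city: CityProfile) -> dict[str, float]:
    """Population share of each age band for a city.

    The three published fractions pin the macro bands (<15, 15-64, 65+);
    mass is spread uniformly by width within each macro band.
    """
    u15 = city.frac_under15
    o64 = city.frac_over64
    mid = 1.0 - u15 - o64
    masses: dict[str, float] = {}
    for label, lo, hi in AGE_BANDS:
        width = hi - lo
        if hi <= 15:
            masses[label] = u15 * width / 15.0
        elif lo >= 65:
            masses[label] = o64 * width / 30.0  # 65..95 spans 30 years
        else:
            masses[label] = mid * width / 50.0  # 15..65 spans 50 years
    return masses
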