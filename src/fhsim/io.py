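"""Readers and writers for city tables, hazard-ratio tables and result files.

All files are plain CSV/JSON: comma-separated, UTF-8, ``.`` decimal point.
City tables store percentages and per-1,000 rates exactly as published;
readers convert percentages to proportions. Output writers are deterministic:
the same results object produces byte-identical files.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    ADULT_CAUSES,
    CAUSE_REGISTRY,
    CityProfile,
    HazardRatioEntry,
    HazardRatioTable,
    Subgroup,
    ValidationError,
)

__all__ = [
    "read_city_table",
    "load_packaged_cities",
    "load_default_cause_mix",
    "load_reference_ratio_matrix",
    "read_hr_table",
    "write_hr_table",
    "write_city_table",
    "write_results",
    "round_half_up",
]

_CITY_COLUMNS = {
    "pct_under15": "frac_under15",
    "pct_over64": "frac_over64",
    "pct_female": "frac_female",
    "pct_white": "frac_white",
    "pct_black": "frac_black",
    "pct_pardo": "frac_pardo",
    "pct_poverty": "frac_poverty",
    "pct_secondary_edu": "frac_secondary_edu",
    "fhs_coverage_pct": "fhs_coverage",
}

_RATE_COLUMNS = {
    "crude_mortality_per_1000": "crude_mortality",
    "age_std_mortality_per_1000": "age_std_mortality",
    "infant_mortality_per_1000": "infant_mortality",
    "under5_mortality_per_1000": "under5_mortality",
}

_DEFAULT_COLUMNS = ("population", "bolsa_familia_pct", "crude_birth_rate_per_1000")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("fhsim").joinpath("data", name)))


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError("file is empty", entity=str(path)) from None
    if df.empty:
        raise ValidationError("file has a header but no rows", entity=str(path))
    return df


def read_city_table(
    path: str | Path,
    defaults_path: str | Path | None = None,
) -> list[CityProfile]:
    """Read and validate a city-profile CSV.

    ``path`` must carry the published columns (percentages and per-1,000
    rates). Population, Bolsa Família share and crude birth rate are merged
    in from ``defaults_path`` (the packaged synthetic defaults when omitted)
    unless the table already carries those columns itself.
    """
    df = _read_csv(path)
    required = ["city", *_CITY_COLUMNS, *_RATE_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s) {missing}", entity=str(path))

    if not all(c in df.columns for c in _DEFAULT_COLUMNS):
        defaults = _read_csv(defaults_path or _data_path("city_defaults.csv"))
        df = df.merge(defaults, on="city", how="left", validate="one_to_one")
    if df[list(_DEFAULT_COLUMNS)].isna().any().any():
        bad = df.loc[df[list(_DEFAULT_COLUMNS)].isna().any(axis=1), "city"].tolist()
        raise ValidationError(f"no defaults entry for city/cities {bad}", entity=str(path))

    profiles: list[CityProfile] = []
    for _, row in df.iterrows():
        city = str(row["city"])
        kwargs: dict = {"name": city}
        for col in list(_CITY_COLUMNS) + list(_RATE_COLUMNS) + list(_DEFAULT_COLUMNS):
            v = row[col]
            try:
                v = float(v)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric cell {row[col]!r}", entity=city, field_name=col
                ) from None
            if col in _CITY_COLUMNS:
                kwargs[_CITY_COLUMNS[col]] = v / 100.0
            elif col in _RATE_COLUMNS:
                kwargs[_RATE_COLUMNS[col]] = v
            elif col == "population":
                kwargs["population"] = int(v)
            elif col == "bolsa_familia_pct":
                kwargs["frac_bolsa_familia"] = v / 100.0
            else:
                kwargs["crude_birth_rate"] = v
        profiles.append(CityProfile(**kwargs))
    return profiles


def load_packaged_cities() -> list[CityProfile]:
    """The packaged 15-city table (2016) with synthetic default weights."""
    return read_city_table(_data_path("cities.csv"))


def load_default_cause_mix() -> dict[str, float]:
    """Packaged plausible adult cause-of-death mix (fractions sum to 1)."""
    df = _read_csv(_data_path("cause_mix.csv"))
    mix = dict(zip(df["cause"], df["fraction"].astype(float)))
    unknown = set(mix) - set(CAUSE_REGISTRY)
    if unknown:
        raise ValidationError(f"unknown cause code(s) {sorted(unknown)}", entity="cause_mix")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"cause mix sums to {total}, expected 1", entity="cause_mix")
    return mix


def load_reference_ratio_matrix() -> pd.DataFrame:
    """Packaged published pooled ratio matrix (cause label x delta column)."""
    df = _read_csv(_data_path("reference_ratio_matrix.csv"))
    return df.set_index("cause")


# --------------------------------------------------------------------------
# Hazard-ratio tables
# --------------------------------------------------------------------------

_HR_COLUMNS = ("cause", "sex", "race", "bolsa_familia", "hr_mean", "hr_lo", "hr_hi")


def read_hr_table(path: str | Path) -> HazardRatioTable:
    """Read a hazard-ratio CSV into a validated, duplicate-free table."""
    df = _read_csv(path)
    missing = [c for c in _HR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s) {missing}", entity=str(path))
    entries = []
    for _, row in df.iterrows():
        sg = Subgroup(str(row["sex"]), str(row["race"]), str(row["bolsa_familia"]))
        entries.append(
            HazardRatioEntry(
                str(row["cause"]), sg,
                float(row["hr_mean"]), float(row["hr_lo"]), float(row["hr_hi"]),
            )
        )
    return HazardRatioTable(entries)


def write_hr_table(entries: Iterable[HazardRatioEntry], path: str | Path) -> None:
    rows = [
        {
            "cause": e.cause,
            "sex": e.subgroup.sex,
            "race": e.subgroup.race,
            "bolsa_familia": e.subgroup.bolsa_familia,
            "hr_mean": repr(e.hr_mean),
            "hr_lo": repr(e.hr_lo),
            "hr_hi": repr(e.hr_hi),
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=list(_HR_COLUMNS)).to_csv(path, index=False)


def write_city_table(profiles: Sequence[CityProfile], path: str | Path) -> None:
    """Write city profiles back to the published-units CSV schema."""
    rows = []
    for c in profiles:
        rows.append(
            {
                "city": c.name,
                **{col: repr(round(getattr(c, attr) * 100.0, 10)) for col, attr in _CITY_COLUMNS.items()},
                **{col: repr(getattr(c, attr)) for col, attr in _RATE_COLUMNS.items()},
                "population": c.population,
                "bolsa_familia_pct": repr(round(c.frac_bolsa_familia * 100.0, 10)),
                "crude_birth_rate_per_1000": repr(c.crude_birth_rate),
            }
        )
    cols = ["city", *_CITY_COLUMNS, *_RATE_COLUMNS, *_DEFAULT_COLUMNS]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Results
# --------------------------------------------------------------------------


def round_half_up(x: float, decimals: int = 2) -> float:
    """Display rounding (0.005 -> 0.01), matching published-table style."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def write_results(results: Sequence, outdir: str | Path) -> dict[str, Path]:
    """Write a scenario sweep to disk.

    Produces ``results.csv`` (long format, full precision), a published-style
    wide ``ratio_matrix.csv`` (pooled cause ratios, 2 dp, half-up) and
    ``summary.json``. Deterministic: identical inputs give identical bytes.

    ``results`` is a sequence of :class:`fhsim.engine.ScenarioResult`.
    """
    if not results:
        raise ValidationError("results must be non-empty", entity="write_results")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = sorted(results, key=lambda r: r.delta_pp)

    long = pd.concat(
        [r.rates.assign(delta_pp=r.delta_pp) for r in results], ignore_index=True
    )
    cols = ["delta_pp"] + [c for c in long.columns if c != "delta_pp"]
    long = long[cols]
    results_path = outdir / "results.csv"
    long.to_csv(results_path, index=False, float_format="%.12g")

    # Wide published-style matrix: rows = cause labels (all-cause first),
    # columns = percentage-point deltas, cells = pooled ratio at 2 dp.
    def _col(delta: float) -> str:
        d = int(delta) if float(delta).is_integer() else delta
        return f"{d}%"

    matrix: dict[str, dict[str, str]] = {}
    all_label = "All causes"
    for r in results:
        col = _col(r.delta_pp)
        matrix.setdefault(all_label, {})[col] = f"{round_half_up(r.pooled_all_cause_ratio):.2f}"
        for code, ratio in r.pooled_cause["ratio"].items():
            label = CAUSE_REGISTRY[code].label
            matrix.setdefault(label, {})[col] = f"{round_half_up(float(ratio)):.2f}"
    order = [all_label] + [c.label for c in ADULT_CAUSES if c.label in matrix]
    wide = pd.DataFrame.from_dict(matrix, orient="index").reindex(order)
    wide.index.name = "cause"
    matrix_path = outdir / "ratio_matrix.csv"
    wide.to_csv(matrix_path)

    summary = {
        "deltas_pp": [r.delta_pp for r in results],
        "pooled_all_cause": {
            _col(r.delta_pp): {
                "rate_per_1000": r.pooled_all_cause_rate,
                "ratio": r.pooled_all_cause_ratio,
            }
            for r in results
        },
        "city_crude_per_1000": {
            _col(r.delta_pp): {k: float(v) for k, v in r.city_crude.items()} for r in results
        },
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    return {"results": results_path, "ratio_matrix": matrix_path, "summary": summary_path}
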