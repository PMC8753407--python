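"""Coverage-response curves: mortality vs percentage-point coverage shift.

One line per city, four panels — crude all-cause, age-standardised
all-cause, infant and under-5 mortality — the standard way these scenario
sweeps are displayed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .engine import ScenarioResult
from .metrics import child_mortality, pooled_standard_weights, age_standardise
from .synth import SynthConfig, gen_age_schedule
from .types import CityProfile, HazardRatioTable

__all__ = ["plot_curves", "coverage_response_figure"]


def plot_curves(
    curves: Mapping[str, Mapping[float, float]],
    ylabel: str,
    title: str = "",
    ax: "plt.Axes | None" = None,
) -> "plt.Axes":
    """Plot one line per city over percentage-point deltas."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for name, pts in curves.items():
        deltas = sorted(pts)
        ax.plot(deltas, [pts[d] for d in deltas], label=name, lw=1.2)
    ax.axvline(0.0, color="grey", lw=0.6, ls=":")
    ax.set_xlabel("Change in FHS coverage (percentage points)")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    return ax


def coverage_response_figure(
    results: Sequence[ScenarioResult],
    cities: Sequence[CityProfile],
    hr_table: HazardRatioTable,
    cfg: SynthConfig | None = None,
) -> "plt.Figure":
    """Four-panel figure of projected mortality vs coverage shift."""
    cfg = cfg or SynthConfig()
    std = pooled_standard_weights(cities)

    crude = {c.name: {} for c in cities}
    agestd = {c.name: {} for c in cities}
    infant = {c.name: {} for c in cities}
    under5 = {c.name: {} for c in cities}
    for r in results:
        for c in cities:
            crude[c.name][r.delta_pp] = float(r.city_crude[c.name])
            # proportional scaling of the baseline age schedule by the
            # city's all-cause response, then re-standardisation
            ratio = float(r.city_crude[c.name] / r.city_crude_baseline[c.name])
            sched = {b: v * ratio for b, v in gen_age_schedule(c, cfg).items()}
            agestd[c.name][r.delta_pp] = age_standardise(sched, std)
            i, u = child_mortality(c, hr_table, r.delta_pp)
            infant[c.name][r.delta_pp] = i
            under5[c.name][r.delta_pp] = u

    fig, axes = plt.subplots(2, 2, figsize=(11, 8), sharex=True)
    plot_curves(crude, "Deaths per 1,000", "(A) Crude all-cause mortality", axes[0, 0])
    plot_curves(agestd, "Deaths per 1,000", "(B) Age-standardised all-cause mortality", axes[0, 1])
    plot_curves(infant, "Deaths per 1,000 live births", "(C) Infant mortality", axes[1, 0])
    plot_curves(under5, "Deaths per 1,000 live births", "(D) Under-5 mortality", axes[1, 1])
    axes[0, 0].legend(fontsize=6, ncol=2)
    fig.tight_layout()
    return fig
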