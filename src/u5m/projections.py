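"""Scenario projections of component mortality rates, 2025-30.

To keep NMR, IMR and U5MR internally consistent, projections operate on
*component rates*: the neonatal rate q(0-28d), the conditional
post-neonatal rate q(28d-1y) and the conditional child rate q(1-5y).
Their survival product reconstructs IMR and U5MR.  Each component is
projected log-linearly under a scenario, clamped at an absorbing floor,
then recombined.

Scenarios: ``constant`` (rates frozen at the base year), ``current_trends``
(each component declines at the country's crisis-free 2015-24 annual rate
of reduction; negative ARRs clamp to zero), the lower/upper-UI variants of
current trends, ``sdg_target`` (off-track countries follow a log-linear
path reaching U5MR 25 and NMR 12 per 1000 exactly in 2030) and
``high_income`` (countries above the 2024 high-income averages reach U5MR
5.1 and NMR 2.8 per 1000 in 2030).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from u5m.data_model import ConfigError
from u5m.deaths import DeathsTable, compute_deaths, rates_to_hazards
from u5m.metrics import arr_with_ui

SCENARIO_KINDS = (
    "constant", "current_trends", "current_trends_lower",
    "current_trends_upper", "sdg_target", "high_income",
)
COMPONENTS = ("nmr", "pnmr", "cmr")


@dataclass
class ComponentRates:
    """Internally consistent component probabilities per country-year.

    All fields are probabilities (not per-1000): ``nmr`` = q(0-28d),
    ``pnmr`` = conditional q(28d-1y), ``cmr`` = conditional q(1-5y).
    Arrays are aligned with ``years``.
    """

    country_id: str
    years: np.ndarray
    nmr: np.ndarray
    pnmr: np.ndarray
    cmr: np.ndarray

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            v = getattr(self, name)
            if np.any(v < 0) or np.any(v >= 1):
                raise ValueError(f"component {name} outside [0, 1)")

    def component(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def at(self, year: int) -> dict[str, float]:
        i = int(np.nonzero(np.asarray(self.years) == year)[0][0])
        return {c: float(getattr(self, c)[i]) for c in COMPONENTS}


@dataclass
class ScenarioSpec:
    """A projection scenario with its floors and thresholds (per 1000)."""

    kind: str
    arr_period: tuple = (2015, 2024)
    floors: Mapping[str, float] = field(
        default_factory=lambda: {"nmr": 0.7, "pnmr": 0.1, "cmr": 0.3})
    floor_min_births: float = 10_000.0
    sdg_u5mr: float = 25.0
    sdg_nmr: float = 12.0
    hic_u5mr: float = 5.1
    hic_nmr: float = 2.8
    base_year: int = 2024
    horizon: int = 2030

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ConfigError(f"unknown scenario kind {self.kind!r}")
        if not (self.sdg_u5mr > self.floors["nmr"] and self.sdg_nmr > 0):
            raise ConfigError("thresholds must exceed floors")


def decompose(nmr, imr, u5mr) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split NMR/IMR/U5MR probabilities into component rates.

    ``pnmr = 1 - (1-imr)/(1-nmr)``; ``cmr = 1 - (1-u5mr)/(1-imr)``.
    Inputs are probabilities in [0, 1) obeying nmr <= imr <= u5mr.
    """
    nmr = np.asarray(nmr, float)
    imr = np.asarray(imr, float)
    u5mr = np.asarray(u5mr, float)
    if np.any(nmr > imr + 1e-12) or np.any(imr > u5mr + 1e-12):
        raise ValueError("ordering violated: need nmr <= imr <= u5mr")
    pnmr = 1.0 - (1.0 - imr) / (1.0 - nmr)
    cmr = 1.0 - (1.0 - u5mr) / (1.0 - imr)
    return nmr, np.clip(pnmr, 0.0, None), np.clip(cmr, 0.0, None)


def recombine(nmr, pnmr, cmr) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`decompose`; ordering holds by construction."""
    nmr = np.asarray(nmr, float)
    imr = 1.0 - (1.0 - nmr) * (1.0 - np.asarray(pnmr, float))
    u5mr = 1.0 - (1.0 - imr) * (1.0 - np.asarray(cmr, float))
    return nmr, imr, u5mr


def components_from_trajectories(
    country_id: str,
    years: np.ndarray,
    nmr_per1000: np.ndarray,
    imr_per1000: np.ndarray,
    u5mr_per1000: np.ndarray,
) -> ComponentRates:
    """Build :class:`ComponentRates` from per-1000 rate series."""
    n, p, c = decompose(
        np.asarray(nmr_per1000, float) / 1000.0,
        np.asarray(imr_per1000, float) / 1000.0,
        np.asarray(u5mr_per1000, float) / 1000.0,
    )
    return ComponentRates(country_id=country_id, years=np.asarray(years, int),
                          nmr=n, pnmr=p, cmr=c)


def scenario_arr(
    component_trajectories: Mapping[str, object],
    scenario: ScenarioSpec,
) -> dict[str, float]:
    """Per-component ARR implied by a scenario.

    ``component_trajectories`` maps component name to a posterior
    trajectory object (years + draws of the component rate).  The median
    (or the 5th/95th percentile for the UI-bound variants) of the per-draw
    ARR over ``scenario.arr_period`` is used; negative values clamp to
    zero, so rising mortality holds rates at base-year levels.
    """
    if scenario.kind == "constant":
        return {c: 0.0 for c in COMPONENTS}
    t1, t2 = scenario.arr_period
    out = {}
    for comp in COMPONENTS:
        res = arr_with_ui(component_trajectories[comp], t1, t2)
        if scenario.kind == "current_trends_lower":
            a = res.lower
        elif scenario.kind == "current_trends_upper":
            a = res.upper
        else:
            a = res.median
        out[comp] = max(0.0, a)
    return out


def _log_linear_path(v0: float, v1: float, n_steps: int) -> np.ndarray:
    """Per-year values v0 -> v1 on a log-linear path, excluding v0."""
    if v0 <= 0 or v1 <= 0:
        raise ValueError("log-linear path needs positive endpoints")
    return v0 * (v1 / v0) ** (np.arange(1, n_steps + 1) / n_steps)


def _current_trends_path(
    v0: float, arr_value: float, years_ahead: int, floor: float
) -> np.ndarray:
    """Log-linear decline at ``arr_value`` with an absorbing floor."""
    eff_floor = min(floor, v0)  # never raise a country to the floor
    path = v0 * np.exp(-arr_value * np.arange(1, years_ahead + 1))
    return np.maximum(path, eff_floor)


def project(
    components_base: ComponentRates,
    scenario: ScenarioSpec,
    arrs: Mapping[str, float],
) -> ComponentRates:
    """Project component rates from the base year to the horizon.

    Returns component rates for base_year..horizon (inclusive).  For the
    target scenarios, the NMR path is fixed first (log-linear to the NMR
    target when off track), then the post-neonatal and child components of
    the current-trends path are scaled proportionally on the log-survival
    scale so the recombined U5MR hits its target exactly in the horizon
    year.
    """
    base = components_base.at(scenario.base_year)
    n_ahead = scenario.horizon - scenario.base_year
    if n_ahead <= 0:
        raise ConfigError("horizon must exceed base year")

    floors = {c: scenario.floors[c] / 1000.0 for c in COMPONENTS}
    paths = {
        c: _current_trends_path(base[c], arrs.get(c, 0.0), n_ahead, floors[c])
        if base[c] > 0 else np.zeros(n_ahead)
        for c in COMPONENTS
    }

    if scenario.kind in ("sdg_target", "high_income"):
        u5_target = (scenario.sdg_u5mr if scenario.kind == "sdg_target"
                     else scenario.hic_u5mr) / 1000.0
        nmr_target = (scenario.sdg_nmr if scenario.kind == "sdg_target"
                      else scenario.hic_nmr) / 1000.0
        nmr_end, pnmr_end, cmr_end = (paths[c][-1] for c in COMPONENTS)
        _, _, u5_end = recombine(nmr_end, pnmr_end, cmr_end)
        off_track_nmr = nmr_end > nmr_target
        off_track_u5 = u5_end > u5_target
        if off_track_nmr:
            paths["nmr"] = _log_linear_path(base["nmr"], nmr_target, n_ahead)
        if off_track_u5:
            new_nmr_end = paths["nmr"][-1]
            denom = np.log1p(-pnmr_end) + np.log1p(-cmr_end)
            if denom < 0:
                s = (np.log1p(-u5_target) - np.log1p(-new_nmr_end)) / denom
                s = max(s, 0.0)
                pnmr_t = 1.0 - (1.0 - pnmr_end) ** s
                cmr_t = 1.0 - (1.0 - cmr_end) ** s
            else:  # both components already ~zero: put everything on cmr
                surv = (1.0 - u5_target) / (1.0 - new_nmr_end)
                pnmr_t, cmr_t = 0.0, max(0.0, 1.0 - surv)
            for comp, tgt in (("pnmr", pnmr_t), ("cmr", cmr_t)):
                if tgt > 0 and base[comp] > 0:
                    paths[comp] = _log_linear_path(base[comp], tgt, n_ahead)
                else:
                    paths[comp] = np.full(n_ahead, tgt)

    years = np.arange(scenario.base_year, scenario.horizon + 1)
    return ComponentRates(
        country_id=components_base.country_id,
        years=years,
        nmr=np.concatenate([[base["nmr"]], paths["nmr"]]),
        pnmr=np.concatenate([[base["pnmr"]], paths["pnmr"]]),
        cmr=np.concatenate([[base["cmr"]], paths["cmr"]]),
    )


def projected_deaths(
    components: ComponentRates,
    births: pd.Series,
    lead_components: Optional[ComponentRates] = None,
    report_years: Optional[tuple[int, int]] = None,
) -> tuple[DeathsTable, dict[str, float]]:
    """Deaths implied by projected component rates and projected births.

    ``lead_components`` optionally supplies the pre-projection years needed
    so cohorts already alive at the projection start are exposed correctly;
    ``births`` must cover every supplied year.  Returns the deaths table
    plus cumulative totals by age group over ``report_years`` (default: the
    projection span beyond the base year).
    """
    if lead_components is not None:
        years = np.concatenate([lead_components.years, components.years])
        if np.any(np.diff(years) != 1):
            raise ValueError("lead and projected years must be contiguous")
        comp = {
            c: np.concatenate([lead_components.component(c),
                               components.component(c)])
            for c in COMPONENTS
        }
    else:
        years = np.asarray(components.years)
        comp = {c: components.component(c) for c in COMPONENTS}

    missing = set(years.tolist()) - set(int(y) for y in births.index)
    if missing:
        raise ValueError(f"missing births for year {min(missing)}")
    b = births.loc[years]

    nmr, imr, u5mr = recombine(comp["nmr"], comp["pnmr"], comp["cmr"])
    hazards = rates_to_hazards(nmr * 1000, imr * 1000, u5mr * 1000, years=years)
    table = compute_deaths(b, hazards, country_id=components.country_id)

    if report_years is None:
        report_years = (int(components.years[0]) + 1, int(components.years[-1]))
    mask = (table.years >= report_years[0]) & (table.years <= report_years[1])
    totals = {
        g: float(table.group(g)[mask].mean(axis=1).sum())
        for g in table.groups
    }
    return table, totals


def averted_deaths(totals_a: Mapping[str, float],
                   totals_b: Mapping[str, float]) -> dict[str, float]:
    """Cumulative deaths averted by scenario B relative to scenario A."""
    return {g: totals_a[g] - totals_b[g] for g in totals_a}
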