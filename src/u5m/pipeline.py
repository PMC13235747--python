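"""End-to-end orchestration on a synthetic world.

Chains the pipeline stages — simulate, filter, fit, ratio model, crisis
adjustment, deaths, metrics, projections, aggregation — into a single
callable used by the command-line interface and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from u5m import metrics
from u5m.aggregation import RegionMap, aggregate_deaths, aggregate_rates, render_report
from u5m.adjustments import apply_crisis_adjustment
from u5m.b3 import (
    B3Config,
    PosteriorTrajectories,
    cap_imr_at_u5mr,
    compute_global_trend,
    extrapolate,
    fit_b3,
)
from u5m.data_model import InclusionRules, apply_inclusion_rules, last_included_year
from u5m.deaths import compute_deaths, rates_to_hazards
from u5m.nmr import RatioModelConfig, derive_nmr, fit_country_multiplier
from u5m.projections import (
    COMPONENTS,
    ComponentRates,
    ScenarioSpec,
    components_from_trajectories,
    project,
    projected_deaths,
    recombine,
    scenario_arr,
)
from u5m.synthetic import SimConfig, generate_world, to_country_dataset


@dataclass
class PipelineResult:
    countries: list
    datasets: dict
    trajectories: dict          # cid -> indicator -> PosteriorTrajectories
    deaths: dict                # cid -> DeathsTable
    regional_deaths: dict
    regional_rates: dict        # indicator -> region -> trajectories
    global_trend: dict
    scenario_totals: dict       # scenario -> age group -> cumulative deaths
    report: dict = field(default_factory=dict)


def _component_trajectories(
    nmr: PosteriorTrajectories,
    imr: PosteriorTrajectories,
    u5mr: PosteriorTrajectories,
) -> dict[str, SimpleNamespace]:
    """Per-draw component-rate pseudo-trajectories for ARR computation."""
    n = min(nmr.n_draws, imr.n_draws, u5mr.n_draws)
    pn = nmr.draws[:n] / 1000.0
    pi = np.minimum(np.maximum(imr.draws[:n] / 1000.0, pn), 0.999)
    pu = np.minimum(np.maximum(u5mr.draws[:n] / 1000.0, pi), 0.9995)
    pnmr = 1.0 - (1.0 - pi) / (1.0 - pn)
    cmr = 1.0 - (1.0 - pu) / (1.0 - pi)
    eps = 1e-7
    return {
        "nmr": SimpleNamespace(years=nmr.years, draws=np.maximum(pn, eps)),
        "pnmr": SimpleNamespace(years=nmr.years, draws=np.maximum(pnmr, eps)),
        "cmr": SimpleNamespace(years=nmr.years, draws=np.maximum(cmr, eps)),
    }


def _restrict(traj: PosteriorTrajectories, y0: int, y1: int
              ) -> PosteriorTrajectories:
    """Restrict a trajectory to the year window [y0, y1]."""
    sel = (traj.years >= y0) & (traj.years <= y1)
    return PosteriorTrajectories(
        country_id=traj.country_id, indicator=traj.indicator,
        years=traj.years[sel], draws=traj.draws[:, sel],
        fitted=traj.fitted[sel], crisis_adjusted=traj.crisis_adjusted,
        metadata=dict(traj.metadata))


def _extend_births(births: pd.Series, through: int) -> pd.Series:
    """Extend a birth series at its recent growth rate."""
    years = np.asarray(births.index, int)
    last = int(years[-1])
    if last >= through:
        return births
    if len(births) >= 2 and births.iloc[-2] > 0:
        growth = births.iloc[-1] / births.iloc[-2]
    else:
        growth = 1.0
    future_years = np.arange(last + 1, through + 1)
    future = births.iloc[-1] * growth ** (future_years - last)
    return pd.concat([births, pd.Series(np.round(future), index=future_years)])


def run_pipeline(
    sim_config: Optional[SimConfig] = None,
    b3_config: Optional[B3Config] = None,
    ratio_config: Optional[RatioModelConfig] = None,
    rules: Optional[InclusionRules] = None,
    scenarios: tuple = ("constant", "current_trends", "sdg_target", "high_income"),
    deaths_draws: int = 200,
    seed: int = 0,
) -> PipelineResult:
    """Run the full pipeline on a synthetic world.

    ``deaths_draws`` caps the number of posterior draws pushed through the
    cohort deaths engine (rate metrics always use the full posterior).
    """
    sim_config = sim_config or SimConfig(seed=seed)
    b3_config = b3_config or B3Config(seed=seed)
    ratio_config = ratio_config or RatioModelConfig(seed=seed)
    rules = rules or InclusionRules()

    countries = generate_world(sim_config)
    datasets = {c.country_id: apply_inclusion_rules(to_country_dataset(c), rules)
                for c in countries}
    region_map = RegionMap({c.country_id: c.region_id for c in countries})
    births = {c.country_id: c.births for c in countries}

    # --- stage 1: U5MR and IMR spline fits ------------------------------
    fitted: dict[str, dict[str, PosteriorTrajectories]] = {}
    for cid, ds in datasets.items():
        fitted[cid] = {}
        for indicator in ("U5MR", "IMR"):
            try:
                fitted[cid][indicator] = fit_b3(
                    ds.observations, b3_config, indicator=indicator)
            except ValueError:
                continue
        if "U5MR" not in fitted[cid]:
            raise RuntimeError(f"country {cid} has no usable U5MR data")
        if "IMR" in fitted[cid]:
            fitted[cid]["IMR"] = cap_imr_at_u5mr(
                fitted[cid]["IMR"], fitted[cid]["U5MR"])

    # --- stage 2: global trend and extrapolation to the reference year --
    gtrend = compute_global_trend(
        {cid: t["U5MR"] for cid, t in fitted.items()}, births,
        window=b3_config.extrapolation_window)
    for cid, ds in datasets.items():
        for indicator in list(fitted[cid]):
            last_year = last_included_year(ds, indicator)
            fitted[cid][indicator] = extrapolate(
                fitted[cid][indicator],
                last_year if last_year is not None else -np.inf,
                gtrend["arr"],
                window=b3_config.extrapolation_window,
                reference_year=b3_config.reference_year)

    # --- stage 3: neonatal ratio model ----------------------------------
    for cid, ds in datasets.items():
        nmr_obs = [o for o in ds.observations if o.indicator == "NMR"]
        ratio = fit_country_multiplier(
            nmr_obs, fitted[cid]["U5MR"], ratio_config)
        fitted[cid]["NMR"] = derive_nmr(fitted[cid]["U5MR"], ratio)
        if "IMR" not in fitted[cid]:
            # no infant data: place IMR a fixed fraction of the way from
            # NMR to U5MR (the generator's own component structure)
            f = sim_config.imr_gap_fraction
            draws = (fitted[cid]["NMR"].draws
                     + f * (fitted[cid]["U5MR"].draws - fitted[cid]["NMR"].draws))
            fitted[cid]["IMR"] = PosteriorTrajectories(
                country_id=cid, indicator="IMR",
                years=fitted[cid]["U5MR"].years, draws=draws,
                fitted=fitted[cid]["U5MR"].fitted)

    crisis_free = {cid: dict(t) for cid, t in fitted.items()}

    # --- stage 4: crisis adjustment -------------------------------------
    adjusted = {}
    for cid, ds in datasets.items():
        adjusted[cid] = apply_crisis_adjustment(
            fitted[cid], ds.crisis_events, births[cid])

    # --- stage 5: deaths -------------------------------------------------
    # deaths are aggregated across countries, so use the common year window
    common_start = max(int(t["U5MR"].years[0]) for t in adjusted.values())
    death_tables = {}
    for cid in adjusted:
        t = {ind: _restrict(traj, common_start, b3_config.reference_year)
             for ind, traj in adjusted[cid].items()}
        n = min(deaths_draws, t["U5MR"].n_draws)
        years = t["U5MR"].years
        nmr_d = t["NMR"].draws[:n]
        imr_d = np.maximum(t["IMR"].draws[:n], nmr_d)
        u5_d = np.maximum(t["U5MR"].draws[:n], imr_d)
        hz = rates_to_hazards(nmr_d.T, imr_d.T, u5_d.T, years=years)
        death_tables[cid] = compute_deaths(
            births[cid].loc[years[0]:years[-1]], hz, country_id=cid)

    regional_deaths = aggregate_deaths(death_tables, region_map)
    regional_rates = {
        indicator: aggregate_rates(
            {cid: t[indicator] for cid, t in adjusted.items()},
            births, region_map)
        for indicator in ("U5MR", "NMR")
    }

    # --- stage 6: scenario projections ----------------------------------
    scenario_totals: dict[str, dict[str, float]] = {}
    base_year = b3_config.reference_year
    horizon = 2030
    for kind in scenarios:
        spec = ScenarioSpec(kind=kind, base_year=base_year, horizon=horizon)
        world_totals = {g: 0.0 for g in ("neonatal", "infant", "1-59m", "under5")}
        for cid in crisis_free:
            t = crisis_free[cid]
            comp_traj = _component_trajectories(t["NMR"], t["IMR"], t["U5MR"])
            arrs = scenario_arr(comp_traj, spec)
            med = {
                c: np.median(comp_traj[c].draws, axis=0) for c in COMPONENTS
            }
            years = t["U5MR"].years
            base_components = ComponentRates(
                country_id=cid, years=years,
                nmr=med["nmr"], pnmr=med["pnmr"], cmr=med["cmr"])
            proj = project(base_components, spec, arrs)
            lead_sel = (years >= base_year - 4) & (years < base_year)
            lead = ComponentRates(
                country_id=cid, years=years[lead_sel],
                nmr=med["nmr"][lead_sel], pnmr=med["pnmr"][lead_sel],
                cmr=med["cmr"][lead_sel])
            b = _extend_births(births[cid], horizon)
            _, totals = projected_deaths(
                proj, b, lead_components=lead,
                report_years=(base_year + 1, horizon))
            for g in world_totals:
                world_totals[g] += totals[g]
        scenario_totals[kind] = world_totals

    report = render_report(
        {region: {ind: regional_rates[ind][region] for ind in regional_rates}
         for region in regional_deaths},
        regional_deaths,
        scenario_totals=scenario_totals,
    )

    return PipelineResult(
        countries=countries, datasets=datasets, trajectories=adjusted,
        deaths=death_tables, regional_deaths=regional_deaths,
        regional_rates=regional_rates, global_trend=gtrend,
        scenario_totals=scenario_totals, report=report,
    )
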