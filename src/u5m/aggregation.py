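"""Regional and global aggregation of country results; report tables.

Totals are aggregated per posterior draw — percentiles are always taken on
aggregated draws, never on summed percentiles (a sum of medians is not the
median of a sum).  Regional rates are birth-weighted means of country
rates per draw-year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from u5m.b3 import PosteriorTrajectories
from u5m.deaths import DeathsTable
from u5m.metrics import arr


@dataclass
class RegionMap:
    """country_id -> region_id, with every country in exactly one region."""

    mapping: Mapping[str, str]

    def region_of(self, country_id: str) -> str:
        try:
            return self.mapping[country_id]
        except KeyError:
            raise KeyError(f"country {country_id!r} has no region") from None

    @property
    def regions(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionMap":
        return cls(dict(zip(df["country_id"].astype(str),
                            df["region_id"].astype(str))))


WORLD = "World"


def aggregate_deaths(
    tables: Mapping[str, DeathsTable],
    region_map: RegionMap,
) -> dict[str, DeathsTable]:
    """Sum country death tables within regions per draw; world = sum of all.

    Countries must share years and draw counts.
    """
    if not tables:
        raise ValueError("no countries to aggregate")
    first = next(iter(tables.values()))
    years = first.years
    out_arrays: dict[str, np.ndarray] = {}
    for cid, table in tables.items():
        region = region_map.region_of(cid)
        if not np.array_equal(table.years, years):
            raise ValueError(f"country {cid} has a different year grid")
        if table.deaths.shape != first.deaths.shape:
            raise ValueError(f"country {cid} has a different draw count")
        for key in (region, WORLD):
            if key not in out_arrays:
                out_arrays[key] = np.zeros_like(first.deaths)
            out_arrays[key] = out_arrays[key] + table.deaths
    return {
        key: DeathsTable(country_id=key, years=years, deaths=dead,
                         complete_from=first.complete_from)
        for key, dead in out_arrays.items()
    }


def aggregate_rates(
    trajectories: Mapping[str, PosteriorTrajectories],
    births: Mapping[str, pd.Series],
    region_map: RegionMap,
) -> dict[str, PosteriorTrajectories]:
    """Birth-weighted regional/world rate trajectories per draw."""
    if not trajectories:
        raise ValueError("no countries to aggregate")
    years_sets = [set(t.years.tolist()) for t in trajectories.values()]
    years = np.array(sorted(set.intersection(*years_sets)), int)
    if years.size == 0:
        raise ValueError("no common years")
    first = next(iter(trajectories.values()))
    n_draws = first.n_draws
    groups: dict[str, list[str]] = {WORLD: list(trajectories)}
    for cid in trajectories:
        groups.setdefault(region_map.region_of(cid), []).append(cid)

    out = {}
    for key, members in groups.items():
        num = np.zeros((n_draws, years.size))
        den = np.zeros(years.size)
        for cid in members:
            traj = trajectories[cid]
            if traj.n_draws != n_draws:
                raise ValueError(f"country {cid} has a different draw count")
            idx = np.searchsorted(traj.years, years)
            b = births[cid]
            wt = np.array([
                float(b.loc[y]) if y in b.index else float(b.iloc[-1])
                for y in years
            ])
            num += traj.draws[:, idx] * wt[None, :]
            den += wt
        if np.any(den <= 0):
            raise ValueError("zero total births in aggregation")
        out[key] = PosteriorTrajectories(
            country_id=key, indicator=first.indicator, years=years,
            draws=num / den[None, :],
        )
    return out


def _fmt_ui(median: float, lo: float, hi: float, nd: int = 1) -> str:
    return f"{median:.{nd}f} ({lo:.{nd}f} to {hi:.{nd}f})"


def render_report(
    rate_trajectories: Mapping[str, Mapping[str, PosteriorTrajectories]],
    death_tables: Mapping[str, DeathsTable],
    report_years: tuple = (1990, 2000, 2015, 2024),
    arr_periods: tuple = ((2000, 2015), (2015, 2024)),
    scenario_totals: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> dict[str, pd.DataFrame]:
    """Assemble report tables in the "median (lo to hi)" house style.

    ``rate_trajectories``: region -> indicator -> trajectories.
    Returns a dict of DataFrames: ``rates``, ``deaths``, ``arr`` and, when
    scenario totals are given, ``scenarios``.
    """
    rate_rows, arr_rows = [], []
    for region, by_ind in rate_trajectories.items():
        for indicator, traj in by_ind.items():
            med = traj.median()
            lo, hi = traj.interval(0.90)
            row = {"region": region, "indicator": indicator}
            for y in report_years:
                sel = np.nonzero(traj.years == y)[0]
                if sel.size:
                    i = sel[0]
                    row[str(y)] = _fmt_ui(med[i], lo[i], hi[i])
            rate_rows.append(row)
            for (t1, t2) in arr_periods:
                if t1 in traj.years and t2 in traj.years:
                    per_draw = arr(traj.at(t1), traj.at(t2), t1, t2) * 100.0
                    arr_rows.append({
                        "region": region, "indicator": indicator,
                        "period": f"{t1}-{t2}",
                        "arr_pct": _fmt_ui(
                            float(np.median(per_draw)),
                            float(np.percentile(per_draw, 5)),
                            float(np.percentile(per_draw, 95)), nd=1),
                    })
    death_rows = []
    for region, table in death_tables.items():
        lo, med, hi = np.percentile(table.deaths, [5, 50, 95], axis=1)
        for gi, g in enumerate(table.groups):
            row = {"region": region, "age_group": g}
            for y in report_years:
                sel = np.nonzero(table.years == y)[0]
                if sel.size:
                    i = sel[0]
                    row[str(y)] = _fmt_ui(med[i, gi], lo[i, gi], hi[i, gi], nd=0)
            death_rows.append(row)

    out = {
        "rates": pd.DataFrame(rate_rows),
        "deaths": pd.DataFrame(death_rows),
        "arr": pd.DataFrame(arr_rows),
    }
    if scenario_totals is not None:
        out["scenarios"] = pd.DataFrame([
            {"scenario": sc, **{g: v for g, v in totals.items()}}
            for sc, totals in scenario_totals.items()
        ])
    return out
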