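"""Cohort-component death counts from rate trajectories and live births.

Each annual birth cohort is split into 52 equal birth-week cohorts entering
at week midpoints.  Every cohort is exposed, over its first five years of
life, to piecewise-constant hazards specific to its current age segment
(0-27 days, 28 days-1 year, 1-4 years) and current calendar year; deaths
are allocated to the calendar year in which they occur and aggregated by
age group.  Within a segment the hazard is constant (exponential survival),
so the survival product over the three segments reconstructs
``1 - U5MR/1000`` exactly.

Conventions: a year is 365.25 days, a week 1/52 year, the neonatal
boundary 28/365.25 years; cohorts crossing a calendar-year boundary switch
to the new year's hazards at the boundary instant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

#: length of a year in days and the age-segment boundaries in years
DAYS_PER_YEAR = 365.25
NEONATAL_END = 28.0 / DAYS_PER_YEAR
SEGMENT_BOUNDS = (0.0, NEONATAL_END, 1.0, 5.0)
SEGMENT_LENGTHS = (NEONATAL_END, 1.0 - NEONATAL_END, 4.0)

AGE_GROUPS = ("neonatal", "infant", "1-59m", "under5")


@dataclass
class AgeSegmentHazards:
    """Per-year hazards (per person-year) on the three under-5 age segments.

    ``hazard`` has shape ``(n_years, 3)`` for point rates or
    ``(n_years, n_draws, 3)`` for draw-level rates.
    """

    years: np.ndarray
    hazard: np.ndarray
    q: np.ndarray  # segment conditional probabilities, same shape

    def __post_init__(self) -> None:
        if np.any(self.hazard < 0):
            raise ValueError("hazards must be non-negative")


def rates_to_hazards(nmr, imr, u5mr, years=None) -> AgeSegmentHazards:
    """Convert NMR/IMR/U5MR (per 1000) into segment hazards.

    The segment conditional probabilities are
    ``q1 = nmr/1000``, ``q2 = 1 - (1-imr/1000)/(1-nmr/1000)``,
    ``q3 = 1 - (1-u5mr/1000)/(1-imr/1000)``; each converts to a constant
    hazard ``h = -ln(1-q)/dt`` over its segment length.

    Inputs may be scalars, per-year vectors, or ``(n_years, n_draws)``
    matrices; ``years`` defaults to ``0..n_years-1``.
    """
    nmr = np.atleast_1d(np.asarray(nmr, dtype=float))
    imr = np.atleast_1d(np.asarray(imr, dtype=float))
    u5mr = np.atleast_1d(np.asarray(u5mr, dtype=float))
    if not (np.all(nmr > 0) and np.all(u5mr < 1000)):
        raise ValueError("rates must satisfy 0 < rate < 1000")
    if np.any(nmr > imr + 1e-12) or np.any(imr > u5mr + 1e-12):
        raise ValueError("rate ordering violated: need nmr <= imr <= u5mr")
    p1, p2, p5 = nmr / 1000.0, imr / 1000.0, u5mr / 1000.0
    q1 = p1
    q2 = 1.0 - (1.0 - p2) / (1.0 - p1)
    q3 = 1.0 - (1.0 - p5) / (1.0 - p2)
    q = np.stack([q1, np.clip(q2, 0, None), np.clip(q3, 0, None)], axis=-1)
    dt = np.asarray(SEGMENT_LENGTHS)
    hazard = -np.log1p(-q) / dt
    if years is None:
        years = np.arange(q.shape[0])
    return AgeSegmentHazards(years=np.asarray(years, int), hazard=hazard, q=q)


def _week_schedule(week: int) -> list[tuple[float, int, int]]:
    """Exposure intervals for a cohort entering at week midpoint.

    Returns ``(duration, segment, calendar_year_offset)`` triples covering
    ages 0 to 5, split at age-segment and calendar-year boundaries.
    """
    entry = (week + 0.5) / 52.0  # fraction of the birth year already elapsed
    cuts = {0.0, 5.0}
    cuts.update(b for b in SEGMENT_BOUNDS if 0.0 < b < 5.0)
    cuts.update(j - entry for j in range(1, 6) if 0.0 < j - entry < 5.0)
    ages = sorted(cuts)
    out = []
    for lo, hi in zip(ages[:-1], ages[1:]):
        seg = int(np.searchsorted(SEGMENT_BOUNDS, lo, side="right")) - 1
        year_offset = int(np.floor(entry + lo + 1e-12))
        out.append((hi - lo, seg, year_offset))
    return out


def compute_deaths(births: pd.Series, hazards: AgeSegmentHazards,
                   country_id: str = "") -> "DeathsTable":
    """Run the 52-weekly-cohort engine.

    ``births``: live births indexed by calendar year.  Every birth year must
    have hazards; exposure extending past the last hazard year is truncated
    there (those deaths fall outside the reported span).  Deaths are
    reported for calendar years from the first birth year through
    ``min(last birth year, last hazard year)``; the first five reported
    years are incomplete unless births for the preceding five years are
    included (``DeathsTable.complete_from``).
    """
    byears = np.asarray(births.index, int)
    if byears.size == 0:
        raise ValueError("no birth years supplied")
    if np.any(np.diff(byears) != 1):
        raise ValueError("birth years must be contiguous")
    hyears = np.asarray(hazards.years, int)
    if np.any(np.diff(hyears) != 1):
        raise ValueError("hazard years must be contiguous")
    missing = set(byears) - set(hyears)
    if missing:
        raise ValueError(f"missing hazards for year {min(missing)}")

    hz = hazards.hazard
    squeeze = hz.ndim == 2
    if squeeze:
        hz = hz[:, None, :]
    n_draws = hz.shape[1]

    b0, b1 = int(byears[0]), int(byears[-1])
    h0, h1 = int(hyears[0]), int(hyears[-1])
    out_years = np.arange(b0, min(b1, h1) + 1)
    n_out = out_years.size
    n_t = byears.size
    bvals = births.to_numpy(float)

    deaths_seg = np.zeros((n_out, n_draws, 3))
    for week in range(52):
        surv = np.repeat(bvals[:, None] / 52.0, n_draws, axis=1)  # (n_t, D)
        for dur, seg, yoff in _week_schedule(week):
            year_idx = byears + yoff - h0           # into hazard array
            out_idx = byears + yoff - b0            # into output array
            valid = year_idx <= (h1 - h0)
            if not valid.any():
                break
            v = np.nonzero(valid)[0]
            h = hz[year_idx[v], :, seg]             # (n_valid, D)
            p_die = -np.expm1(-h * dur)
            dying = surv[v] * p_die
            # one output year per birth year here, so indices are distinct
            rep = out_idx[v] < n_out
            deaths_seg[out_idx[v][rep], :, seg] += dying[rep]
            surv[v] = surv[v] * (1.0 - p_die)

    neon = deaths_seg[..., 0]
    postneo = deaths_seg[..., 1]
    child = deaths_seg[..., 2]
    deaths = np.stack(
        [neon, neon + postneo, postneo + child, neon + postneo + child], axis=-1
    )
    return DeathsTable(
        country_id=country_id,
        years=out_years,
        deaths=deaths,
        complete_from=b0 + 5,
    )


@dataclass
class DeathsTable:
    """Death counts by age group x calendar year (per posterior draw).

    ``deaths`` has shape ``(n_years, n_draws, 4)`` with the age-group axis
    ordered ``neonatal, infant, 1-59m, under5``.  Invariants: neonatal <=
    infant <= under5 and under5 = neonatal + 1-59m in every cell.
    """

    country_id: str
    years: np.ndarray
    deaths: np.ndarray
    complete_from: int = 0
    groups: tuple = AGE_GROUPS

    @property
    def n_draws(self) -> int:
        return self.deaths.shape[1]

    def group(self, name: str) -> np.ndarray:
        return self.deaths[..., self.groups.index(name)]

    def point(self, name: str) -> np.ndarray:
        """Mean across draws for one age group (per year)."""
        return self.group(name).mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, g in enumerate(self.groups):
            for yi, y in enumerate(self.years):
                rows.append({
                    "country_id": self.country_id, "year": int(y),
                    "age_group": g,
                    "deaths": float(self.deaths[yi, :, gi].mean()),
                })
        return pd.DataFrame(rows)


def deaths_uncertainty(table: DeathsTable) -> pd.DataFrame:
    """Median and 90% UI per year x age group across draws.

    Births are treated as fixed: the intervals reflect only mortality-rate
    uncertainty.
    """
    if table.n_draws < 1:
        raise ValueError("need at least one draw")
    lo, med, hi = np.percentile(table.deaths, [5, 50, 95], axis=1)
    rows = []
    for gi, g in enumerate(table.groups):
        for yi, y in enumerate(table.years):
            rows.append({
                "country_id": table.country_id, "year": int(y), "age_group": g,
                "median": med[yi, gi], "lower": lo[yi, gi], "upper": hi[yi, gi],
            })
    return pd.DataFrame(rows)
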