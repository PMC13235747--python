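"""Crisis and HIV/AIDS mortality adjustments.

Trend models are fitted to crisis-free data; deaths from qualifying crisis
events (conflicts, disasters, famines, epidemics) are added back afterwards
as additive rate adjustments in the event years.  The adjustment converts
each event's under-5 crisis deaths to a rate (deaths / live births x 1000)
and adds it to every posterior draw, allocated consistently across
NMR/IMR/U5MR through the event's age pattern.  HIV/AIDS adjustments follow
the same additive mechanics from a per-year table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from u5m.data_model import ConfigError

#: order of age-pattern fractions on a crisis event
CRISIS_AGE_GROUPS = ("0-27d", "28d-11m", "12-59m", "5y+")


@dataclass
class CrisisEvent:
    """A major crisis with total excess deaths and an age allocation pattern.

    ``age_pattern`` gives fractions of total deaths in the four groups
    ``0-27d, 28d-11m, 12-59m, 5y+`` (summing to one).  When age-specific
    under-5 death counts were directly observed (e.g. well-covered vital
    registration), ``direct_counts`` carries them and takes precedence over
    the pattern.
    """

    country_id: str
    years: Sequence[int]
    excess_deaths_total: float
    age_pattern: Sequence[float]
    source: str = ""
    meets_criteria: bool = True
    direct_counts: Optional[Sequence[float]] = None  # (neonatal, postneo, child)

    def __post_init__(self) -> None:
        if self.excess_deaths_total < 0:
            raise ValueError("excess deaths must be non-negative")
        pat = np.asarray(self.age_pattern, dtype=float)
        if pat.size != 4 or np.any(pat < 0):
            raise ValueError("age_pattern needs 4 non-negative fractions")
        if abs(pat.sum() - 1.0) > 1e-6:
            raise ValueError(f"age_pattern fractions sum to {pat.sum()}, not 1")


def allocate_crisis_deaths(event: CrisisEvent) -> dict[str, float]:
    """Split an event's total deaths into under-5 age-group counts.

    Returns counts for ``neonatal`` (0-27d), ``postneonatal`` (28d-11m) and
    ``child`` (12-59m).  Direct vital-registration counts, when present,
    are used verbatim.
    """
    if event.direct_counts is not None:
        d = [float(x) for x in event.direct_counts]
        if len(d) != 3 or any(x < 0 for x in d):
            raise ValueError("direct_counts needs 3 non-negative counts")
        return {"neonatal": d[0], "postneonatal": d[1], "child": d[2]}
    pat = np.asarray(event.age_pattern, dtype=float)
    total = event.excess_deaths_total
    return {
        "neonatal": total * pat[0],
        "postneonatal": total * pat[1],
        "child": total * pat[2],
    }


def crisis_rate_additions(
    events: Sequence[CrisisEvent],
    births: pd.Series,
) -> pd.DataFrame:
    """Per-year additive rate adjustments (per 1000) implied by the events.

    Only events with ``meets_criteria`` contribute.  Multi-year events
    spread their deaths equally across their years.  Columns: ``NMR``,
    ``IMR``, ``U5MR``; index: calendar year.
    """
    rows: dict[int, np.ndarray] = {}
    for ev in events:
        if not ev.meets_criteria:
            continue
        counts = allocate_crisis_deaths(ev)
        n_years = len(ev.years)
        for year in ev.years:
            year = int(year)
            if year not in births.index:
                raise ValueError(f"no live-birth count for crisis year {year}")
            b = float(births.loc[year])
            add = np.array([
                counts["neonatal"],
                counts["neonatal"] + counts["postneonatal"],
                counts["neonatal"] + counts["postneonatal"] + counts["child"],
            ]) / n_years / b * 1000.0
            rows[year] = rows.get(year, np.zeros(3)) + add
    if not rows:
        return pd.DataFrame(columns=["NMR", "IMR", "U5MR"], dtype=float)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["NMR", "IMR", "U5MR"])
    return df.sort_index()


def _add_rates(trajectories, additions: Mapping[int, float]):
    """Return a copy of a PosteriorTrajectories with per-year additive rates."""
    new = replace(trajectories, draws=trajectories.draws.copy())
    years = np.asarray(new.years)
    for year, add in additions.items():
        if add == 0.0:
            continue
        idx = np.nonzero(years == int(year))[0]
        if idx.size == 0:
            raise ValueError(f"adjustment year {year} outside trajectory span")
        new.draws[:, idx[0]] += add
    new.crisis_adjusted = True
    return new


def apply_crisis_adjustment(
    trajectories: Mapping[str, object],
    events: Sequence[CrisisEvent],
    births: pd.Series,
) -> dict[str, object]:
    """Add qualifying crisis deaths to fitted crisis-free trajectories.

    ``trajectories`` maps indicator name (subset of NMR/IMR/U5MR) to
    :class:`~u5m.b3.PosteriorTrajectories`.  Non-event years are unchanged;
    the same additive rate is applied to every posterior draw.  The nested
    allocation (NMR gets neonatal deaths, IMR neonatal+postneonatal, U5MR
    all under-5 deaths) preserves NMR <= IMR <= U5MR ordering.
    """
    additions = crisis_rate_additions(events, births)
    out = {}
    for indicator, traj in trajectories.items():
        if indicator not in ("NMR", "IMR", "U5MR"):
            raise ConfigError(f"unknown indicator {indicator!r}")
        if len(additions):
            out[indicator] = _add_rates(traj, additions[indicator].to_dict())
        else:
            out[indicator] = traj
    return out


def apply_hiv_adjustment(
    trajectories: Mapping[str, object],
    hiv_table: Optional[pd.DataFrame],
    imr_share_of_postneonatal: float = 0.75,
) -> dict[str, object]:
    """Add HIV/AIDS excess child mortality from a per-year table.

    ``hiv_table`` columns: ``year``, ``u5mr_add``, ``nmr_add`` (per 1000,
    non-negative).  The infant-rate addition interpolates between the two:
    neonatal addition plus a fixed share of the post-neonatal under-5
    addition (HIV child deaths concentrate in infancy).  An absent or empty
    table is the identity.
    """
    if hiv_table is None or len(hiv_table) == 0:
        return dict(trajectories)
    tab = hiv_table.set_index("year") if "year" in hiv_table.columns else hiv_table
    u5_add = tab["u5mr_add"].astype(float)
    nmr_add = tab["nmr_add"].astype(float)
    if np.any(u5_add < 0) or np.any(nmr_add < 0):
        raise ValueError("HIV adjustments must be non-negative")
    if np.any(nmr_add > u5_add):
        raise ValueError("neonatal HIV addition exceeds under-5 addition")
    imr_add = nmr_add + imr_share_of_postneonatal * (u5_add - nmr_add)
    adds = {"NMR": nmr_add, "IMR": imr_add, "U5MR": u5_add}
    out = {}
    for indicator, traj in trajectories.items():
        if indicator in adds:
            out[indicator] = _add_rates(traj, adds[indicator].to_dict())
        else:
            out[indicator] = traj
    return out
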