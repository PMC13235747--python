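"""Pace-of-change and share metrics with posterior uncertainty.

The annual rate of reduction (ARR) over a period [t1, t2] is
``ln(rate_t1 / rate_t2) / (t2 - t1)``: a positive fraction per year when
mortality declines.  Uncertainty intervals are 5th/95th percentiles of the
metric computed across posterior trajectories (90% UI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ArrResult:
    name: str
    indicator: str
    t1: float
    t2: float
    median: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        assert self.t1 < self.t2
        assert self.lower <= self.median <= self.upper


def arr(rate_t1: float, rate_t2: float, t1: float, t2: float) -> float:
    """Annual rate of reduction (fraction/year), positive for declines."""
    rate_t1 = np.asarray(rate_t1, dtype=float)
    rate_t2 = np.asarray(rate_t2, dtype=float)
    if np.any(rate_t1 <= 0) or np.any(rate_t2 <= 0):
        raise ValueError("rates must be positive")
    if not t1 < t2:
        raise ValueError("need t1 < t2")
    out = np.log(rate_t1 / rate_t2) / (t2 - t1)
    return float(out) if out.ndim == 0 else out


def arr_with_ui(trajectories, t1: float, t2: float) -> ArrResult:
    """ARR per posterior draw; median and 90% UI across draws.

    ``trajectories`` is a :class:`~u5m.b3.PosteriorTrajectories` (or any
    object with integer ``years`` and a ``(n_draws, n_years)`` ``draws``
    matrix of rates).
    """
    years = np.asarray(trajectories.years)
    for t in (t1, t2):
        if t < years.min() or t > years.max():
            raise ValueError(f"year {t} outside trajectory span")
    i1 = int(np.argmin(np.abs(years - t1)))
    i2 = int(np.argmin(np.abs(years - t2)))
    per_draw = arr(trajectories.draws[:, i1], trajectories.draws[:, i2], t1, t2)
    per_draw = np.atleast_1d(per_draw)
    lo, med, hi = np.percentile(per_draw, [5, 50, 95])
    return ArrResult(
        name=getattr(trajectories, "country_id", ""),
        indicator=getattr(trajectories, "indicator", ""),
        t1=t1, t2=t2, median=float(med), lower=float(lo), upper=float(hi),
    )


def percent_decline(rate_a: float, rate_b: float) -> float:
    """Fractional decline from ``rate_a`` to ``rate_b``: 1 - b/a."""
    if rate_a <= 0:
        raise ValueError("baseline rate must be positive")
    return 1.0 - rate_b / rate_a


def nmr_share(nmr: float, u5mr: float) -> float:
    """Ratio of neonatal to under-5 mortality rate."""
    if not (0 < nmr <= u5mr):
        raise ValueError("need 0 < nmr <= u5mr")
    return nmr / u5mr


def deaths_share(part: float, total: float) -> float:
    """Share of deaths in a subgroup."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= part <= total):
        raise ValueError("need 0 <= part <= total")
    return part / total
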