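"""Synthetic country generator for end-to-end pipeline testing.

Produces complete fake countries with the statistical structure the
estimation model assumes: smooth declining true mortality trajectories
(log-scale piecewise-linear with a slowly varying slope), multi-series
observations with multiplicative log-scale source-type biases and
sampling/non-sampling noise, deterministic live-birth series, and
occasional additive crisis spikes.  Source types follow the usual quality
hierarchy: vital registration (VR) least biased and least noisy, summary
birth histories (SBH) most; SBH series never report neonatal mortality,
which cannot be estimated from summary birth histories.

Observations are drawn around the *crisis-free* truth: crisis deaths enter
the pipeline post-fit through the adjustments stage, mirroring how trend
models are fitted to crisis-free data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from u5m.adjustments import CrisisEvent
from u5m.data_model import (
    ConfigError,
    CountryDataset,
    DataSeries,
    MortalityObservation,
    write_observations,
)

SOURCE_ORDER = ("VR", "SVR", "survey_FBH", "survey_SBH", "census")


@dataclass
class SourceProfile:
    """Log-scale error structure of one source type."""

    bias_sd: float          # spread of the systematic log-offset across series
    sampling_sd: float      # known, reported with each observation
    nonsampling_sd: float   # unknown to the analyst; the model estimates it

    def __post_init__(self) -> None:
        if min(self.bias_sd, self.sampling_sd, self.nonsampling_sd) < 0:
            raise ConfigError("error magnitudes must be non-negative")


#: default quality hierarchy; magnitudes are plausible placeholders, not
#: estimates of any real source's error structure
DEFAULT_PROFILES: dict[str, SourceProfile] = {
    "VR": SourceProfile(bias_sd=0.0, sampling_sd=0.025, nonsampling_sd=0.02),
    "SVR": SourceProfile(bias_sd=0.05, sampling_sd=0.05, nonsampling_sd=0.04),
    "survey_FBH": SourceProfile(bias_sd=0.08, sampling_sd=0.07, nonsampling_sd=0.05),
    "survey_SBH": SourceProfile(bias_sd=0.12, sampling_sd=0.10, nonsampling_sd=0.08),
    "census": SourceProfile(bias_sd=0.10, sampling_sd=0.06, nonsampling_sd=0.06),
}


@dataclass
class SeriesSpec:
    """One data series: its bias, error magnitudes and observation years."""

    series_id: str
    source_type: str
    bias: float
    sampling_sd: float
    nonsampling_sd: float
    obs_years: Sequence[float]
    indicators_covered: Sequence[str] = ("U5MR", "IMR", "NMR")

    def __post_init__(self) -> None:
        if self.sampling_sd < 0 or self.nonsampling_sd < 0:
            raise ConfigError("error sds must be non-negative")
        if self.source_type == "survey_SBH" and "NMR" in self.indicators_covered:
            raise ConfigError("SBH series cannot cover NMR")


@dataclass
class TrueTrajectory:
    """Unobserved true rates (per 1000) with any additive crisis component."""

    country_id: str
    years: np.ndarray
    u5mr: np.ndarray
    imr: np.ndarray
    nmr: np.ndarray
    crisis_additions: np.ndarray  # additive U5MR rate, per 1000

    def __post_init__(self) -> None:
        if np.any(self.nmr <= 0):
            raise ValueError("rates must be positive")
        if np.any(self.nmr > self.imr) or np.any(self.imr > self.u5mr):
            raise ValueError("need nmr <= imr <= u5mr at every year")
        if np.any(self.crisis_additions < 0):
            raise ValueError("crisis additions must be non-negative")

    def rate(self, indicator: str) -> np.ndarray:
        return {"U5MR": self.u5mr, "IMR": self.imr, "NMR": self.nmr}[indicator]


@dataclass
class SimConfig:
    """Study conditions for the synthetic world.

    Baseline levels, decline paces, error magnitudes and crisis frequency
    are chosen to span the range seen across real countries (baseline-year
    U5MR mostly tens to a couple of hundred per 1000, declines of a few
    percent a year, occasional multi-per-1000 crisis spikes).
    """

    n_countries: int = 10
    year_start: int = 1985
    year_end: int = 2024
    n_regions: int = 3
    # true-trajectory family: log-linear with random-walk slope
    baseline_u5mr_meanlog: float = math.log(90.0)
    baseline_u5mr_sdlog: float = 0.6
    arr_mean: float = 0.03              # mean annual decline of log U5MR
    arr_sd: float = 0.012
    slope_rw_sd: float = 0.004          # per-year innovation of the slope
    # component structure of the truth
    nmr_ratio_intercept: float = 0.95   # log R = a + b log U5MR above plateau
    nmr_ratio_slope: float = -0.31
    nmr_ratio_plateau_u5mr: float = 10.0
    nmr_multiplier_sdlog: float = 0.15  # country deviation from expected ratio
    imr_gap_fraction: float = 0.6       # imr = nmr + f (u5mr - nmr)
    # data availability
    p_vr: float = 0.35
    vr_coverage_beta: tuple = (8.0, 1.5)
    n_fbh_mean: float = 3.0
    n_sbh_mean: float = 1.5
    p_census: float = 0.5
    source_profiles: Mapping[str, SourceProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES))
    # crisis process
    crisis_prob: float = 0.02           # per country-year
    crisis_rate_meanlog: float = math.log(4.0)  # additive U5MR spike, per 1000
    crisis_rate_sdlog: float = 0.7
    crisis_under5_share: float = 0.30   # under-5 share of all-age crisis deaths
    crisis_age_pattern: tuple = (0.05, 0.10, 0.15, 0.70)
    # births
    births_level_logrange: tuple = (math.log(5e4), math.log(2e6))
    births_growth_mean: float = 0.010
    births_growth_sd: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1 or self.year_end <= self.year_start:
            raise ConfigError("need at least one country and a positive span")
        for v in (self.arr_sd, self.slope_rw_sd, self.crisis_prob,
                  self.births_growth_sd, self.nmr_multiplier_sdlog):
            if v < 0:
                raise ConfigError("spread parameters must be non-negative")
        if not 0.0 < self.imr_gap_fraction <= 1.0:
            raise ConfigError("imr_gap_fraction must be in (0, 1]")
        if abs(sum(self.crisis_age_pattern) - 1.0) > 1e-9:
            raise ConfigError("crisis age pattern must sum to 1")


@dataclass
class SyntheticCountry:
    country_id: str
    region_id: str
    truth: TrueTrajectory
    series: list
    observations: list
    births: pd.Series
    crisis_events: list


def _rng(config: SimConfig, country_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, country_index, stream])


def _expected_ratio_truth(u5mr: np.ndarray, config: SimConfig) -> np.ndarray:
    u = np.maximum(u5mr, config.nmr_ratio_plateau_u5mr)
    return np.exp(config.nmr_ratio_intercept + config.nmr_ratio_slope * np.log(u))


def generate_true_trajectory(
    config: SimConfig, country_index: int
) -> TrueTrajectory:
    """Smooth log-scale trajectory with ordering enforced and crisis spikes.

    log U5MR follows a line whose slope (the instantaneous ARR) performs a
    random walk; NMR comes from the ratio relation with a country-specific
    multiplier; IMR sits a fixed fraction of the way from NMR to U5MR.
    """
    rng = _rng(config, country_index, 0)
    years = np.arange(config.year_start, config.year_end + 1)
    n = years.size
    base = math.exp(rng.normal(config.baseline_u5mr_meanlog,
                               config.baseline_u5mr_sdlog))
    base = float(np.clip(base, 3.0, 350.0))
    arr0 = rng.normal(config.arr_mean, config.arr_sd)
    slopes = arr0 + np.cumsum(rng.normal(0.0, config.slope_rw_sd, n - 1))
    log_u5 = math.log(base) - np.concatenate([[0.0], np.cumsum(slopes)])
    u5mr = np.exp(log_u5)
    u5mr = np.clip(u5mr, 1.0, 400.0)

    mult = math.exp(rng.normal(0.0, config.nmr_multiplier_sdlog))
    ratio = _expected_ratio_truth(u5mr, config) * mult
    nmr = u5mr * ratio / (1.0 + ratio)
    imr = nmr + config.imr_gap_fraction * (u5mr - nmr)

    crisis = np.zeros(n)
    if config.crisis_prob > 0:
        hits = rng.random(n) < config.crisis_prob
        sizes = np.exp(rng.normal(config.crisis_rate_meanlog,
                                  config.crisis_rate_sdlog, n))
        crisis = np.where(hits, sizes, 0.0)

    return TrueTrajectory(
        country_id=f"C{country_index:03d}", years=years,
        u5mr=u5mr, imr=imr, nmr=nmr, crisis_additions=crisis,
    )


def generate_births(config: SimConfig, country_index: int) -> pd.Series:
    """Deterministic exponential-growth live-birth series (integer counts)."""
    rng = _rng(config, country_index, 1)
    lo, hi = config.births_level_logrange
    level = math.exp(rng.uniform(lo, hi))
    growth = rng.normal(config.births_growth_mean, config.births_growth_sd)
    years = np.arange(config.year_start, config.year_end + 1)
    births = np.round(level * (1.0 + growth) ** (years - years[0]))
    return pd.Series(births, index=years, name="births")


def generate_series_specs(
    config: SimConfig, country_index: int
) -> list[SeriesSpec]:
    """Sample which series exist for a country and their error structure."""
    rng = _rng(config, country_index, 2)
    cid = f"C{country_index:03d}"
    specs: list[SeriesSpec] = []
    y0, y1 = config.year_start, config.year_end

    def draw(source: str) -> tuple[float, float, float]:
        prof = config.source_profiles[source]
        bias = rng.normal(0.0, prof.bias_sd) if prof.bias_sd > 0 else 0.0
        return bias, prof.sampling_sd, prof.nonsampling_sd

    if rng.random() < config.p_vr:
        lag = int(rng.integers(0, 4))
        bias, ssd, nsd = draw("VR")
        specs.append(SeriesSpec(
            series_id=f"{cid}-VR", source_type="VR", bias=bias,
            sampling_sd=ssd, nonsampling_sd=nsd,
            obs_years=[y + 0.5 for y in range(y0, y1 - lag + 1)],
        ))
    for k in range(rng.poisson(config.n_fbh_mean)):
        sy = int(rng.integers(y0 + 8, y1 + 1))
        bias, ssd, nsd = draw("survey_FBH")
        # retrospective estimates at midpoints of three 5-year recall windows
        obs_years = [sy - 2.5, sy - 7.5, sy - 12.5]
        specs.append(SeriesSpec(
            series_id=f"{cid}-FBH{k}", source_type="survey_FBH", bias=bias,
            sampling_sd=ssd, nonsampling_sd=nsd,
            obs_years=[y for y in obs_years if y >= y0],
        ))
    for k in range(rng.poisson(config.n_sbh_mean)):
        sy = int(rng.integers(y0 + 6, y1 + 1))
        bias, ssd, nsd = draw("survey_SBH")
        obs_years = [sy - 2.0, sy - 5.0, sy - 8.0]
        specs.append(SeriesSpec(
            series_id=f"{cid}-SBH{k}", source_type="survey_SBH", bias=bias,
            sampling_sd=ssd, nonsampling_sd=nsd,
            obs_years=[y for y in obs_years if y >= y0],
            indicators_covered=("U5MR", "IMR"),
        ))
    if rng.random() < config.p_census:
        cy = int(rng.integers(y0 + 5, y1 + 1))
        bias, ssd, nsd = draw("census")
        specs.append(SeriesSpec(
            series_id=f"{cid}-CEN", source_type="census", bias=bias,
            sampling_sd=ssd, nonsampling_sd=nsd,
            obs_years=[cy - 3.0],
            indicators_covered=("U5MR", "IMR"),
        ))
    if not specs:  # guarantee at least one series per country
        bias, ssd, nsd = draw("survey_FBH")
        sy = y1 - 2
        specs.append(SeriesSpec(
            series_id=f"{cid}-FBH0", source_type="survey_FBH", bias=bias,
            sampling_sd=ssd, nonsampling_sd=nsd,
            obs_years=[sy - 2.5, sy - 7.5, sy - 12.5],
        ))
    return specs


def generate_observations(
    truth: TrueTrajectory,
    spec: SeriesSpec,
    seed: int | np.random.Generator = 0,
) -> list[MortalityObservation]:
    """Noisy observations of the crisis-free truth for one series.

    ``observed = true x exp(bias + e)`` with
    ``e ~ Normal(0, sampling_sd^2 + nonsampling_sd^2)``.  The reported
    standard error covers the sampling component only, on the rate scale.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ymin, ymax = float(truth.years.min()), float(truth.years.max() + 1)
    out = []
    total_sd = math.hypot(spec.sampling_sd, spec.nonsampling_sd)
    for ref_year in spec.obs_years:
        if not (ymin <= ref_year <= ymax):
            raise ValueError(f"obs year {ref_year} outside truth span")
        yi = int(np.clip(math.floor(ref_year) - truth.years[0], 0,
                         truth.years.size - 1))
        for indicator in spec.indicators_covered:
            true_rate = float(truth.rate(indicator)[yi])
            value = true_rate * math.exp(spec.bias + rng.normal(0.0, total_sd))
            se = value * spec.sampling_sd
            out.append(MortalityObservation(
                country_id=truth.country_id, series_id=spec.series_id,
                source_type=spec.source_type, indicator=indicator,
                ref_year=float(ref_year), value=value, se=se,
            ))
    return out


def _crisis_events(
    config: SimConfig, truth: TrueTrajectory, births: pd.Series
) -> list[CrisisEvent]:
    events = []
    share = config.crisis_under5_share
    for year, add in zip(truth.years, truth.crisis_additions):
        if add <= 0:
            continue
        under5 = add * float(births.loc[year]) / 1000.0
        events.append(CrisisEvent(
            country_id=truth.country_id, years=(int(year),),
            excess_deaths_total=under5 / share,
            age_pattern=_scaled_pattern(config, share),
            source="synthetic", meets_criteria=True,
        ))
    return events


def _scaled_pattern(config: SimConfig, share: float) -> tuple:
    """Rescale the under-5 part of the age pattern to the under-5 share."""
    p = np.asarray(config.crisis_age_pattern[:3], float)
    p = p / p.sum() * share
    return (p[0], p[1], p[2], 1.0 - share)


def generate_country(config: SimConfig, country_index: int) -> SyntheticCountry:
    truth = generate_true_trajectory(config, country_index)
    births = generate_births(config, country_index)
    specs = generate_series_specs(config, country_index)
    rng = _rng(config, country_index, 3)
    observations = []
    for spec in specs:
        observations.extend(generate_observations(truth, spec, rng))
    return SyntheticCountry(
        country_id=truth.country_id,
        region_id=f"R{country_index % config.n_regions}",
        truth=truth, series=specs, observations=observations,
        births=births, crisis_events=_crisis_events(config, truth, births),
    )


def generate_world(config: SimConfig) -> list[SyntheticCountry]:
    """All countries of a synthetic world; fully determined by the seed."""
    return [generate_country(config, i) for i in range(config.n_countries)]


def to_country_dataset(sc: SyntheticCountry) -> CountryDataset:
    """View a synthetic country through the canonical data model."""
    series = []
    for spec in sc.series:
        series.append(DataSeries(
            series_id=spec.series_id, source_type=spec.source_type,
            country_id=sc.country_id,
            vr_population_coverage=(
                0.95 if spec.source_type == "VR" else None),
        ))
    return CountryDataset(
        country_id=sc.country_id, region_id=sc.region_id,
        series=series, observations=list(sc.observations),
        births=sc.births, crisis_events=list(sc.crisis_events),
    )


def write_dataset(countries: Sequence[SyntheticCountry],
                  path: str | Path) -> None:
    """Write the synthetic world as the pipeline's CSV input schema."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    all_obs = [o for c in countries for o in c.observations]
    write_observations(all_obs, path / "observations.csv")

    series_rows = [
        {
            "country_id": c.country_id, "series_id": s.series_id,
            "source_type": s.source_type,
            "vr_population_coverage": "" if s.source_type != "VR" else 0.95,
            "quality_flags": "",
        }
        for c in countries for s in c.series
    ]
    pd.DataFrame(series_rows, columns=[
        "country_id", "series_id", "source_type",
        "vr_population_coverage", "quality_flags",
    ]).to_csv(path / "series.csv", index=False)

    birth_rows = [
        {"country_id": c.country_id, "year": int(y), "births": int(b)}
        for c in countries for y, b in c.births.items()
    ]
    pd.DataFrame(birth_rows, columns=["country_id", "year", "births"]
                 ).to_csv(path / "births.csv", index=False)

    crisis_rows = [
        {
            "country_id": c.country_id, "year": int(ev.years[0]),
            "excess_deaths_total": ev.excess_deaths_total,
            "age_pattern_id": "synthetic",
            "frac_neonatal": ev.age_pattern[0],
            "frac_postneonatal": ev.age_pattern[1],
            "frac_child": ev.age_pattern[2],
            "frac_over5": ev.age_pattern[3],
            "meets_criteria": ev.meets_criteria,
        }
        for c in countries for ev in c.crisis_events
    ]
    pd.DataFrame(crisis_rows, columns=[
        "country_id", "year", "excess_deaths_total", "age_pattern_id",
        "frac_neonatal", "frac_postneonatal", "frac_child", "frac_over5",
        "meets_criteria",
    ]).to_csv(path / "crises.csv", index=False)

    truth_rows = [
        {
            "country_id": c.country_id, "year": int(y),
            "u5mr": c.truth.u5mr[i], "imr": c.truth.imr[i],
            "nmr": c.truth.nmr[i], "crisis_addition": c.truth.crisis_additions[i],
        }
        for c in countries for i, y in enumerate(c.truth.years)
    ]
    pd.DataFrame(truth_rows, columns=[
        "country_id", "year", "u5mr", "imr", "nmr", "crisis_addition",
    ]).to_csv(path / "truth.csv", index=False)

    regions = [{"country_id": c.country_id, "region_id": c.region_id}
               for c in countries]
    pd.DataFrame(regions, columns=["country_id", "region_id"]
                 ).to_csv(path / "region_map.csv", index=False)
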