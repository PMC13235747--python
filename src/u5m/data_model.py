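"""Canonical observation types, CSV readers/writers and inclusion filters.

A *series* is the set of observations derived from a single survey, census,
vital-registration (VR) or sample-vital-registration (SVR) source.  Series
carry the quality metadata (VR population coverage, quality flags) on which
the pre-fit inclusion rules operate.  Exclusions are flags with reasons, not
deletions, so reports can list what was dropped and why.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SOURCE_TYPES = ("VR", "SVR", "survey_FBH", "survey_SBH", "census")
INDICATORS = ("U5MR", "IMR", "NMR")

#: age-group labels used for crisis allocation and death tables
UNDER5_GROUPS = ("neonatal", "infant", "1-59m", "under5")


class SchemaError(ValueError):
    """A data file violates the expected schema (names the column and row)."""


class ConfigError(ValueError):
    """Invalid configuration passed to a pipeline stage."""


@dataclass
class MortalityObservation:
    """One empirical mortality data point.

    ``value`` is a rate in deaths per 1000 live births; ``se`` is its
    standard error on the same scale.  ``ref_year`` is a decimal year
    (mid-year = x.5).  ``included`` / ``exclusion_reason`` are set by
    :func:`apply_inclusion_rules`.
    """

    country_id: str
    series_id: str
    source_type: str
    indicator: str
    ref_year: float
    value: float
    se: float
    included: bool = True
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.source_type not in SOURCE_TYPES:
            raise SchemaError(f"unknown source_type {self.source_type!r}")
        if self.indicator not in INDICATORS:
            raise SchemaError(f"unknown indicator {self.indicator!r}")
        if not (self.value > 0):
            raise SchemaError(f"non-positive rate {self.value} in {self.series_id}")
        if self.se < 0:
            raise SchemaError(f"negative se {self.se} in {self.series_id}")
        if not (1900.0 <= self.ref_year <= 2100.0):
            raise SchemaError(f"ref_year {self.ref_year} outside plausible range")


@dataclass
class DataSeries:
    series_id: str
    source_type: str
    country_id: str
    vr_population_coverage: Optional[float] = None  # fraction in [0, 1], VR only
    quality_flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.vr_population_coverage is not None and not (
            0.0 <= self.vr_population_coverage <= 1.0
        ):
            raise SchemaError(
                f"vr_population_coverage {self.vr_population_coverage} outside [0, 1]"
            )


@dataclass
class CountryDataset:
    """All inputs for one country: series, observations, births, crises."""

    country_id: str
    region_id: str = "World"
    series: list = field(default_factory=list)
    observations: list = field(default_factory=list)
    births: Optional[pd.Series] = None  # index: calendar year, values: live births
    crisis_events: list = field(default_factory=list)
    hiv_adjustment: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        known = {s.series_id for s in self.series}
        for obs in self.observations:
            if obs.series_id not in known:
                raise SchemaError(
                    f"observation references unknown series {obs.series_id!r}"
                )

    def series_by_id(self, series_id: str) -> DataSeries:
        for s in self.series:
            if s.series_id == series_id:
                return s
        raise KeyError(series_id)


@dataclass
class InclusionRules:
    """Pre-fit quality filters.

    VR series need at least ``min_vr_coverage`` population coverage
    (boundary inclusive).  Series carrying any flag in ``exclude_flags``
    (e.g. ``fieldwork_disrupted``) are excluded.
    """

    min_vr_coverage: float = 0.80
    exclude_flags: frozenset = frozenset({"fieldwork_disrupted", "quality_concern"})
    known_flags: frozenset = frozenset(
        {"fieldwork_disrupted", "quality_concern", "recall_bias_suspected"}
    )

    def __post_init__(self) -> None:
        unknown = set(self.exclude_flags) - set(self.known_flags)
        if unknown:
            raise ConfigError(f"unknown quality flags in rules: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "InclusionRules":
        """Load rules from YAML: ``min_vr_coverage`` and ``exclude_flags``."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "min_vr_coverage" in raw:
            kwargs["min_vr_coverage"] = float(raw["min_vr_coverage"])
        if "exclude_flags" in raw:
            kwargs["exclude_flags"] = frozenset(raw["exclude_flags"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

OBS_COLUMNS = ("country_id", "series_id", "source_type", "indicator",
               "ref_year", "value", "se")
SERIES_COLUMNS = ("country_id", "series_id", "source_type",
                  "vr_population_coverage", "quality_flags")
BIRTHS_COLUMNS = ("country_id", "year", "births")
CRISES_COLUMNS = ("country_id", "year", "excess_deaths_total", "age_pattern_id",
                  "frac_neonatal", "frac_postneonatal", "frac_child", "frac_over5",
                  "meets_criteria")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def read_dataset(
    directory: str | Path,
    region_map: Optional[Mapping[str, str]] = None,
) -> dict[str, CountryDataset]:
    """Read a dataset directory into typed per-country datasets.

    Expects ``observations.csv`` and ``births.csv``; ``series.csv`` and
    ``crises.csv`` are optional (series are reconstructed from observations
    if absent).  Malformed rows raise :class:`SchemaError` naming the file,
    row and column.
    """
    directory = Path(directory)
    obs_df = pd.read_csv(directory / "observations.csv")
    _require_columns(obs_df, OBS_COLUMNS, "observations.csv")
    births_df = pd.read_csv(directory / "births.csv")
    _require_columns(births_df, BIRTHS_COLUMNS, "births.csv")

    series_path = directory / "series.csv"
    if series_path.exists():
        series_df = pd.read_csv(series_path)
        _require_columns(series_df, SERIES_COLUMNS[:3], "series.csv")
    else:
        series_df = obs_df[["country_id", "series_id", "source_type"]].drop_duplicates()

    crises_path = directory / "crises.csv"
    crises_df = pd.read_csv(crises_path) if crises_path.exists() else None
    if crises_df is not None and len(crises_df):
        _require_columns(crises_df, CRISES_COLUMNS[:3], "crises.csv")

    datasets: dict[str, CountryDataset] = {}
    countries = sorted(set(obs_df["country_id"]) | set(births_df["country_id"]))
    for cid in countries:
        cid = str(cid)
        series = []
        for _, row in series_df[series_df["country_id"].astype(str) == cid].iterrows():
            cov = row.get("vr_population_coverage")
            flags = row.get("quality_flags")
            flagset = frozenset(
                f for f in str(flags).split(";") if f and f.lower() != "nan"
            ) if flags is not None and not (isinstance(flags, float) and math.isnan(flags)) else frozenset()
            series.append(DataSeries(
                series_id=str(row["series_id"]),
                source_type=str(row["source_type"]),
                country_id=cid,
                vr_population_coverage=None if cov is None or (isinstance(cov, float) and math.isnan(cov)) else float(cov),
                quality_flags=flagset,
            ))
        observations = []
        sub = obs_df[obs_df["country_id"].astype(str) == cid]
        for idx, row in sub.iterrows():
            try:
                observations.append(MortalityObservation(
                    country_id=cid,
                    series_id=str(row["series_id"]),
                    source_type=str(row["source_type"]),
                    indicator=str(row["indicator"]),
                    ref_year=float(row["ref_year"]),
                    value=float(row["value"]),
                    se=float(row["se"]),
                ))
            except (SchemaError, ValueError) as exc:
                # +2: header line and 1-based indexing
                raise SchemaError(
                    f"observations.csv row {idx + 2}: {exc}"
                ) from exc
        bsub = births_df[births_df["country_id"].astype(str) == cid]
        births = pd.Series(
            bsub["births"].to_numpy(float),
            index=bsub["year"].to_numpy(int),
            name="births",
        ).sort_index() if len(bsub) else None

        crisis_events = []
        if crises_df is not None and len(crises_df):
            from u5m.adjustments import CrisisEvent  # local import: avoid cycle
            csub = crises_df[crises_df["country_id"].astype(str) == cid]
            for _, row in csub.iterrows():
                crisis_events.append(CrisisEvent(
                    country_id=cid,
                    years=(int(row["year"]),),
                    excess_deaths_total=float(row["excess_deaths_total"]),
                    age_pattern=(
                        float(row.get("frac_neonatal", 0.0)),
                        float(row.get("frac_postneonatal", 0.0)),
                        float(row.get("frac_child", 0.0)),
                        float(row.get("frac_over5", 1.0)),
                    ),
                    meets_criteria=bool(row.get("meets_criteria", True)),
                ))
        datasets[cid] = CountryDataset(
            country_id=cid,
            region_id=(region_map or {}).get(cid, "World"),
            series=series,
            observations=observations,
            births=births,
            crisis_events=crisis_events,
        )
    return datasets


def write_observations(observations: Iterable[MortalityObservation],
                       path: str | Path) -> None:
    rows = [
        {
            "country_id": o.country_id, "series_id": o.series_id,
            "source_type": o.source_type, "indicator": o.indicator,
            "ref_year": o.ref_year, "value": o.value, "se": o.se,
        }
        for o in observations
    ]
    pd.DataFrame(rows, columns=list(OBS_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Inclusion rules
# ---------------------------------------------------------------------------

def apply_inclusion_rules(
    dataset: CountryDataset, rules: InclusionRules
) -> CountryDataset:
    """Flag observations for inclusion; idempotent; nothing is deleted.

    VR series with population coverage below ``rules.min_vr_coverage``
    (strictly below: the boundary is inclusive) are excluded with reason
    ``"vr_coverage"``; series carrying an excluded quality flag get reason
    ``"flag:<name>"``.
    """
    excluded_series: dict[str, str] = {}
    for s in dataset.series:
        if s.source_type == "VR" and s.vr_population_coverage is not None:
            if s.vr_population_coverage < rules.min_vr_coverage:
                excluded_series[s.series_id] = "vr_coverage"
                continue
        hit = sorted(set(s.quality_flags) & set(rules.exclude_flags))
        if hit:
            excluded_series[s.series_id] = f"flag:{hit[0]}"
    for obs in dataset.observations:
        reason = excluded_series.get(obs.series_id)
        obs.included = reason is None
        obs.exclusion_reason = reason
    return dataset


def last_included_year(
    dataset: CountryDataset, indicator: str
) -> Optional[float]:
    """Most recent ``ref_year`` among included observations of ``indicator``.

    Returns ``None`` when no observation of that indicator is included.
    """
    years = [
        o.ref_year
        for o in dataset.observations
        if o.included and o.indicator == indicator
    ]
    return max(years) if years else None
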